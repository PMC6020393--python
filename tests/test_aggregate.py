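import numpy as np
import pandas as pd
import pytest

from popaccess import (
    NCHSCountyRecord,
    ValidationError,
    aggregate,
    classify_counties,
    metric_correlations,
    nchs_classify,
    stratified_summary,
)
from popaccess.aggregate import MEASURE_ORDER


def _metrics(rows):
    return pd.DataFrame(rows, columns=["block_id", "metric", "m", "A", "PWD", "pop", "excluded"])


def _hier(block_ids, tract="T1", county="C1", state="S1"):
    return pd.DataFrame({
        "block_id": block_ids,
        "tract_id": tract if isinstance(tract, str) else tract,
        "county_id": county, "state_id": state,
    })


class TestAggregate:
    def test_hand_worked_population_weighting(self):
        m = _metrics([("B1", "euclidean", 7, 0.9, 2.0, 100, False),
                      ("B2", "euclidean", 7, 0.5, 4.0, 300, False)])
        out = aggregate(m, _hier(["B1", "B2"]), "county")
        assert out.loc[0, "PWD"] == pytest.approx(3.5)
        assert out.loc[0, "PWA"] == pytest.approx((100 * 0.9 + 300 * 0.5) / 400)
        assert out.loc[0, "pop"] == 400

    def test_single_block_area_identity(self):
        m = _metrics([("B1", "euclidean", 7, 1.3, 2.7, 50, False)])
        out = aggregate(m, _hier(["B1"]), "tract")
        assert out.loc[0, "PWA"] == 1.3 and out.loc[0, "PWD"] == 2.7

    def test_equal_populations_simple_mean(self):
        m = _metrics([(f"B{i}", "euclidean", 7, a, d, 10, False)
                      for i, (a, d) in enumerate([(1.0, 2.0), (3.0, 6.0), (2.0, 4.0)])])
        out = aggregate(m, _hier([f"B{i}" for i in range(3)]), "county")
        assert out.loc[0, "PWD"] == pytest.approx(4.0)
        assert out.loc[0, "PWA"] == pytest.approx(2.0)

    def test_excluded_blocks_leave_both_numerator_and_denominator(self):
        m = _metrics([("B1", "drive_time", 7, 1.0, 2.0, 100, False),
                      ("B2", "drive_time", 0, np.nan, np.nan, 900, True)])
        out = aggregate(m, _hier(["B1", "B2"]), "county")
        assert out.loc[0, "PWD"] == pytest.approx(2.0)
        assert out.loc[0, "pop"] == 100

    def test_zero_included_population_undefined(self):
        m = _metrics([("B1", "euclidean", 0, np.nan, np.nan, 10, True)])
        out = aggregate(m, _hier(["B1"]), "county")
        assert np.isnan(out.loc[0, "PWA"]) and out.loc[0, "pop"] == 0

    def test_block_absent_from_hierarchy_errors(self):
        m = _metrics([("B9", "euclidean", 7, 1.0, 1.0, 10, False)])
        with pytest.raises(ValidationError, match="B9"):
            aggregate(m, _hier(["B1"]), "county")

    def test_weighted_means_nest_block_tract_county(self, rng):
        n = 60
        bids = [f"B{i:02d}" for i in range(n)]
        hier = pd.DataFrame({
            "block_id": bids,
            "tract_id": [f"T{i % 7}" for i in range(n)],
            "county_id": [f"C{i % 3}" for i in range(n)],
            "state_id": "S1",
        })
        # tracts must nest inside counties for the roll-up comparison
        hier["tract_id"] = hier["county_id"] + hier["tract_id"]
        m = _metrics([(b, "euclidean", 7, rng.uniform(0.1, 5), rng.uniform(0.5, 20),
                       int(rng.integers(1, 500)), False) for b in bids])
        direct = aggregate(m, hier, "county").set_index("area_id")
        tracts = aggregate(m, hier, "tract").merge(
            hier[["tract_id", "county_id"]].drop_duplicates(),
            left_on="area_id", right_on="tract_id")
        for county, grp in tracts.groupby("county_id"):
            w = grp["pop"].to_numpy(float)
            assert np.sum(w * grp["PWD"]) / w.sum() == pytest.approx(
                direct.loc[county, "PWD"], rel=1e-9)
            assert np.sum(w * grp["PWA"]) / w.sum() == pytest.approx(
                direct.loc[county, "PWA"], rel=1e-9)

    def test_population_conservation_across_levels(self, rng):
        n = 40
        bids = [f"B{i:02d}" for i in range(n)]
        hier = pd.DataFrame({"block_id": bids,
                             "tract_id": [f"T{i % 5}" for i in range(n)],
                             "county_id": [f"C{i % 2}" for i in range(n)],
                             "state_id": "S1"})
        m = _metrics([(b, "euclidean", 7, 1.0, 1.0, int(rng.integers(1, 100)), False)
                      for b in bids])
        total = m["pop"].sum()
        for level in ("tract", "county", "state", "national"):
            assert aggregate(m, hier, level)["pop"].sum() == total

    def test_splitting_a_block_preserves_aggregates(self):
        m1 = _metrics([("B1", "euclidean", 7, 2.0, 3.0, 100, False)])
        m2 = _metrics([("B1a", "euclidean", 7, 2.0, 3.0, 60, False),
                       ("B1b", "euclidean", 7, 2.0, 3.0, 40, False)])
        a1 = aggregate(m1, _hier(["B1"]), "county")
        a2 = aggregate(m2, _hier(["B1a", "B1b"]), "county")
        assert a1.loc[0, "PWD"] == a2.loc[0, "PWD"]
        assert a1.loc[0, "pop"] == a2.loc[0, "pop"]

    def test_common_support_unifies_denominators(self):
        m = _metrics([("B1", "euclidean", 7, 1.0, 2.0, 100, False),
                      ("B2", "euclidean", 7, 1.0, 8.0, 100, False),
                      ("B1", "drive_time", 7, 1.0, 3.0, 100, False),
                      ("B2", "drive_time", 0, np.nan, np.nan, 100, True)])
        hier = _hier(["B1", "B2"])
        per_metric = aggregate(m, hier, "national").set_index("metric")
        common = aggregate(m, hier, "national", common_support=True).set_index("metric")
        assert per_metric.loc["euclidean", "pop"] == 200
        assert common.loc["euclidean", "pop"] == 100
        assert common.loc["euclidean", "PWD"] == pytest.approx(2.0)


class TestNCHSClassifier:
    def test_all_six_rule_branches(self):
        cases = [
            # three class-1 subclauses
            (NCHSCountyRecord("c1a", in_msa=True, msa_population=1_500_000,
                              contains_entire_largest_principal_city=True), 1),
            (NCHSCountyRecord("c1b", in_msa=True, msa_population=1_000_000,
                              contained_in_largest_principal_city=True), 1),
            (NCHSCountyRecord("c1c", in_msa=True, msa_population=2_000_000,
                              principal_city_residents=250_000), 1),
            (NCHSCountyRecord("c2", in_msa=True, msa_population=2_000_000,
                              principal_city_residents=249_999), 2),
            (NCHSCountyRecord("c3", in_msa=True, msa_population=500_000), 3),
            (NCHSCountyRecord("c3lo", in_msa=True, msa_population=250_000), 3),
            (NCHSCountyRecord("c4", in_msa=True, msa_population=249_999), 4),
            (NCHSCountyRecord("c5", in_micropolitan=True), 5),
            (NCHSCountyRecord("c6"), 6),
        ]
        for rec, expected in cases:
            cls, label = nchs_classify(rec)
            assert cls == expected, rec.county_id

    def test_labels(self):
        assert nchs_classify(NCHSCountyRecord("x", in_msa=True, msa_population=500_000))[1] == "medium metro"
        assert nchs_classify(NCHSCountyRecord("x"))[1] == "noncore"

    def test_inconsistent_flags_rejected(self):
        with pytest.raises(ValidationError):
            nchs_classify(NCHSCountyRecord("bad", in_msa=True, msa_population=1, in_micropolitan=True))

    def test_vector_wrapper_matches_scalar(self, default_region):
        classes = classify_counties(default_region.nchs)
        assert set(classes["nchs_class"]) == set(range(1, 7))
        assert len(classes) == len(default_region.nchs)


class TestStratifiedSummary:
    def _county_summaries(self, values, counties=None):
        counties = counties or [f"c{i}" for i in range(len(values))]
        return pd.DataFrame({"area_id": counties, "level": "county", "metric": "euclidean",
                             "PWA": values, "PWD": values, "pop": 10, "n_blocks": 1})

    def test_two_county_descriptives(self):
        summaries = self._county_summaries([2.0, 4.0])
        classes = pd.DataFrame({"county_id": ["c0", "c1"], "nchs_class": 3, "nchs_label": "medium metro"})
        out = stratified_summary(summaries, classes)
        row = out[out["nchs_class"] == 3].iloc[0]
        assert (row["mean"], row["median"], row["min"], row["max"]) == (3.0, 3.0, 2.0, 4.0)
        assert row["sd"] == pytest.approx(np.std([2, 4], ddof=1))

    def test_singleton_class_sd_zero_with_flag(self):
        summaries = self._county_summaries([5.0])
        classes = pd.DataFrame({"county_id": ["c0"], "nchs_class": 1, "nchs_label": "large central metro"})
        out = stratified_summary(summaries, classes)
        row = out[out["nchs_class"] == 1].iloc[0]
        assert row["sd"] == 0.0 and bool(row["sd_degenerate"])

    def test_empty_class_reported_with_zero_count(self):
        summaries = self._county_summaries([5.0])
        classes = pd.DataFrame({"county_id": ["c0"], "nchs_class": 1, "nchs_label": "large central metro"})
        out = stratified_summary(summaries, classes)
        row = out[out["nchs_class"] == 6].iloc[0]
        assert row["count"] == 0 and np.isnan(row["mean"])

    def test_unclassified_county_errors(self):
        summaries = self._county_summaries([5.0])
        classes = pd.DataFrame({"county_id": ["other"], "nchs_class": 1, "nchs_label": "x"})
        with pytest.raises(ValidationError, match="c0"):
            stratified_summary(summaries, classes)


class TestMetricCorrelations:
    def _wide_metrics(self, rng, n=30):
        rows = []
        for i in range(n):
            base = rng.uniform(1, 10)
            for metric in ("euclidean", "drive_distance", "drive_time"):
                d = base * rng.uniform(0.9, 1.5)
                rows.append((f"B{i:02d}", metric, 7, 7.0 / d, d, 10, False))
        return _metrics(rows)

    def test_unit_diagonal_symmetry_and_range(self, rng):
        corr = metric_correlations(self._wide_metrics(rng))
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)
        assert (corr.to_numpy() <= 1.0 + 1e-12).all() and (corr.to_numpy() >= -1.0 - 1e-12).all()
        assert list(corr.columns) == MEASURE_ORDER

    def test_perfect_linearity(self):
        rows = []
        for i, x in enumerate([1.0, 2.0, 3.0, 4.0]):
            rows.append((f"B{i}", "euclidean", 7, 2 * x + 3, x, 10, False))
        corr = metric_correlations(_metrics(rows), min_blocks=3)
        assert corr.loc["A_euclidean", "PWD_euclidean"] == pytest.approx(1.0)

    def test_textbook_pearson_example(self):
        # x = (1,2,3,4) against y = (2,1,4,3): r = 0.6 by the hand formula
        rows = []
        for i, (x, y) in enumerate(zip([1, 2, 3, 4], [2, 1, 4, 3])):
            rows.append((f"B{i}", "euclidean", 7, float(x), float(y), 10, False))
        corr = metric_correlations(_metrics(rows), min_blocks=3)
        assert corr.loc["A_euclidean", "PWD_euclidean"] == pytest.approx(0.6)

    def test_too_few_complete_blocks_errors(self):
        rows = [("B1", "euclidean", 7, 1.0, 1.0, 10, False),
                ("B2", "euclidean", 7, 2.0, 2.0, 10, False)]
        with pytest.raises(ValidationError):
            metric_correlations(_metrics(rows))
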