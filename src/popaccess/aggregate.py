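"""Population-weighted roll-up of block metrics, NCHS urban-rural county
classification, stratified summaries, and cross-metric correlations.

Area-level measures are population-weighted means of block-level values:

    PWA_k = sum_i Pop_i * A_i   / Pop_k
    PWD_k = sum_i Pop_i * PWD_i / Pop_k

over the blocks i of area k, with Pop_k the total included population.
Because weighted means nest, aggregating blocks straight to a county equals
aggregating block->tract then tract->county — the roll-up is free of the
modifiable-areal-unit ambiguity at any intermediate level.

Blocks excluded for a metric (no street access) leave both numerator and
denominator for that metric only, so the straight-line and network measures
legitimately carry different denominators; a ``common_support`` flag
restricts every metric to the blocks present in all of them instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "LEVEL_COLUMNS",
    "NCHS_LABELS",
    "NCHSCountyRecord",
    "aggregate",
    "nchs_classify",
    "classify_counties",
    "stratified_summary",
    "metric_correlations",
]

LEVEL_COLUMNS = {"tract": "tract_id", "county": "county_id", "state": "state_id", "national": None}

NCHS_LABELS = {
    1: "large central metro",
    2: "large fringe metro",
    3: "medium metro",
    4: "small metro",
    5: "micropolitan",
    6: "noncore",
}

#: Table-5 style ordering of the six measures for correlation output.
MEASURE_ORDER = [
    "A_drive_time",
    "A_drive_distance",
    "A_euclidean",
    "PWD_drive_time",
    "PWD_drive_distance",
    "PWD_euclidean",
]


def aggregate(
    metrics: pd.DataFrame,
    hierarchy: pd.DataFrame,
    level: str,
    common_support: bool = False,
) -> pd.DataFrame:
    """Population-weighted PWA/PWD per geographic area at the given level.

    Parameters
    ----------
    metrics
        Long block-metrics table (``block_id, metric, m, A, PWD, pop,
        excluded``).
    hierarchy
        DataFrame mapping ``block_id`` to ``tract_id, county_id, state_id``.
    level
        One of ``tract, county, state, national``.
    common_support
        When True, restrict every metric to blocks non-excluded under all
        metrics, so all denominators agree.

    Returns a DataFrame ``area_id, level, metric, PWA, PWD, pop, n_blocks``;
    an area whose included population is zero for a metric gets NaN measures
    with its zero population recorded.
    """
    if level not in LEVEL_COLUMNS:
        raise ValidationError(f"unknown level {level!r}")
    col = LEVEL_COLUMNS[level]
    df = metrics.copy()
    known = set(hierarchy["block_id"])
    missing = set(df["block_id"]) - known
    if missing:
        raise ValidationError(f"blocks absent from hierarchy: {sorted(missing)[:5]}")
    if common_support:
        bad = set(df.loc[df["excluded"], "block_id"])
        df = df[~df["block_id"].isin(bad)]
    if col is None:
        df = df.assign(_area="national")
        col = "_area"
    else:
        df = df.merge(hierarchy[["block_id", col]], on="block_id", how="left")

    rows = []
    # groups keep areas whose blocks are all excluded: they surface as
    # zero-population rows with undefined (NaN) measures
    for (area, metric), grp in df.groupby([col, "metric"], sort=True):
        inc = grp[~grp["excluded"]]
        pop = inc["pop"].to_numpy(float)
        total = pop.sum()
        if total <= 0:
            rows.append((area, level, metric, np.nan, np.nan, 0, len(inc)))
            continue
        pwa = float(np.sum(pop * inc["A"].to_numpy(float)) / total)
        pwd = float(np.sum(pop * inc["PWD"].to_numpy(float)) / total)
        rows.append((area, level, metric, pwa, pwd, int(total), len(inc)))
    return pd.DataFrame(rows, columns=["area_id", "level", "metric", "PWA", "PWD", "pop", "n_blocks"])


@dataclass(frozen=True)
class NCHSCountyRecord:
    """County attributes needed by the six-class NCHS urban-rural scheme."""

    county_id: str
    in_msa: bool = False
    msa_population: int = 0
    in_micropolitan: bool = False
    contains_entire_largest_principal_city: bool = False
    contained_in_largest_principal_city: bool = False
    principal_city_residents: int = 0


def nchs_classify(rec: NCHSCountyRecord) -> tuple[int, str]:
    """Classify a county into NCHS urban-rural classes 1 (most urban) .. 6.

    1 large central metro: in an MSA of >= 1,000,000 residents and contains
      the MSA's entire largest principal city, or is completely contained in
      it, or holds >= 250,000 residents of any principal city;
    2 large fringe metro: MSA >= 1,000,000, not class 1;
    3 medium metro: MSA of 250,000-999,999;
    4 small metro: MSA < 250,000;
    5 micropolitan; 6 noncore (neither MSA nor micropolitan).
    """
    if rec.in_msa and rec.in_micropolitan:
        raise ValidationError(f"county {rec.county_id!r}: both MSA and micropolitan flags set")
    if rec.in_msa:
        if rec.msa_population >= 1_000_000:
            central = (
                rec.contains_entire_largest_principal_city
                or rec.contained_in_largest_principal_city
                or rec.principal_city_residents >= 250_000
            )
            cls = 1 if central else 2
        elif rec.msa_population >= 250_000:
            cls = 3
        else:
            cls = 4
    elif rec.in_micropolitan:
        cls = 5
    else:
        cls = 6
    return cls, NCHS_LABELS[cls]


def classify_counties(nchs: pd.DataFrame) -> pd.DataFrame:
    """Vector wrapper: NCHS attribute table -> county_id, nchs_class, label."""
    out = []
    for rec in nchs.itertuples(index=False):
        cls, label = nchs_classify(
            NCHSCountyRecord(
                county_id=rec.county_id,
                in_msa=bool(rec.in_msa),
                msa_population=int(rec.msa_population),
                in_micropolitan=bool(rec.in_micropolitan),
                contains_entire_largest_principal_city=bool(rec.contains_entire_largest_principal_city),
                contained_in_largest_principal_city=bool(rec.contained_in_largest_principal_city),
                principal_city_residents=int(rec.principal_city_residents),
            )
        )
        out.append((rec.county_id, cls, label))
    return pd.DataFrame(out, columns=["county_id", "nchs_class", "nchs_label"])


def stratified_summary(
    county_summaries: pd.DataFrame,
    classes: pd.DataFrame,
    value: str = "PWD",
) -> pd.DataFrame:
    """Descriptive statistics of county-level values within each NCHS class.

    Unweighted mean/sd/min/median/max and county count, one row per
    (class, metric).  A single-county class reports sd = 0 with
    ``sd_degenerate=True`` so the table stays rectangular; an empty class
    yields count 0 and NaN statistics.
    """
    merged = county_summaries.merge(classes[["county_id", "nchs_class"]],
                                    left_on="area_id", right_on="county_id", how="left")
    if merged["nchs_class"].isna().any():
        bad = merged.loc[merged["nchs_class"].isna(), "area_id"].tolist()
        raise ValidationError(f"counties without an NCHS class: {bad[:5]}")
    rows = []
    metrics = sorted(merged["metric"].unique())
    for cls in range(1, 7):
        for metric in metrics:
            grp = merged[(merged["nchs_class"] == cls) & (merged["metric"] == metric)][value].dropna()
            n = len(grp)
            if n == 0:
                rows.append((cls, NCHS_LABELS[cls], metric, 0, *[np.nan] * 5, False))
            else:
                sd = float(grp.std(ddof=1)) if n > 1 else 0.0
                rows.append((cls, NCHS_LABELS[cls], metric, n, float(grp.mean()), sd,
                             float(grp.min()), float(grp.median()), float(grp.max()), n == 1))
    return pd.DataFrame(
        rows,
        columns=["nchs_class", "nchs_label", "metric", "count", "mean", "sd",
                 "min", "median", "max", "sd_degenerate"],
    )


def metric_correlations(metrics: pd.DataFrame, min_blocks: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of the six block-level measures.

    The long block-metrics table is pivoted to one row per block with
    columns ``A_<metric>`` and ``PWD_<metric>``; network-excluded blocks
    contribute only to the pairs they have values for.  Output is a
    symmetric 6x6 matrix ordered accessibility-first (drive time, drive
    distance, straight line), then the distance measures in the same order.
    """
    df = metrics[~metrics["excluded"]]
    wide = df.pivot(index="block_id", columns="metric", values=["A", "PWD"])
    wide.columns = [f"{stat}_{metric}" for stat, metric in wide.columns]
    order = [c for c in MEASURE_ORDER if c in wide.columns]
    wide = wide[order]
    n_complete = int(wide.dropna().shape[0])
    if n_complete < min_blocks:
        raise ValidationError(
            f"need >= {min_blocks} blocks with all measures, have {n_complete}"
        )
    return wide.corr(method="pearson", min_periods=min_blocks)
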