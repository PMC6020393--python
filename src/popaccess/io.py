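"""Delimited-text and GeoJSON I/O, run configuration, and the pipeline.

Canonical formats are comma-separated UTF-8 tables with a header row:

* blocks:  ``block_id, lon, lat, pop, tract_id, county_id, state_id``
* outlets: ``outlet_id, lon, lat[, weight]`` (missing weight column -> 1)
* nodes:   ``node_id, lon, lat``
* edges:   ``from, to, length_mi, speed_mph`` (or ``time_min``)
* NCHS county attributes: ``county_id, in_msa, msa_population,
  in_micropolitan, contains_entire_largest_principal_city,
  contained_in_largest_principal_city, principal_city_residents``

Readers validate eagerly — missing columns, duplicate ids and unparseable
coordinates are reported with row numbers — and every writer emits tables
the same readers re-parse losslessly (floats at 6 significant digits on
disk, full precision in memory).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .access import DecayConfig, block_metrics
from .aggregate import (
    LEVEL_COLUMNS,
    aggregate,
    classify_counties,
    metric_correlations,
    stratified_summary,
)
from .core import METRICS, ValidationError, check_mode
from .geodist import euclidean_nearest_k
from .network import build_network, network_nearest_k, snap_points

__all__ = [
    "read_blocks", "read_outlets", "read_nodes", "read_edges", "read_nchs",
    "write_table", "points_to_geojson", "points_from_geojson",
    "RunConfig", "PipelineResult", "run_pipeline", "run_from_config", "write_outputs",
]

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False, "t": True, "f": False}


def _require_columns(df: pd.DataFrame, required: tuple, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _check_unique(df: pd.DataFrame, col: str, path) -> None:
    dup = df.loc[df[col].duplicated(), col]
    if len(dup):
        rows = [f"{v!r} (row {i + 2})" for i, v in dup.head(5).items()]
        raise ValidationError(f"{path}: duplicate {col}: " + ", ".join(rows))


def _coerce_floats(df: pd.DataFrame, cols: tuple, path) -> pd.DataFrame:
    errors = []
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad[:5]:
            errors.append(f"{col}={df.loc[i, col]!r} (row {i + 2})")
        if df[col].isna().any():
            i = int(df.index[df[col].isna()][0])
            errors.append(f"{col} empty (row {i + 2})")
        df[col] = coerced
    if errors:
        raise ValidationError(f"{path}: unparseable values: " + "; ".join(errors))
    return df


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise ValidationError(f"input file not found: {path}")


def read_blocks(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ("block_id", "lon", "lat", "pop", "tract_id", "county_id", "state_id"), path)
    _check_unique(df, "block_id", path)
    df = _coerce_floats(df, ("lon", "lat", "pop"), path)
    df["pop"] = df["pop"].astype(int)
    if (df["pop"] < 0).any():
        raise ValidationError(f"{path}: negative population")
    return df


def read_outlets(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ("outlet_id", "lon", "lat"), path)
    _check_unique(df, "outlet_id", path)
    if "weight" not in df.columns:
        df["weight"] = 1.0  # unit weight: every destination treated equally
    df = _coerce_floats(df, ("lon", "lat", "weight"), path)
    if (df["weight"] <= 0).any():
        raise ValidationError(f"{path}: non-positive outlet weight")
    return df


def read_nodes(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ("node_id", "lon", "lat"), path)
    _check_unique(df, "node_id", path)
    return _coerce_floats(df, ("lon", "lat"), path)


def read_edges(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ("from", "to", "length_mi"), path)
    cols = ["length_mi"] + [c for c in ("speed_mph", "time_min") if c in df.columns]
    if len(cols) == 1:
        raise ValidationError(f"{path}: needs a speed_mph or time_min column")
    return _coerce_floats(df, tuple(cols), path)


def read_nchs(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(
        df,
        ("county_id", "in_msa", "msa_population", "in_micropolitan",
         "contains_entire_largest_principal_city",
         "contained_in_largest_principal_city", "principal_city_residents"),
        path,
    )
    _check_unique(df, "county_id", path)
    for col in ("in_msa", "in_micropolitan", "contains_entire_largest_principal_city",
                "contained_in_largest_principal_city"):
        vals = df[col].astype(str).str.strip().str.lower()
        bad = vals[~vals.isin(_BOOL_MAP)]
        if len(bad):
            i = int(bad.index[0])
            raise ValidationError(f"{path}: unparseable boolean {col}={df.loc[i, col]!r} (row {i + 2})")
        df[col] = vals.map(_BOOL_MAP)
    df = _coerce_floats(df, ("msa_population", "principal_city_residents"), path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def points_to_geojson(df: pd.DataFrame, id_col: str, path=None, extra_cols: tuple = ()) -> dict:
    """Point table -> GeoJSON FeatureCollection (optionally written to path)."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r["lon"]), float(r["lat"])]},
            "properties": {id_col: r[id_col], **{c: r[c] for c in extra_cols}},
        }
        for _, r in df.iterrows()
    ]
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(fc))
    return fc


def points_from_geojson(src, id_col: str) -> pd.DataFrame:
    fc = json.loads(Path(src).read_text()) if not isinstance(src, dict) else src
    rows = []
    for feat in fc.get("features", []):
        lon, lat = feat["geometry"]["coordinates"][:2]
        rows.append({id_col: feat["properties"][id_col], "lon": lon, "lat": lat,
                     **{k: v for k, v in feat["properties"].items() if k != id_col}})
    df = pd.DataFrame(rows)
    _check_unique(df, id_col, "geojson")
    return df


@dataclass
class RunConfig:
    """File paths plus model knobs for a pipeline run."""

    blocks: str = ""
    outlets: str = ""
    nodes: str | None = None
    edges: str | None = None
    nchs: str | None = None
    outdir: str = "out"
    mode: str = "geographic"
    n: int = 7
    beta: float = 1.0
    epsilon: float = 0.01
    max_snap_miles: float = 1.0
    metrics: tuple = METRICS
    common_support: bool = False
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        return cls(**data)

    def decay(self) -> DecayConfig:
        return DecayConfig(beta=self.beta, n=self.n, epsilon=self.epsilon)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    block_metrics: pd.DataFrame
    summaries: dict = field(default_factory=dict)  # level -> AreaSummary table
    nchs_classes: pd.DataFrame | None = None
    stratified: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)


def run_pipeline(
    blocks: pd.DataFrame,
    outlets: pd.DataFrame,
    nodes: pd.DataFrame | None = None,
    edges: pd.DataFrame | None = None,
    nchs: pd.DataFrame | None = None,
    mode: str = "geographic",
    decay: DecayConfig = DecayConfig(),
    max_snap_miles: float = 1.0,
    metrics: tuple = METRICS,
    common_support: bool = False,
) -> PipelineResult:
    """Compute block metrics, roll-ups, NCHS strata and correlations.

    The straight-line metric covers every populated block; network metrics
    cover only blocks that snap to the street graph within the snap radius,
    the rest being flagged excluded (and leaving those metrics'
    denominators).  Deterministic given its inputs.
    """
    check_mode(mode)
    metrics = tuple(metrics)
    if not metrics:
        raise ValidationError("metric set is empty")
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValidationError(f"unknown metric(s) {sorted(unknown)}")
    need_net = any(m != "euclidean" for m in metrics)
    if need_net and (nodes is None or edges is None):
        raise ValidationError("network metrics requested but no node/edge tables given")

    populated = blocks[blocks["pop"] > 0].reset_index(drop=True)
    nearest: dict = {}
    excluded: dict = {}
    counts: dict = {}

    if "euclidean" in metrics:
        nearest["euclidean"] = euclidean_nearest_k(populated, outlets, decay.n, mode=mode)

    if need_net:
        net = build_network(nodes, edges, mode=mode)
        bsnap = snap_points(net, populated, "block_id", max_snap_miles)
        osnap = snap_points(net, outlets, "outlet_id", max_snap_miles)
        counts["outlets_snap_excluded"] = int(osnap["excluded"].sum())
        origins = {
            r.block_id: r.node_id for r in bsnap.itertuples(index=False) if not r.excluded
        }
        destinations = {
            r.outlet_id: r.node_id for r in osnap.itertuples(index=False) if not r.excluded
        }
        if not destinations:
            raise ValidationError("no outlet snaps to the street network")
        excl = set(bsnap.loc[bsnap["excluded"], "block_id"])
        for metric, weight in (("drive_distance", "length_mi"), ("drive_time", "time_min")):
            if metric in metrics:
                sets = network_nearest_k(net, origins, destinations, decay.n, weight)
                # origins whose component holds no destination count as excluded too
                unreachable = {ns.origin_id for ns in sets if not ns.reachable}
                nearest[metric] = [ns for ns in sets if ns.reachable]
                excluded[metric] = excl | unreachable

    weights = dict(zip(outlets["outlet_id"], outlets["weight"])) if "weight" in outlets.columns else None
    table, bm_counts = block_metrics(blocks, nearest, decay, weights, excluded)
    counts.update(bm_counts)

    hierarchy = blocks[["block_id", "tract_id", "county_id", "state_id"]]
    summaries = {
        level: aggregate(table, hierarchy, level, common_support) for level in LEVEL_COLUMNS
    }

    nchs_classes = stratified = None
    if nchs is not None:
        nchs_classes = classify_counties(nchs)
        county = summaries["county"]
        strat_pwd = stratified_summary(county, nchs_classes, value="PWD")
        strat_pwa = stratified_summary(county, nchs_classes, value="PWA")
        stratified = pd.concat(
            [strat_pwa.assign(measure="PWA"), strat_pwd.assign(measure="PWD")],
            ignore_index=True,
        )

    correlations = None
    if len(metrics) >= 2:
        try:
            correlations = metric_correlations(table)
        except ValidationError as exc:
            log.warning("correlations skipped: %s", exc)

    return PipelineResult(table, summaries, nchs_classes, stratified, correlations, counts)


def write_outputs(result: PipelineResult, outdir) -> list[str]:
    """Serialize a result bundle; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df, name):
        p = outdir / name
        write_table(df, p)
        written.append(str(p))

    _w(result.block_metrics, "block_metrics.csv")
    for level, df in result.summaries.items():
        _w(df, f"summary_{level}.csv")
    if result.nchs_classes is not None:
        _w(result.nchs_classes, "nchs_classes.csv")
    if result.stratified is not None:
        _w(result.stratified, "stratified_nchs.csv")
    if result.correlations is not None:
        p = outdir / "correlations.csv"
        result.correlations.to_csv(p, float_format=FLOAT_FORMAT)
        written.append(str(p))
    p = outdir / "run_log.json"
    p.write_text(json.dumps(result.counts, indent=2, default=int))
    written.append(str(p))
    return written


def run_from_config(cfg: RunConfig) -> PipelineResult:
    """Read the configured inputs, run the pipeline, write the outputs."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    blocks = read_blocks(cfg.blocks)
    outlets = read_outlets(cfg.outlets)
    nodes = read_nodes(cfg.nodes) if cfg.nodes else None
    edges = read_edges(cfg.edges) if cfg.edges else None
    nchs = read_nchs(cfg.nchs) if cfg.nchs else None
    result = run_pipeline(
        blocks, outlets, nodes, edges, nchs,
        mode=cfg.mode, decay=cfg.decay(), max_snap_miles=cfg.max_snap_miles,
        metrics=cfg.metrics, common_support=cfg.common_support,
    )
    write_outputs(result, cfg.outdir)
    return result
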