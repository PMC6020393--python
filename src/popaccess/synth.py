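"""Seeded synthetic geography: blocks, clustered outlets, a street grid, a
nested hierarchy, and county urban-rural attributes.

The generator emulates the statistical structure the accessibility metrics
assume, so the whole pipeline is exercisable without any licensed data:

* demand units ("blocks") with heavy-tailed (log-normal) populations, a few
  intentionally zero-population to exercise the populated-block filter;
* destinations ("outlets") of which a configurable fraction clusters near
  high-population blocks — the mechanism behind the urban-rural access
  gradient — and the rest scatter uniformly;
* a connected rectangular street grid with per-edge speed classes, hence
  both a driving-distance and a driving-time metric;
* a proper census-style hierarchy (block -> tract -> county -> state) of
  contiguous rectangles, FIPS-style nested id strings;
* county attribute records spanning all six NCHS urban-rural classes, with
  per-class block-population multipliers creating a metro -> noncore
  density gradient.

Planar mode (coordinates in miles on a flat plane) is the default: the
metric algebra is indifferent to Earth curvature and a flat plane supports
exact scaling arguments.  Geographic mode places the same grid near the
equator, where degree-to-mile conversion is uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ValidationError
from .network import StreetNetwork, build_network

__all__ = ["RegionConfig", "Region", "generate_region", "perturb_scale"]

#: Relative block-population scale per NCHS class (1 = large central metro
#: .. 6 = noncore): a ~30x density span, coarsely mirroring how census-block
#: populations fall from metro cores to rural counties.
CLASS_POP_MULTIPLIERS = (32.0, 16.0, 8.0, 4.0, 2.0, 1.0)

# Attribute templates that classify to each NCHS class (see aggregate.nchs_classify).
_NCHS_TEMPLATES = {
    1: dict(in_msa=True, msa_population=2_500_000, in_micropolitan=False,
            contains_entire_largest_principal_city=True,
            contained_in_largest_principal_city=False, principal_city_residents=300_000),
    2: dict(in_msa=True, msa_population=2_500_000, in_micropolitan=False,
            contains_entire_largest_principal_city=False,
            contained_in_largest_principal_city=False, principal_city_residents=40_000),
    3: dict(in_msa=True, msa_population=600_000, in_micropolitan=False,
            contains_entire_largest_principal_city=False,
            contained_in_largest_principal_city=False, principal_city_residents=0),
    4: dict(in_msa=True, msa_population=120_000, in_micropolitan=False,
            contains_entire_largest_principal_city=False,
            contained_in_largest_principal_city=False, principal_city_residents=0),
    5: dict(in_msa=False, msa_population=0, in_micropolitan=True,
            contains_entire_largest_principal_city=False,
            contained_in_largest_principal_city=False, principal_city_residents=0),
    6: dict(in_msa=False, msa_population=0, in_micropolitan=False,
            contains_entire_largest_principal_city=False,
            contained_in_largest_principal_city=False, principal_city_residents=0),
}


@dataclass(frozen=True)
class RegionConfig:
    """Knobs of the synthetic region; defaults define the study conditions.

    The default region is a 23.5 x 15.5 mile street grid (48 x 32 nodes at
    0.5-mile spacing) carrying 720 blocks, 200 outlets (85% clustered
    toward population), and 24 counties tiled 6 columns x 4 rows across 3
    states, 2 tracts per county.  Each county column carries one NCHS
    urban-rural class (1 most urban, west, to 6 most rural, east), and
    log-normal block populations (median ~33 people at the rural baseline)
    are scaled by the column's class multiplier, so outlet clustering
    toward population produces the metro -> noncore access-density
    gradient the stratified summaries are meant to expose.  Four counties
    per class keeps the unweighted class means stable across seeds.
    """

    mode: str = "planar"
    grid_nx: int = 48
    grid_ny: int = 32
    spacing_mi: float = 0.5
    n_blocks: int = 720
    n_outlets: int = 200
    clustering: float = 0.85
    pop_mu: float = 3.5
    pop_sigma: float = 1.2
    zero_pop_fraction: float = 0.02
    speed_classes: tuple = (25.0, 45.0, 65.0)
    speed_weights: tuple = (0.6, 0.3, 0.1)
    n_states: int = 3
    n_counties: int = 24
    county_rows: int = 4
    tracts_per_county: int = 2
    class_pop_multipliers: tuple = CLASS_POP_MULTIPLIERS
    outlet_jitter_mi: float = 0.15
    n_isolated_blocks: int = 0
    island_offset_mi: float = 10.0
    seed: int = 0

    def validate(self) -> "RegionConfig":
        if min(self.grid_nx, self.grid_ny) < 2:
            raise ValidationError("grid must be at least 2 x 2 nodes")
        if not self.spacing_mi > 0:
            raise ValidationError("spacing_mi must be > 0")
        if min(self.n_blocks, self.n_outlets, self.n_states,
               self.n_counties, self.tracts_per_county) < 1:
            raise ValidationError("all counts must be >= 1")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValidationError("clustering must lie in [0, 1]")
        cells = (self.grid_nx - 1) * (self.grid_ny - 1)
        if self.n_counties > cells:
            raise ValidationError(f"{self.n_counties} counties exceed {cells} grid cells")
        if self.county_rows < 1 or self.n_counties % self.county_rows:
            raise ValidationError("n_counties must be a positive multiple of county_rows")
        if self.n_states > self.n_counties // self.county_rows:
            raise ValidationError("more states than county columns")
        if abs(sum(self.speed_weights) - 1.0) > 1e-9 or len(self.speed_weights) != len(self.speed_classes):
            raise ValidationError("speed_weights must match speed_classes and sum to 1")
        return self


@dataclass
class Region:
    """A generated region: all pipeline inputs as plain tables."""

    blocks: pd.DataFrame   # block_id, lon, lat, pop, tract_id, county_id, state_id
    outlets: pd.DataFrame  # outlet_id, lon, lat, weight
    nodes: pd.DataFrame    # node_id, lon, lat
    edges: pd.DataFrame    # from, to, length_mi, speed_mph
    nchs: pd.DataFrame     # county attribute table
    mode: str = "planar"
    config: RegionConfig | None = field(default=None, repr=False)

    def network(self) -> StreetNetwork:
        return build_network(self.nodes, self.edges, mode=self.mode)

    @property
    def hierarchy(self) -> pd.DataFrame:
        return self.blocks[["block_id", "tract_id", "county_id", "state_id"]]


def _county_class(c: int, n_counties: int) -> int:
    """Deterministic class 1..6 for the c-th county strip (urban -> rural)."""
    return 1 + (c * 6) // n_counties


def generate_region(cfg: RegionConfig = RegionConfig()) -> Region:
    """Generate a reproducible synthetic region from a seeded config.

    Counties are contiguous vertical strips ordered most-urban (class 1) to
    most-rural (class 6) along x; tracts slice each strip horizontally;
    states group contiguous strips.  Block centroids fall uniformly inside
    their tract's rectangle (hence near grid nodes); outlet positions mix a
    population-clustered fraction with a uniform remainder.  Every draw
    comes from one seeded generator stream, so equal seeds give
    byte-identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ext_x = (cfg.grid_nx - 1) * cfg.spacing_mi
    ext_y = (cfg.grid_ny - 1) * cfg.spacing_mi

    # street grid
    node_rows = [
        (i * cfg.grid_ny + j, i * cfg.spacing_mi, j * cfg.spacing_mi)
        for i in range(cfg.grid_nx)
        for j in range(cfg.grid_ny)
    ]
    nodes = pd.DataFrame(node_rows, columns=["node_id", "lon", "lat"])
    edge_rows = []
    for i in range(cfg.grid_nx):
        for j in range(cfg.grid_ny):
            nid = i * cfg.grid_ny + j
            if i + 1 < cfg.grid_nx:
                edge_rows.append((nid, (i + 1) * cfg.grid_ny + j))
            if j + 1 < cfg.grid_ny:
                edge_rows.append((nid, nid + 1))
    edges = pd.DataFrame(edge_rows, columns=["from", "to"])
    edges["length_mi"] = cfg.spacing_mi
    edges["speed_mph"] = rng.choice(cfg.speed_classes, size=len(edges), p=cfg.speed_weights)

    # hierarchy geometry: counties tile a (columns x rows) grid; the column
    # determines the urban-rural class (urban west -> rural east); tracts
    # slice each county cell horizontally; states group county columns.
    ncols = cfg.n_counties // cfg.county_rows
    county_w = ext_x / ncols
    county_h = ext_y / cfg.county_rows
    slab_h = county_h / cfg.tracts_per_county
    cols_per_state = math.ceil(ncols / cfg.n_states)

    county_ids, state_ids, county_cols, nchs_rows = [], [], [], []
    for c in range(cfg.n_counties):
        col, row = divmod(c, cfg.county_rows)
        state_id = f"{col // cols_per_state + 1:02d}"
        county_id = f"{state_id}{c + 1:03d}"
        county_ids.append(county_id)
        state_ids.append(state_id)
        county_cols.append(col)
        cls = _county_class(col, ncols)
        nchs_rows.append({"county_id": county_id, **_NCHS_TEMPLATES[cls]})
    nchs = pd.DataFrame(nchs_rows)

    # blocks: even split across counties, uniform position within a tract
    base = cfg.n_blocks // cfg.n_counties
    extra = cfg.n_blocks % cfg.n_counties
    block_rows = []
    tract_seq: dict[str, int] = {}
    for c in range(cfg.n_counties):
        col, row = divmod(c, cfg.county_rows)
        cls = _county_class(col, ncols)
        mult = cfg.class_pop_multipliers[cls - 1]
        n_here = base + (1 if c < extra else 0)
        for _ in range(n_here):
            t = int(rng.integers(cfg.tracts_per_county))
            x = (col + rng.random()) * county_w
            y = row * county_h + (t + rng.random()) * slab_h
            pop = float(rng.lognormal(cfg.pop_mu + math.log(mult), cfg.pop_sigma))
            if rng.random() < cfg.zero_pop_fraction:
                pop = 0.0
            tract_id = f"{county_ids[c]}{t + 1:06d}"
            k = tract_seq.get(tract_id, 0) + 1
            tract_seq[tract_id] = k
            block_rows.append(
                (f"{tract_id}{k:04d}", x, y, int(round(pop)), tract_id, county_ids[c], state_ids[c])
            )

    # isolated island blocks: far off-grid, beyond any snap radius
    for q in range(cfg.n_isolated_blocks):
        tract_id = f"{county_ids[-1]}{1:06d}"
        k = tract_seq.get(tract_id, 0) + 1
        tract_seq[tract_id] = k
        x = ext_x + cfg.island_offset_mi + rng.random() * 0.2
        y = ext_y / 2 + rng.random() * 0.2
        pop = int(round(rng.lognormal(cfg.pop_mu, cfg.pop_sigma)))
        block_rows.append(
            (f"{tract_id}{k:04d}", x, y, max(pop, 1), tract_id, county_ids[-1], state_ids[-1])
        )
    blocks = pd.DataFrame(
        block_rows, columns=["block_id", "lon", "lat", "pop", "tract_id", "county_id", "state_id"]
    ).sort_values("block_id", kind="stable").reset_index(drop=True)

    # outlets: clustered fraction near population, remainder uniform
    n_clustered = int(round(cfg.clustering * cfg.n_outlets))
    populated = blocks[blocks["pop"] > 0]
    outlet_xy = []
    if n_clustered and len(populated):
        w = populated["pop"].to_numpy(float)
        pick = rng.choice(len(populated), size=n_clustered, p=w / w.sum())
        ox = populated["lon"].to_numpy()[pick] + rng.normal(0, cfg.outlet_jitter_mi, n_clustered)
        oy = populated["lat"].to_numpy()[pick] + rng.normal(0, cfg.outlet_jitter_mi, n_clustered)
        outlet_xy.append(np.column_stack([np.clip(ox, 0, ext_x), np.clip(oy, 0, ext_y)]))
    n_uniform = cfg.n_outlets - (n_clustered if len(populated) else 0)
    if n_uniform:
        outlet_xy.append(np.column_stack([rng.random(n_uniform) * ext_x, rng.random(n_uniform) * ext_y]))
    xy = np.vstack(outlet_xy)
    outlets = pd.DataFrame(
        {
            "outlet_id": [f"O{i + 1:04d}" for i in range(cfg.n_outlets)],
            "lon": xy[:, 0],
            "lat": xy[:, 1],
            "weight": 1.0,
        }
    )

    region = Region(blocks, outlets, nodes, edges, nchs, cfg.mode, cfg)
    if cfg.mode == "geographic":
        region = _to_geographic(region)
    return region


_MILES_PER_DEGREE = 2 * math.pi * 3958.7613 / 360.0  # at the equator


def _to_geographic(region: Region) -> Region:
    """Re-express planar miles as equatorial degrees (uniform conversion)."""
    f = 1.0 / _MILES_PER_DEGREE
    blocks = region.blocks.assign(lon=region.blocks["lon"] * f, lat=region.blocks["lat"] * f)
    outlets = region.outlets.assign(lon=region.outlets["lon"] * f, lat=region.outlets["lat"] * f)
    nodes = region.nodes.assign(lon=region.nodes["lon"] * f, lat=region.nodes["lat"] * f)
    return replace(region, blocks=blocks, outlets=outlets, nodes=nodes, mode="geographic")


def perturb_scale(region: Region, c: float) -> Region:
    """Scale every coordinate and edge length (hence edge time) by c > 0.

    Planar geometry scales exactly; geographic coordinates are scaled about
    the origin and rejected if any leaves the valid lon/lat range (note the
    great-circle metric is not linear in degrees, so the exact-covariance
    properties are stated for planar mode only).
    """
    if not c > 0:
        raise ValidationError("scale factor must be > 0")
    blocks = region.blocks.assign(lon=region.blocks["lon"] * c, lat=region.blocks["lat"] * c)
    outlets = region.outlets.assign(lon=region.outlets["lon"] * c, lat=region.outlets["lat"] * c)
    nodes = region.nodes.assign(lon=region.nodes["lon"] * c, lat=region.nodes["lat"] * c)
    if region.mode == "geographic":
        if (nodes["lon"].abs().max() > 180 or nodes["lat"].abs().max() > 90
                or blocks["lon"].abs().max() > 180 or blocks["lat"].abs().max() > 90
                or outlets["lon"].abs().max() > 180 or outlets["lat"].abs().max() > 90):
            raise ValidationError("geographic scaling leaves valid lon/lat range")
    edges = region.edges.assign(length_mi=region.edges["length_mi"] * c)
    if "time_min" in edges.columns:
        edges["time_min"] = edges["time_min"] * c
    return replace(region, blocks=blocks, outlets=outlets, nodes=nodes, edges=edges)
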