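"""Straight-line distance engine and k-nearest-destination search.

"Euclidean" follows the field's loose usage for point-to-point (off-network)
distance: in geographic mode it is the great-circle (haversine) distance on a
mean-radius sphere, in planar mode the ordinary Euclidean distance in miles.
The haversine sphere deviates from ellipsoidal geodesics by well under 0.5%,
which is negligible relative to the network/straight-line contrast the
accessibility metrics are built to expose; the radius is configurable.

Exhaustive all-pairs search is the reference semantics for the k-nearest
query; the optional tile index is an optimization that provably returns the
same answer (it falls back to the exhaustive scan whenever the tile buffer
cannot certify the result).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EARTH_RADIUS_MILES, GeoPoint, NearestSet, ValidationError, check_mode

__all__ = ["geodesic_distance", "pairwise_distances", "euclidean_nearest_k"]


def _haversine(lon1, lat1, lon2, lat2, radius=EARTH_RADIUS_MILES):
    """Vectorized great-circle distance in the radius' units (default miles)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geodesic_distance(a: GeoPoint, b: GeoPoint, radius: float = EARTH_RADIUS_MILES) -> float:
    """Great-circle distance in miles between two validated lon/lat points."""
    a.validate("geographic")
    b.validate("geographic")
    return float(_haversine(a.lon, a.lat, b.lon, b.lat, radius))


def pairwise_distances(
    lon_a: np.ndarray,
    lat_a: np.ndarray,
    lon_b: np.ndarray,
    lat_b: np.ndarray,
    mode: str = "geographic",
    radius: float = EARTH_RADIUS_MILES,
) -> np.ndarray:
    """(len(a), len(b)) distance matrix in miles under the given mode."""
    check_mode(mode)
    la, pa = np.asarray(lon_a, float)[:, None], np.asarray(lat_a, float)[:, None]
    lb, pb = np.asarray(lon_b, float)[None, :], np.asarray(lat_b, float)[None, :]
    if mode == "planar":
        return np.hypot(la - lb, pa - pb)
    return _haversine(la, pa, lb, pb, radius)


def _topk_from_row(d_row: np.ndarray, outlet_ids: np.ndarray, k: int) -> list:
    # outlet_ids are pre-sorted ascending, so a stable argsort on distance
    # breaks ties by outlet id.
    order = np.argsort(d_row, kind="stable")[:k]
    return [(outlet_ids[j], float(d_row[j])) for j in order]


def euclidean_nearest_k(
    blocks: pd.DataFrame,
    outlets: pd.DataFrame,
    k: int,
    mode: str = "geographic",
    radius: float = EARTH_RADIUS_MILES,
    tile_size: float | None = None,
    tile_buffer: float | None = None,
) -> list[NearestSet]:
    """For each block, the k nearest outlets by straight-line distance.

    Parameters
    ----------
    blocks, outlets
        DataFrames with columns ``block_id``/``outlet_id``, ``lon``, ``lat``.
    k
        Choice-set size; each result holds ``min(k, len(outlets))`` pairs.
    tile_size, tile_buffer
        When both given, blocks are bucketed into square tiles of side
        ``tile_size`` (metric units) and only outlets within the tile's
        bounding box expanded by ``tile_buffer`` are scanned; any block whose
        k-th candidate distance exceeds the buffer is recomputed against all
        outlets, so the output is identical to the exhaustive search.

    Returns one :class:`NearestSet` (metric ``"euclidean"``) per block, in
    input block order; pairs sorted ascending by distance, ties broken by
    outlet id ascending.
    """
    check_mode(mode)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(outlets) == 0:
        raise ValidationError("outlet table is empty")
    if len(blocks) == 0:
        return []

    out = outlets.sort_values("outlet_id", kind="stable").reset_index(drop=True)
    oid = out["outlet_id"].to_numpy()
    olon, olat = out["lon"].to_numpy(float), out["lat"].to_numpy(float)
    blon, blat = blocks["lon"].to_numpy(float), blocks["lat"].to_numpy(float)
    bid = blocks["block_id"].to_numpy()

    if tile_size is None or tile_buffer is None:
        dmat = pairwise_distances(blon, blat, olon, olat, mode, radius)
        return [
            NearestSet(bid[i], "euclidean", _topk_from_row(dmat[i], oid, k))
            for i in range(len(bid))
        ]
    return _tiled_nearest_k(bid, blon, blat, oid, olon, olat, k, mode, radius, tile_size, tile_buffer)


def _tiled_nearest_k(bid, blon, blat, oid, olon, olat, k, mode, radius, tile, buf):
    if tile <= 0 or buf <= 0:
        raise ValidationError("tile_size and tile_buffer must be positive")
    results: dict[int, NearestSet] = {}
    tx = np.floor(blon / tile).astype(int)
    ty = np.floor(blat / tile).astype(int)
    keys = pd.DataFrame({"tx": tx, "ty": ty, "i": np.arange(len(bid))})
    for (gx, gy), grp in keys.groupby(["tx", "ty"]):
        x0, x1 = gx * tile - buf, (gx + 1) * tile + buf
        y0, y1 = gy * tile - buf, (gy + 1) * tile + buf
        cand = np.where((olon >= x0) & (olon <= x1) & (olat >= y0) & (olat <= y1))[0]
        idx = grp["i"].to_numpy()
        if cand.size:
            d = pairwise_distances(blon[idx], blat[idx], olon[cand], olat[cand], mode, radius)
        for row, i in enumerate(idx):
            ok = cand.size >= min(k, len(oid))
            if ok:
                pairs = _topk_from_row(d[row], oid[cand], k)
                ok = pairs[-1][1] <= buf or cand.size == len(oid)
            if not ok:  # buffer cannot certify: exhaustive fallback
                full = pairwise_distances(blon[i : i + 1], blat[i : i + 1], olon, olat, mode, radius)
                pairs = _topk_from_row(full[0], oid, k)
            results[i] = NearestSet(bid[i], "euclidean", pairs)
    return [results[i] for i in range(len(bid))]
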