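"""Street-network construction, point snapping, and network k-nearest search.

The network is an (by default undirected) graph whose edges carry a length in
miles and a travel time in minutes; when a speed column is supplied instead
of times, ``time_min = 60 * length_mi / speed_mph``.  Snapping is node-based:
each demand or destination point is assigned its nearest network node, or
excluded when no node lies within the maximum snap radius — exclusion is a
recorded outcome, not an error, mirroring how blocks with no street access
are dropped from network-based metrics but kept for straight-line ones.

The k-nearest-destination query runs a per-origin Dijkstra with early
termination: the search stops once k destinations are settled and the
frontier has passed the k-th destination's cost, so national-scale runs do
not need all-pairs shortest paths.  Exhaustive single-source shortest paths
followed by a top-k sort is the reference semantics.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import NearestSet, ValidationError, check_mode
from .geodist import pairwise_distances

__all__ = ["StreetNetwork", "build_network", "snap_points", "network_nearest_k"]

_INF = float("inf")


@dataclass
class StreetNetwork:
    """Validated street graph plus node coordinates and component labels."""

    graph: nx.Graph
    nodes: pd.DataFrame  # node_id, lon, lat
    mode: str = "geographic"
    directed: bool = False
    component: dict = field(default_factory=dict)  # node_id -> component label

    @property
    def n_components(self) -> int:
        return len(set(self.component.values()))

    def adjacency(self, weight: str) -> dict:
        """node -> list of (neighbor, weight) for the requested edge attribute."""
        adj: dict = {n: [] for n in self.graph.nodes}
        for u, v, data in self.graph.edges(data=True):
            w = data[weight]
            adj[u].append((v, w))
            if not self.directed:
                adj[v].append((u, w))
        return adj


def build_network(
    nodes: pd.DataFrame,
    edges: pd.DataFrame,
    mode: str = "geographic",
    directed: bool = False,
) -> StreetNetwork:
    """Validate node/edge tables and assemble a :class:`StreetNetwork`.

    ``nodes`` needs columns ``node_id, lon, lat``; ``edges`` needs
    ``from, to, length_mi`` and either ``speed_mph`` or ``time_min``.
    Per-edge travel time is derived from speed when no time column exists.
    Dangling endpoints and non-positive lengths/speeds/times raise a
    :class:`ValidationError` naming the offending row.
    """
    check_mode(mode)
    for col in ("node_id", "lon", "lat"):
        if col not in nodes.columns:
            raise ValidationError(f"node table missing column {col!r}")
    if nodes["node_id"].duplicated().any():
        dups = nodes.loc[nodes["node_id"].duplicated(), "node_id"].tolist()
        raise ValidationError(f"duplicate node ids: {dups[:5]}")
    for col in ("from", "to", "length_mi"):
        if col not in edges.columns:
            raise ValidationError(f"edge table missing column {col!r}")
    has_speed = "speed_mph" in edges.columns
    has_time = "time_min" in edges.columns
    if not (has_speed or has_time):
        raise ValidationError("edge table needs a speed_mph or time_min column")

    known = set(nodes["node_id"])
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["node_id"])
    for i, row in edges.iterrows():
        u, v = row["from"], row["to"]
        for endpoint in (u, v):
            if endpoint not in known:
                raise ValidationError(f"edge row {i}: endpoint node {endpoint!r} not in node table")
        length = float(row["length_mi"])
        if not length > 0:
            raise ValidationError(f"edge row {i} ({u!r}-{v!r}): non-positive length {length}")
        if has_time and not pd.isna(row.get("time_min", np.nan)):
            time = float(row["time_min"])
            if not time > 0:
                raise ValidationError(f"edge row {i} ({u!r}-{v!r}): non-positive time {time}")
        else:
            speed = float(row["speed_mph"])
            if not speed > 0:
                raise ValidationError(f"edge row {i} ({u!r}-{v!r}): non-positive speed {speed}")
            time = 60.0 * length / speed
        g.add_edge(u, v, length_mi=length, time_min=time)

    comps = nx.weakly_connected_components(g) if directed else nx.connected_components(g)
    component = {}
    for label, comp in enumerate(comps):
        for n in comp:
            component[n] = label
    return StreetNetwork(g, nodes.reset_index(drop=True), mode, directed, component)


def snap_points(
    net: StreetNetwork,
    points: pd.DataFrame,
    id_col: str,
    max_snap_miles: float = 1.0,
) -> pd.DataFrame:
    """Assign each point its nearest network node, or mark it excluded.

    Returns a DataFrame with columns ``[id_col, node_id, snap_dist_mi,
    excluded]``; ties at equal distance go to the lower node id.
    """
    if not max_snap_miles > 0:
        raise ValidationError("max_snap_miles must be > 0")
    nd = net.nodes.sort_values("node_id", kind="stable").reset_index(drop=True)
    nids = nd["node_id"].to_numpy()
    d = pairwise_distances(
        points["lon"].to_numpy(float), points["lat"].to_numpy(float),
        nd["lon"].to_numpy(float), nd["lat"].to_numpy(float), net.mode,
    )
    # stable argmin over id-sorted nodes implements the lower-id tie rule
    best = np.argmin(d, axis=1)
    dist = d[np.arange(len(points)), best]
    excluded = dist > max_snap_miles
    return pd.DataFrame(
        {
            id_col: points[id_col].to_numpy(),
            "node_id": np.where(excluded, None, nids[best]),
            "snap_dist_mi": dist,
            "excluded": excluded,
        }
    )


def _knearest_from_node(adj: dict, source, node_outlets: dict, k: int) -> list:
    """Early-termination Dijkstra: (distance, outlet_id) for k nearest outlets."""
    dist = {source: 0.0}
    settled: set = set()
    heap = [(0.0, 0, source)]  # (cost, tiebreak counter, node): ids need not compare
    counter = 1
    found: list = []
    kth = _INF
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in settled:
            continue
        if len(found) >= k and d > kth:
            break
        settled.add(u)
        for oid in node_outlets.get(u, ()):
            found.append((d, oid))
        if len(found) >= k:
            kth = sorted(d for d, _ in found)[k - 1]
        for v, w in adj.get(u, ()):
            nd = d + w
            if v not in settled and nd < dist.get(v, _INF):
                dist[v] = nd
                heapq.heappush(heap, (nd, counter, v))
                counter += 1
    found.sort(key=lambda t: (t[0], t[1]))
    return found[:k]


def network_nearest_k(
    net: StreetNetwork,
    origins: dict,
    destinations: dict,
    k: int,
    weight: str = "length_mi",
) -> list[NearestSet]:
    """Shortest-path cost from each origin to its k nearest destinations.

    Parameters
    ----------
    origins
        Mapping origin id -> snapped node id (ids with node ``None`` are
        skipped by the caller's bookkeeping and must not appear here).
    destinations
        Mapping destination (outlet) id -> snapped node id.
    weight
        ``"length_mi"`` for driving distance or ``"time_min"`` for driving
        time.

    Returns one :class:`NearestSet` per origin in ``origins`` iteration
    order; destinations unreachable from the origin's component are omitted
    (set size m < k), and an origin whose component holds no destination at
    all yields an empty set flagged ``reachable=False``.  Ties broken by
    destination id ascending.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if weight not in ("length_mi", "time_min"):
        raise ValidationError(f"unknown weight {weight!r}")
    metric = "drive_distance" if weight == "length_mi" else "drive_time"
    node_outlets: dict = {}
    comp_outlets: dict = {}
    for oid in sorted(destinations):
        node = destinations[oid]
        node_outlets.setdefault(node, []).append(oid)
        comp_outlets[net.component[node]] = True
    adj = net.adjacency(weight)
    cache: dict = {}
    results = []
    for origin_id, node in origins.items():
        if node not in cache:
            if not comp_outlets.get(net.component[node], False):
                cache[node] = None
            else:
                cache[node] = _knearest_from_node(adj, node, node_outlets, k)
        hit = cache[node]
        if hit is None:
            results.append(NearestSet(origin_id, metric, [], reachable=False))
        else:
            results.append(NearestSet(origin_id, metric, [(oid, d) for d, oid in hit]))
    return results
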