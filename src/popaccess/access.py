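"""Block-level gravity accessibility, Huff choice probabilities, and
population-weighted distance.

Given a block's choice set of the n nearest destinations with distances
d_ij (miles or minutes), the metrics are

* gravity accessibility index  ``A_i = sum_j w_j / d_ij^beta``
* Huff choice probability      ``P_ij = (w_j / d_ij^beta) / A_i``
* population-weighted distance ``PWD_i = sum_j P_ij * d_ij``

with distance-decay exponent ``beta`` (default 1) and unit destination
weights ``w_j`` by default.  For beta = 1 and unit weights, PWD_i is the
harmonic mean of the choice-set distances, so ``PWD_i * A_i = m`` exactly
(m = choice-set size) — an identity the tests enforce.

A destination coincident with a block centroid would make A_i infinite, so
all distances are floored at a small epsilon (default 0.01 metric units)
before any formula is applied; floor events are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NearestSet, ValidationError

__all__ = [
    "DecayConfig",
    "accessibility_index",
    "choice_probabilities",
    "population_weighted_distance",
    "block_metrics",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecayConfig:
    """Gravity-model knobs: decay exponent, choice-set size, distance floor.

    beta : distance-decay exponent (> 0); 1 gives inverse-distance decay
        and the harmonic-mean identity.
    n : choice-set size — how many nearest destinations form each block's
        set of realistic alternatives (7 by default).
    epsilon : zero-distance floor in metric units (miles or minutes);
        applied before every formula.
    """

    beta: float = 1.0
    n: int = 7
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValidationError("beta must be > 0")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not self.epsilon > 0:
            raise ValidationError("epsilon must be > 0")


def _floored(ns: NearestSet, cfg: DecayConfig) -> np.ndarray:
    d = ns.distances
    n_floor = int(np.sum(d < cfg.epsilon))
    if n_floor:
        log.debug("floored %d distance(s) at epsilon=%g for origin %r", n_floor, cfg.epsilon, ns.origin_id)
    return np.maximum(d, cfg.epsilon)


def _weights(ns: NearestSet, weights) -> np.ndarray:
    if weights is None:
        return np.ones(ns.m)
    w = np.asarray([weights.get(oid, 1.0) for oid in ns.outlet_ids], dtype=float)
    if np.any(w <= 0):
        raise ValidationError("destination weights must be positive")
    return w


def accessibility_index(ns: NearestSet, cfg: DecayConfig = DecayConfig(), weights=None) -> float:
    """Gravity index A_i = sum_j w_j / d_ij^beta; NaN for an empty choice set."""
    if ns.m == 0:
        return float("nan")
    d = _floored(ns, cfg)
    return float(np.sum(_weights(ns, weights) * d ** (-cfg.beta)))


def choice_probabilities(ns: NearestSet, cfg: DecayConfig = DecayConfig(), weights=None) -> np.ndarray:
    """Huff probabilities P_ij, summing to 1, non-increasing in distance."""
    if ns.m == 0:
        raise ValidationError(f"empty choice set for origin {ns.origin_id!r}")
    d = _floored(ns, cfg)
    a = _weights(ns, weights) * d ** (-cfg.beta)
    return a / a.sum()


def population_weighted_distance(ns: NearestSet, cfg: DecayConfig = DecayConfig(), weights=None) -> float:
    """Expected travel cost PWD_i = sum_j P_ij * d_ij; NaN for an empty set."""
    if ns.m == 0:
        return float("nan")
    d = _floored(ns, cfg)
    return float(np.sum(choice_probabilities(ns, cfg, weights) * d))


def block_metrics(
    blocks: pd.DataFrame,
    nearest_sets: dict[str, list[NearestSet]],
    cfg: DecayConfig = DecayConfig(),
    weights=None,
    excluded: dict[str, set] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join per-block choice sets with populations into a long metrics table.

    Parameters
    ----------
    blocks
        DataFrame with ``block_id`` and ``pop``; zero-population blocks are
        dropped (and counted) before any metric is attached.
    nearest_sets
        metric kind -> list of NearestSet for every included, non-excluded
        block under that metric.
    excluded
        metric kind -> set of block ids excluded for that metric (e.g. no
        street access); they appear in the output flagged, with NaN metrics.

    Returns
    -------
    (table, counts) where table has one row per block x metric with columns
    ``block_id, metric, m, A, PWD, pop, excluded`` and counts records the
    bookkeeping (blocks read, zero-population dropped, exclusions and
    short choice sets per metric).
    """
    excluded = excluded or {}
    pop = blocks.set_index("block_id")["pop"]
    populated = pop[pop > 0]
    counts = {
        "blocks_read": int(len(pop)),
        "zero_pop_dropped": int((pop <= 0).sum()),
        "excluded": {},
        "short_choice_sets": {},
    }
    if counts["zero_pop_dropped"]:
        log.info("dropped %d zero-population block(s)", counts["zero_pop_dropped"])

    rows = []
    for metric, sets in nearest_sets.items():
        excl = set(excluded.get(metric, set()))
        seen = set()
        short = 0
        for ns in sets:
            if ns.origin_id not in populated.index:
                continue
            seen.add(ns.origin_id)
            a = accessibility_index(ns, cfg, weights)
            pwd = population_weighted_distance(ns, cfg, weights)
            if 0 < ns.m < cfg.n:
                short += 1
            rows.append((ns.origin_id, metric, ns.m, a, pwd, int(populated[ns.origin_id]), False))
        for bid in excl:
            if bid in populated.index and bid not in seen:
                rows.append((bid, metric, 0, np.nan, np.nan, int(populated[bid]), True))
                seen.add(bid)
        missing = set(populated.index) - seen
        if missing:
            raise ValidationError(
                f"blocks missing from both nearest sets and exclusions for {metric!r}: "
                f"{sorted(missing)[:5]}"
            )
        counts["excluded"][metric] = len(excl & set(populated.index))
        counts["short_choice_sets"][metric] = short
    table = pd.DataFrame(rows, columns=["block_id", "metric", "m", "A", "PWD", "pop", "excluded"])
    return table, counts
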