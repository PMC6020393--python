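"""Shared domain types: points, choice sets, coordinate modes, errors.

Coordinates come in two modes:

* ``"geographic"`` — lon/lat in decimal degrees; distances are great-circle
  miles on a mean-radius sphere.
* ``"planar"`` — lon/lat are interpreted directly as miles on a flat plane;
  distances are ordinary Euclidean miles.

Planar mode is what the synthetic generator emits by default: the metric
algebra (gravity index, Huff probabilities, population weighting) is
indifferent to curvature, and a flat plane makes exact scaling arguments
possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Mean Earth radius in miles used for all great-circle distances.
EARTH_RADIUS_MILES = 3958.7613

#: Metric kinds a choice set can carry.
METRICS = ("euclidean", "drive_distance", "drive_time")

MODES = ("geographic", "planar")


class ValidationError(ValueError):
    """Raised when an input table, point or configuration fails validation."""


@dataclass(frozen=True)
class GeoPoint:
    """A point location: lon/lat degrees (geographic) or x/y miles (planar)."""

    lon: float
    lat: float

    def validate(self, mode: str = "geographic") -> "GeoPoint":
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValidationError(f"non-finite coordinates ({self.lon}, {self.lat})")
        if mode == "geographic":
            if not -180.0 <= self.lon <= 180.0:
                raise ValidationError(f"longitude {self.lon} outside [-180, 180]")
            if not -90.0 <= self.lat <= 90.0:
                raise ValidationError(f"latitude {self.lat} outside [-90, 90]")
        return self


@dataclass
class NearestSet:
    """One origin's ordered choice set of (destination id, distance) pairs.

    ``metric`` is one of :data:`METRICS`; distances are miles for
    ``euclidean`` / ``drive_distance`` and minutes for ``drive_time``.
    Pairs are sorted ascending by distance, ties broken by destination id,
    destination ids distinct.  ``reachable`` is False when the origin sits in
    a network component containing no destination at all.
    """

    origin_id: object
    metric: str
    pairs: list = field(default_factory=list)
    reachable: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        ids = [oid for oid, _ in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate destination ids in choice set for {self.origin_id!r}")
        d = self.distances
        if d.size and (np.any(d < 0) or np.any(np.diff(d) < 0)):
            raise ValidationError(f"choice set for {self.origin_id!r} not sorted/non-negative")

    @property
    def m(self) -> int:
        return len(self.pairs)

    @property
    def distances(self) -> np.ndarray:
        return np.asarray([d for _, d in self.pairs], dtype=float)

    @property
    def outlet_ids(self) -> list:
        return [oid for oid, _ in self.pairs]


def check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValidationError(f"unknown coordinate mode {mode!r}; expected one of {MODES}")
    return mode
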