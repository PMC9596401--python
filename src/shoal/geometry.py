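"""Pond geometry and trial schedules.

A trial takes place in an earthen pond (a polygon in meters, by default a
40 m x 25 m rectangle) containing five candidate shade-square positions
labelled 'a'..'e'.  Exactly one square is shaded (covered by a floating
platform) in a given trial; across consecutive trials the platform rotates
through the labels.  The schedule records the day intervals (civil
sunrise/sunset) of the trial clock, in seconds from trial start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon, box

__all__ = ["PondGeometry", "TrialSchedule", "SHADE_LABELS"]

SHADE_LABELS = ("a", "b", "c", "d", "e")


def _as_polygon(obj) -> Polygon:
    if isinstance(obj, Polygon):
        return obj
    return Polygon(obj)


@dataclass(frozen=True)
class PondGeometry:
    """Pond boundary plus the candidate shade squares and the active one."""

    boundary: Polygon
    shade_squares: Mapping[str, Polygon]
    active_shade: str

    def __post_init__(self):
        object.__setattr__(self, "boundary", _as_polygon(self.boundary))
        object.__setattr__(
            self,
            "shade_squares",
            {k: _as_polygon(v) for k, v in self.shade_squares.items()},
        )
        if self.boundary.area <= 0:
            raise ValueError("pond boundary polygon is degenerate")
        if self.active_shade not in self.shade_squares:
            raise ValueError(
                f"active shade {self.active_shade!r} not among "
                f"{sorted(self.shade_squares)}"
            )
        for label, square in self.shade_squares.items():
            if square.area <= 0:
                raise ValueError(f"shade square {label!r} is degenerate")
            if not self.boundary.covers(square):
                raise ValueError(f"shade square {label!r} lies outside the pond")

    @property
    def shade(self) -> Polygon:
        """Polygon of the currently shaded square."""
        return self.shade_squares[self.active_shade]

    def with_active(self, label: str) -> "PondGeometry":
        """Same pond with a different active shade square."""
        return PondGeometry(self.boundary, dict(self.shade_squares), label)

    def inside_pond(self, x, y) -> np.ndarray:
        """Boundary-inclusive pond membership test (vectorized)."""
        return shapely.intersects_xy(self.boundary, x, y)

    def under_shade(self, x, y, label: str | None = None) -> np.ndarray:
        """Boundary-inclusive membership in a shade square (default: active)."""
        square = self.shade_squares[label or self.active_shade]
        return shapely.intersects_xy(square, x, y)

    def shade_area_fraction(self, label: str | None = None) -> float:
        """area(shade square intersected with pond) / area(pond)."""
        square = self.shade_squares[label or self.active_shade]
        return square.intersection(self.boundary).area / self.boundary.area

    @classmethod
    def default_pond(cls, active_shade: str = "a") -> "PondGeometry":
        """40 m x 25 m rectangular pond with five 5 m x 5 m shade squares."""
        squares = {
            "a": box(5.0, 3.0, 10.0, 8.0),
            "b": box(30.0, 3.0, 35.0, 8.0),
            "c": box(17.5, 10.0, 22.5, 15.0),
            "d": box(5.0, 17.0, 10.0, 22.0),
            "e": box(30.0, 17.0, 35.0, 22.0),
        }
        return cls(box(0.0, 0.0, 40.0, 25.0), squares, active_shade)

    @classmethod
    def from_dict(cls, d: dict) -> "PondGeometry":
        return cls(
            boundary=Polygon(d["boundary"]),
            shade_squares={k: Polygon(v) for k, v in d["shade_squares"].items()},
            active_shade=d["active_shade"],
        )

    @classmethod
    def from_yaml(cls, path) -> "PondGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "boundary": [list(p) for p in self.boundary.exterior.coords[:-1]],
            "shade_squares": {
                k: [list(p) for p in v.exterior.coords[:-1]]
                for k, v in self.shade_squares.items()
            },
            "active_shade": self.active_shade,
        }


@dataclass(frozen=True)
class TrialSchedule:
    """Day intervals and shade rotation for one trial of one pond.

    ``trial_id`` is the 1-based position of the trial in ``shade_rotation``;
    the labels immediately before/after it are used by the shifted-shade
    control analysis.  Times are seconds from trial start.
    """

    trial_id: int
    pond_id: int
    day_intervals: tuple
    shade_rotation: tuple

    def __post_init__(self):
        iv = tuple((float(a), float(b)) for a, b in self.day_intervals)
        object.__setattr__(self, "day_intervals", iv)
        object.__setattr__(self, "shade_rotation", tuple(self.shade_rotation))
        for a, b in iv:
            if b <= a:
                raise ValueError(f"empty day interval ({a}, {b})")
        starts = [a for a, _ in iv]
        if sorted(starts) != starts:
            raise ValueError("day intervals must be sorted")
        for (_, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("day intervals overlap")
        if self.shade_rotation and not (1 <= self.trial_id <= len(self.shade_rotation)):
            raise ValueError("trial_id does not index the shade rotation")

    @property
    def active_label(self) -> str:
        return self.shade_rotation[self.trial_id - 1]

    def neighbor_labels(self) -> dict:
        """Shade labels of the previous/next trial (None at the ends)."""
        i = self.trial_id - 1
        prev_label = self.shade_rotation[i - 1] if i > 0 else None
        next_label = self.shade_rotation[i + 1] if i + 1 < len(self.shade_rotation) else None
        return {"previous": prev_label, "next": next_label}

    def is_day(self, t) -> np.ndarray:
        """Whether each time (s from trial start) falls in a day interval."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for a, b in self.day_intervals:
            out |= (t >= a) & (t < b)
        return out if out.shape else bool(out)

    @classmethod
    def regular(
        cls,
        trial_length: float,
        sunrise: float = 6 * 3600.0,
        sunset: float = 18 * 3600.0,
        trial_id: int = 1,
        pond_id: int = 1,
        shade_rotation: Sequence[str] = SHADE_LABELS,
    ) -> "TrialSchedule":
        """Daily sunrise/sunset intervals clipped to the trial span."""
        intervals = []
        day = 0
        while day * 86400.0 < trial_length:
            a = day * 86400.0 + sunrise
            b = day * 86400.0 + sunset
            if a < trial_length:
                intervals.append((a, min(b, trial_length)))
            day += 1
        return cls(trial_id, pond_id, tuple(intervals), tuple(shade_rotation))

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSchedule":
        return cls(
            trial_id=int(d["trial_id"]),
            pond_id=int(d.get("pond_id", 1)),
            day_intervals=tuple(tuple(iv) for iv in d["day_intervals"]),
            shade_rotation=tuple(d.get("shade_rotation", SHADE_LABELS)),
        )

    @classmethod
    def from_yaml(cls, path) -> "TrialSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
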