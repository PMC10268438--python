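"""Assembly of 24-hour time-use compositions.

A day is split into four behaviours — sleep, sedentary behaviour (SB), light
physical activity (LPA) and moderate-to-vigorous physical activity (MVPA).
Sleep comes from a self-reported bedtime/wake-time pair; the waking behaviours
come from accelerometry. Because devices are removed for sleep and water
activities, the raw parts rarely sum to 24 h; the unaccounted time is
redistributed proportionally over all four behaviours by closing the vector to
24 h/day (linear adjustment). The closed 4-part vector is a composition: only
the relative information in it is meaningful, which is why downstream analysis
works in isometric log-ratio coordinates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PARTS",
    "Composition",
    "SleepReport",
    "sleep_duration",
    "replace_zeros",
    "build_composition",
]

#: Canonical part order: sleep, sedentary behaviour, light PA, moderate-to-vigorous PA.
PARTS: tuple[str, ...] = ("sleep", "sb", "lpa", "mvpa")

# Internal storage grid.  Part durations are kept as minutes shifted into the
# [2048, 4096) binade, where every float shares the same ulp (2**-41 min).  On
# this fixed absolute grid, adding or subtracting any duration that is itself a
# multiple of the grid (all practical minute values, in particular 10/30/60) is
# exact, which makes one-to-one time reallocations exactly reversible.  The
# one-off quantisation on construction is ~4.5e-13 min and invisible at every
# tolerance used in this package.
_ANCHOR = 2048.0
GRID_RESOLUTION_MIN = 2.0 ** -41


def _anchor_minutes(minutes: float) -> float:
    g = minutes + _ANCHOR
    if not (_ANCHOR < g < 2.0 * _ANCHOR):
        raise ValueError(f"part duration {minutes} min outside (0, 2048) min")
    return g


@dataclass(frozen=True, eq=True)
class Composition:
    """A 4-part time-use composition closed to a fixed daily total.

    Parts are stored internally on a fixed-resolution minute grid so that
    reallocation arithmetic is exact; the public accessors return hours.
    Construct with :meth:`from_hours` or :meth:`from_array`.
    """

    _grid: tuple[float, float, float, float]
    total_h: float = 24.0

    def __post_init__(self) -> None:
        hours = self.as_array()
        if np.any(hours <= 0.0):
            raise ValueError(f"all parts must be strictly positive, got {hours}")
        if abs(float(hours.sum()) - self.total_h) > 1e-9 * max(1.0, self.total_h):
            raise ValueError(
                f"parts sum to {hours.sum():.12f} h, expected {self.total_h} h"
            )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_hours(
        cls,
        sleep_h: float,
        sb_h: float,
        lpa_h: float,
        mvpa_h: float,
        total_h: float = 24.0,
    ) -> "Composition":
        grid = tuple(_anchor_minutes(h * 60.0) for h in (sleep_h, sb_h, lpa_h, mvpa_h))
        return cls(grid, total_h)

    @classmethod
    def from_array(
        cls,
        values_h: np.ndarray,
        part_order: tuple[str, ...] = PARTS,
        total_h: float = 24.0,
    ) -> "Composition":
        """Build from an array of hours given in ``part_order``."""
        values_h = np.asarray(values_h, dtype=float)
        if values_h.shape != (len(PARTS),):
            raise ValueError(f"expected {len(PARTS)} parts, got shape {values_h.shape}")
        named = dict(zip(part_order, values_h))
        return cls.from_hours(
            named["sleep"], named["sb"], named["lpa"], named["mvpa"], total_h
        )

    # -- accessors ---------------------------------------------------------
    def as_array(self, part_order: tuple[str, ...] = PARTS) -> np.ndarray:
        """Part durations in hours, ordered by ``part_order``."""
        by_name = dict(zip(PARTS, self._grid))
        return np.array([(by_name[p] - _ANCHOR) / 60.0 for p in part_order])

    def part_h(self, part: str) -> float:
        return (self._grid[PARTS.index(part)] - _ANCHOR) / 60.0

    def part_min(self, part: str) -> float:
        return self._grid[PARTS.index(part)] - _ANCHOR

    @property
    def sleep_h(self) -> float:
        return self.part_h("sleep")

    @property
    def sb_h(self) -> float:
        return self.part_h("sb")

    @property
    def lpa_h(self) -> float:
        return self.part_h("lpa")

    @property
    def mvpa_h(self) -> float:
        return self.part_h("mvpa")

    def _shift_grid(self, deltas_min: dict[str, float]) -> "Composition":
        """Internal: apply exact minute shifts to named parts on the grid."""
        grid = list(self._grid)
        for part, d in deltas_min.items():
            grid[PARTS.index(part)] += d
        return Composition(tuple(grid), self.total_h)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        vals = ", ".join(f"{p}={v:.4f}" for p, v in zip(PARTS, self.as_array()))
        return f"Composition({vals} h, total={self.total_h})"


@dataclass(frozen=True)
class SleepReport:
    """Self-reported bedtime and wake time (clock times, no dates)."""

    bedtime: dt.time
    waketime: dt.time


def sleep_duration(report: SleepReport) -> float:
    """Sleep duration in hours from a bedtime/wake-time pair.

    When the wake time is at or before the bedtime on the clock, the interval
    wraps midnight. Equal times are ambiguous (0 or 24 h) and rejected.
    """
    bed = report.bedtime.hour * 60 + report.bedtime.minute + report.bedtime.second / 60
    wake = (
        report.waketime.hour * 60
        + report.waketime.minute
        + report.waketime.second / 60
    )
    if bed == wake:
        raise ValueError("bedtime equals wake time: duration is ambiguous (0 or 24 h)")
    minutes = wake - bed if wake > bed else wake - bed + 24 * 60
    return minutes / 60.0


def replace_zeros(raw_parts: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Replace zero parts by ``delta`` (same units as the input), preserving the total.

    Log-ratio coordinates require strictly positive parts. Zero parts are set
    to ``delta`` and the positive parts are multiplicatively shrunk so the raw
    total is unchanged.
    """
    raw = np.asarray(raw_parts, dtype=float)
    if np.any(raw < 0):
        raise ValueError("parts must be non-negative")
    zero = raw == 0.0
    if not zero.any():
        return raw.copy()
    if zero.all():
        raise ValueError("all parts are zero")
    total = raw.sum()
    n_zero = int(zero.sum())
    if n_zero * delta >= total:
        raise ValueError("replacement delta too large for the raw total")
    out = raw * (total - n_zero * delta) / total
    out[zero] = delta
    return out


def build_composition(
    sleep_h: float,
    sb_min: float,
    lpa_min: float,
    mvpa_min: float,
    total_h: float = 24.0,
    zero_delta_min: float = 1.0,
) -> Composition:
    """Close raw behaviour durations to a 24-h day.

    Raw parts (sleep in hours, waking behaviours in minutes/day) are converted
    to minutes, zeros replaced, and every part scaled by ``total / raw_sum`` so
    the output sums to ``total_h``. The proportional scaling redistributes
    unaccounted (or double-counted) time over all four behaviours.
    """
    raw_min = np.array([sleep_h * 60.0, sb_min, lpa_min, mvpa_min], dtype=float)
    if np.any(raw_min < 0):
        raise ValueError(f"raw parts must be non-negative, got {raw_min}")
    raw_min = replace_zeros(raw_min, delta=zero_delta_min)
    s = raw_min.sum()
    if s <= 0:
        raise ValueError("raw parts sum to zero")
    closed_h = raw_min * (total_h / s)  # minutes scaled so the sum is total_h hours
    return Composition.from_array(closed_h, PARTS, total_h)
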