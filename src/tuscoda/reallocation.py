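"""One-to-one time reallocations between behaviours.

An isotemporal substitution asks what happens when a fixed number of minutes
per day moves from one behaviour to another while the remaining behaviours are
held constant. Geometrically this is a straight-line move in raw time units:
the source part decreases and the target part increases by exactly the
reallocated duration, so the 24-h total is preserved by construction and no
re-closure is applied. Infeasible moves (the source part would be exhausted)
are errors, not clamped, so the estimand is never silently changed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .timeuse import PARTS, Composition

__all__ = ["Reallocation", "reallocate", "substitution_grid", "DEFAULT_DURATIONS"]

logger = logging.getLogger(__name__)

DEFAULT_DURATIONS: tuple[float, ...] = (10.0, 30.0, 60.0)


@dataclass(frozen=True)
class Reallocation:
    """A transfer of ``minutes`` per day from ``from_part`` to ``to_part``."""

    from_part: str
    to_part: str
    minutes: float

    def __post_init__(self) -> None:
        if self.from_part not in PARTS or self.to_part not in PARTS:
            raise ValueError(f"parts must be among {PARTS}")
        if self.from_part == self.to_part:
            raise ValueError("source and target behaviours must differ")
        if not (0.0 < self.minutes < 24 * 60):
            raise ValueError("minutes must lie in (0, 1440)")


def reallocate(base: Composition, r: Reallocation) -> Composition:
    """Move ``r.minutes`` from ``r.from_part`` to ``r.to_part``.

    The two moved parts change by exactly the reallocated minutes on the
    composition's internal fixed-resolution grid; the untouched parts are
    bit-identical and the move is exactly reversible.
    """
    if base.part_min(r.from_part) <= r.minutes:
        raise ValueError(
            f"cannot move {r.minutes} min out of {r.from_part} "
            f"({base.part_min(r.from_part):.2f} min available)"
        )
    return base._shift_grid({r.from_part: -r.minutes, r.to_part: +r.minutes})


def substitution_grid(
    base: Composition, durations: tuple[float, ...] = DEFAULT_DURATIONS
) -> list[tuple[Reallocation, Composition]]:
    """All ordered behaviour pairs x durations, skipping infeasible cells.

    Returns (reallocation, reallocated composition) pairs; combinations that
    would exhaust the source behaviour are skipped with a logged warning.
    """
    out: list[tuple[Reallocation, Composition]] = []
    for minutes in durations:
        for from_part, to_part in itertools.permutations(PARTS, 2):
            r = Reallocation(from_part, to_part, minutes)
            try:
                out.append((r, reallocate(base, r)))
            except ValueError:
                logger.warning(
                    "skipping infeasible reallocation %s->%s of %g min "
                    "(only %.2f min of %s available)",
                    from_part,
                    to_part,
                    minutes,
                    base.part_min(from_part),
                    from_part,
                )
    return out
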