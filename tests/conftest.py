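"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from tuscoda.accelerometry import EpochSeries
from tuscoda.timeuse import Composition

#: Printed descriptive centres used as worked-example inputs throughout.
TABLE_BASELINE_H = (9.13, 10.89, 2.93, 1.05)
TABLE_FOLLOWUP_H = (8.92, 11.65, 2.48, 0.95)

A_FRIDAY = dt.datetime(2011, 10, 7, 0, 0)


@pytest.fixture
def baseline_centre() -> Composition:
    return Composition.from_hours(*TABLE_BASELINE_H)


@pytest.fixture
def followup_centre() -> Composition:
    return Composition.from_hours(*TABLE_FOLLOWUP_H)


def oracle_nonwear(
    series: EpochSeries, window: int = 60, allow: int = 2, cpm: int = 100
) -> np.ndarray:
    """Brute-force non-wear oracle: for every start minute, greedily extend the
    longest window satisfying the zero/allowance rule and union all windows of
    length >= ``window``. Independent of the rolling-sum implementation."""
    epm = 60 // series.epoch_s
    n_min = series.n_epochs // epm
    totals = series.counts[: n_min * epm].reshape(n_min, epm).sum(axis=1)
    nonwear = np.zeros(n_min, dtype=bool)
    for a in range(n_min):
        nz = 0
        end = a - 1
        for j in range(a, n_min):
            if totals[j] >= cpm:
                break
            if totals[j] > 0:
                nz += 1
                if nz > allow:
                    break
            end = j
        if end - a + 1 >= window:
            nonwear[a : end + 1] = True
    wear = np.ones(series.n_epochs, dtype=bool)
    wear[: n_min * epm] = ~np.repeat(nonwear, epm)
    return wear


def random_count_series(
    rng: np.random.Generator, epoch_s: int, max_minutes: int = 1440
) -> EpochSeries:
    """Random day-like series mixing zero runs, low-count and active stretches,
    with a random trailing partial minute."""
    n_min = int(rng.integers(90, max_minutes + 1))
    mins: list[int] = []
    while len(mins) < n_min:
        kind = rng.choice(["zero", "low", "active"], p=[0.35, 0.25, 0.4])
        length = int(rng.integers(1, 200))
        if kind == "zero":
            mins += [0] * length
        elif kind == "low":
            mins += [int(v) for v in rng.integers(1, 100, length)]
        else:
            mins += [int(v) for v in rng.integers(100, 3000, length)]
    totals = np.array(mins[:n_min], dtype=np.int64)
    epm = 60 // epoch_s
    if epm == 1:
        counts = totals
    else:
        counts = np.zeros(n_min * epm, dtype=np.int64)
        counts[::epm] = totals  # whole minute total on the first epoch
    tail = rng.integers(0, 50, int(rng.integers(0, epm)))
    counts = np.concatenate([counts, tail])
    return EpochSeries("R", "baseline", A_FRIDAY, epoch_s, counts)
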