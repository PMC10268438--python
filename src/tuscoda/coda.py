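"""Compositional geometry on the simplex: pivot ilr coordinates and descriptives.

A D-part composition carries only relative information; isometric log-ratio
(ilr) coordinates map it isometrically to R^(D-1) where ordinary multivariate
statistics apply. The *pivot* ilr construction is used throughout: under a part
order (x_1, ..., x_D) the j-th coordinate is

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gm(x_{j+1}, ..., x_D) ),

so the first coordinate carries all relative information about the first part
against the rest. Rotating a chosen behaviour to the front of the order yields
"its" first pivot coordinate, the quantity used for paired descriptive tests.

Cohort-level compositions are summarised by the compositional centre: part-wise
geometric means across participants, re-scaled (closed) to 24 h/day.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .timeuse import PARTS, Composition

__all__ = [
    "psi_matrix",
    "pivot_ilr_array",
    "inverse_pivot_ilr_array",
    "pivot_ilr",
    "inverse_pivot_ilr",
    "aitchison_distance",
    "closure",
    "mean_composition",
    "rescaled_geomean_ci",
    "first_pivot_coordinates",
    "paired_pivot_ttest",
    "PairedTestResult",
]


def closure(x: np.ndarray, total: float = 24.0) -> np.ndarray:
    """Scale positive parts (last axis) so they sum to ``total``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("closure requires strictly positive parts")
    return x * (total / x.sum(axis=-1, keepdims=True))


@lru_cache(maxsize=None)
def psi_matrix(n_parts: int) -> np.ndarray:
    """Orthonormal (D-1) x D contrast matrix of the pivot ilr basis.

    Row j (0-based) has sqrt((D-j-1)/(D-j)) at position j and the balancing
    negative weight spread over positions j+1..D-1. ``z = Psi @ ln(x)``.
    """
    d = n_parts
    psi = np.zeros((d - 1, d))
    for j in range(d - 1):
        a = np.sqrt((d - j - 1) / (d - j))
        psi[j, j] = a
        psi[j, j + 1 :] = -a / (d - j - 1)
    return psi


def pivot_ilr_array(x: np.ndarray) -> np.ndarray:
    """Pivot ilr coordinates of composition(s) given as positive parts on the last axis."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("pivot ilr requires strictly positive parts")
    return np.log(x) @ psi_matrix(x.shape[-1]).T


def inverse_pivot_ilr_array(z: np.ndarray, total: float = 24.0) -> np.ndarray:
    """Inverse of :func:`pivot_ilr_array`, closed to ``total``."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("ilr coordinates must be finite")
    d = z.shape[-1] + 1
    return closure(np.exp(z @ psi_matrix(d)), total)


def pivot_ilr(comp: Composition, part_order: tuple[str, ...] = PARTS) -> np.ndarray:
    """Pivot ilr coordinates (length D-1) of one composition under ``part_order``."""
    return pivot_ilr_array(comp.as_array(part_order))


def inverse_pivot_ilr(
    z: np.ndarray, part_order: tuple[str, ...] = PARTS, total: float = 24.0
) -> Composition:
    """Composition whose pivot ilr coordinates under ``part_order`` equal ``z``."""
    return Composition.from_array(inverse_pivot_ilr_array(z, total), part_order, total)


def aitchison_distance(a: Composition, b: Composition) -> float:
    """Aitchison distance = Euclidean distance between ilr images."""
    return float(np.linalg.norm(pivot_ilr(a) - pivot_ilr(b)))


def _cohort_array(cohort: Sequence[Composition] | np.ndarray) -> np.ndarray:
    if isinstance(cohort, np.ndarray):
        arr = np.asarray(cohort, dtype=float)
    else:
        arr = np.array([c.as_array() for c in cohort], dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("cohort must be a non-empty n x D array of compositions")
    if np.any(arr <= 0):
        raise ValueError("cohort compositions must be strictly positive")
    return arr


def mean_composition(
    cohort: Sequence[Composition] | np.ndarray, total: float = 24.0
) -> Composition:
    """Compositional centre: part-wise geometric means, closed to ``total``.

    Equals the inverse ilr of the arithmetic mean of the cohort's ilr vectors.
    """
    arr = _cohort_array(cohort)
    gm = np.exp(np.log(arr).mean(axis=0))
    return Composition.from_array(closure(gm, total))


def rescaled_geomean_ci(
    cohort: Sequence[Composition] | np.ndarray,
    part: str,
    level: float = 0.95,
    total: float = 24.0,
) -> tuple[float, float]:
    """Confidence interval for one part of the re-scaled geometric-mean composition.

    A t interval for the mean of ln(part) across participants is exponentiated
    and multiplied by the same closure factor that re-scales the point
    estimate, so the interval sits on the 24 h/day scale of the centre.
    """
    arr = _cohort_array(cohort)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants for a confidence interval")
    logs = np.log(arr)
    gm = np.exp(logs.mean(axis=0))
    k = total / gm.sum()  # closure factor of the point estimate
    j = PARTS.index(part)
    s = logs[:, j].std(ddof=1)
    if s == 0.0:
        point = gm[j] * k
        return (point, point)
    half = stats.t.ppf((1 + level) / 2, n - 1) * s / np.sqrt(n)
    m = logs[:, j].mean()
    return (float(np.exp(m - half) * k), float(np.exp(m + half) * k))


def first_pivot_coordinates(
    cohort: Sequence[Composition] | np.ndarray, part: str
) -> np.ndarray:
    """First pivot coordinate of each composition with ``part`` rotated to front."""
    arr = _cohort_array(cohort)
    j = PARTS.index(part)
    order = [j] + [i for i in range(len(PARTS)) if i != j]
    d = len(PARTS)
    x = arr[:, order]
    return np.sqrt((d - 1) / d) * (np.log(x[:, 0]) - np.log(x[:, 1:]).mean(axis=1))


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    p_value: float
    mean_diff: float
    zero_variance: bool = False


def paired_pivot_ttest(
    baseline: Sequence[Composition] | np.ndarray,
    followup: Sequence[Composition] | np.ndarray,
    part: str,
) -> PairedTestResult:
    """Paired t-test on first pivot coordinates of one behaviour across waves.

    For each participant the first pivot coordinate with ``part`` pivoted to
    the front is computed at both waves; a two-sided paired t-test is run on
    the follow-up minus baseline differences. Zero-variance differences are
    degenerate and flagged rather than producing an undefined statistic.
    """
    zb = first_pivot_coordinates(baseline, part)
    zf = first_pivot_coordinates(followup, part)
    if zb.shape != zf.shape:
        raise ValueError("baseline and follow-up cohorts differ in size")
    n = zb.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = zf - zb
    mean_diff = float(d.mean())
    # near-machine-zero spread (e.g. a constant compositional shift) is degenerate
    if d.std(ddof=1) <= 1e-12 * max(1.0, abs(mean_diff)):
        if mean_diff == 0.0:
            return PairedTestResult(0.0, 1.0, 0.0, zero_variance=True)
        t = np.inf if mean_diff > 0 else -np.inf
        return PairedTestResult(float(t), 0.0, mean_diff, zero_variance=True)
    res = stats.ttest_rel(zf, zb)
    return PairedTestResult(float(res.statistic), float(res.pvalue), mean_diff)
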