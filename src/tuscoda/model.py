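"""Longitudinal compositional regression and isotemporal substitution estimates.

The outcome is a participant's follow-up marker level. The exposures are the
differences between follow-up and baseline pivot ilr coordinates of the 4-part
time-use composition; the model adjusts for the baseline ilr coordinates,
baseline marker level, sex, age, maternal education, zBMI and its change,
pubertal stage, and baseline and follow-up accelerometer wear time.

Fitting is either ordinary least squares or Huber M-estimation (tuning
constant 1.345) solved by iteratively re-weighted least squares, with the
standard M-estimator sandwich covariance. For a reallocation of time between
two behaviours, the predicted marker change is the linear contrast

    delta_hat = c' beta,  c = Delta-ilr positions set to
                          ilr(reallocated base) - ilr(base),

with a t-based 95% confidence interval using df = n - p; an estimate is
significant when its interval excludes zero. Unstandardised coefficients are
required by this formula, so no covariate is standardised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coda import pivot_ilr, pivot_ilr_array
from .reallocation import DEFAULT_DURATIONS, Reallocation, reallocate
from .timeuse import PARTS, Composition

__all__ = [
    "EDUCATION_LEVELS",
    "PUBERTAL_STAGES",
    "COHORT_COLUMNS",
    "FittedModel",
    "SubstitutionEstimate",
    "build_design",
    "fit",
    "estimate_substitution",
    "substitution_table",
]

logger = logging.getLogger(__name__)

#: Maternal education categories; the first is the reference level.
EDUCATION_LEVELS = ("no_formal", "primary", "secondary", "technical", "university")
#: Pubertal development stages; stage 1 is the reference level.
PUBERTAL_STAGES = (1, 2, 3, 4, 5)

#: Columns a cohort table must provide (marker columns are ``{marker}_base`` /
#: ``{marker}_fu`` for each analysed marker).
COHORT_COLUMNS = (
    "participant_id",
    "sleep_base_h",
    "sb_base_h",
    "lpa_base_h",
    "mvpa_base_h",
    "sleep_fu_h",
    "sb_fu_h",
    "lpa_fu_h",
    "mvpa_fu_h",
    "sex",
    "age",
    "maternal_education",
    "zbmi",
    "d_zbmi",
    "pubertal_stage",
    "wear_base_h",
    "wear_fu_h",
)


def _composition_block(cohort: pd.DataFrame, suffix: str, part_order) -> np.ndarray:
    cols = [f"{p}_{suffix}_h" for p in ("sleep", "sb", "lpa", "mvpa")]
    arr = cohort[cols].to_numpy(dtype=float)
    order_idx = [PARTS.index(p) for p in part_order]
    return pivot_ilr_array(arr[:, order_idx])


def build_design(
    cohort: pd.DataFrame,
    marker: str = "marker",
    part_order: tuple[str, ...] = PARTS,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix, outcome vector and column labels for one marker's model.

    Columns: intercept; 3 ilr-change columns (follow-up minus baseline); 3
    baseline-ilr columns; baseline marker; sex; age; 4 maternal-education
    indicators (reference: no formal education); zBMI; zBMI change; 4
    pubertal-stage indicators (reference: stage 1); baseline and follow-up
    wear time (hours, as-is). Rows with missing values are dropped and logged.
    """
    needed = list(COHORT_COLUMNS) + [f"{marker}_base", f"{marker}_fu"]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table is missing column(s): {missing_cols}")
    complete = cohort[needed].notna().all(axis=1)
    if not complete.all():
        dropped = cohort.loc[~complete, "participant_id"].tolist()
        logger.warning("dropping %d incomplete row(s): %s", len(dropped), dropped)
    data = cohort.loc[complete].reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no complete rows in the cohort table")

    b_ilr = _composition_block(data, "base", part_order)
    f_ilr = _composition_block(data, "fu", part_order)
    d_ilr = f_ilr - b_ilr

    n = len(data)
    blocks: list[np.ndarray] = [np.ones((n, 1)), d_ilr, b_ilr]
    labels = ["intercept"] + [f"d_ilr{i+1}" for i in range(3)] + [
        f"b_ilr{i+1}" for i in range(3)
    ]

    blocks.append(data[[f"{marker}_base"]].to_numpy(dtype=float))
    labels.append(f"{marker}_base")
    blocks.append(data[["sex", "age"]].to_numpy(dtype=float))
    labels += ["sex", "age"]

    edu = data["maternal_education"].astype(str)
    bad = set(edu) - set(EDUCATION_LEVELS)
    if bad:
        raise ValueError(f"unknown maternal_education level(s): {sorted(bad)}")
    edu_dummies = np.column_stack(
        [(edu == lvl).to_numpy(dtype=float) for lvl in EDUCATION_LEVELS[1:]]
    )
    blocks.append(edu_dummies)
    labels += [f"edu_{lvl}" for lvl in EDUCATION_LEVELS[1:]]

    blocks.append(data[["zbmi", "d_zbmi"]].to_numpy(dtype=float))
    labels += ["zbmi", "d_zbmi"]

    pub = data["pubertal_stage"].astype(int)
    bad_pub = set(pub) - set(PUBERTAL_STAGES)
    if bad_pub:
        raise ValueError(f"unknown pubertal stage(s): {sorted(bad_pub)}")
    pub_dummies = np.column_stack(
        [(pub == s).to_numpy(dtype=float) for s in PUBERTAL_STAGES[1:]]
    )
    blocks.append(pub_dummies)
    labels += [f"pub_{s}" for s in PUBERTAL_STAGES[1:]]

    blocks.append(data[["wear_base_h", "wear_fu_h"]].to_numpy(dtype=float))
    labels += ["wear_base_h", "wear_fu_h"]

    X = np.hstack(blocks)
    y = data[f"{marker}_fu"].to_numpy(dtype=float)
    return X, y, labels


@dataclass(frozen=True)
class FittedModel:
    """A fitted marker model: coefficients, covariance and metadata."""

    beta: np.ndarray
    cov: np.ndarray
    df_resid: int
    scale: float
    method: str
    columns: tuple[str, ...]
    part_order: tuple[str, ...] = PARTS

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov, float(np.sqrt(sigma2))


def _huber_irls(
    X: np.ndarray,
    y: np.ndarray,
    c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Huber M-estimation by IRLS with MAD scale and sandwich covariance.

    The scale is re-estimated each iteration as median(|r|)/0.6745. With
    (numerically) zero residuals the least-squares solution is already the
    M-estimate; the covariance then degenerates to zero.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    xtx_inv = np.linalg.inv(X.T @ X)
    scale = 0.0
    for _ in range(max_iter):
        resid = y - X @ beta
        scale = float(np.median(np.abs(resid))) / 0.6745
        if scale <= np.finfo(float).eps * max(1.0, float(np.abs(y).max())):
            return beta, np.zeros((p, p)), 0.0
        u = resid / scale
        absu = np.abs(u)
        w = np.ones_like(u)
        outside = absu > c
        w[outside] = c / absu[outside]
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) <= tol * max(1.0, float(np.max(np.abs(beta_new)))):
            beta = beta_new
            break
        beta = beta_new
    else:
        raise RuntimeError(f"Huber IRLS did not converge in {max_iter} iterations")

    resid = y - X @ beta
    scale = float(np.median(np.abs(resid))) / 0.6745
    if scale <= 0:
        return beta, np.zeros((p, p)), 0.0
    u = resid / scale
    psi = np.clip(u, -c, c)
    dpsi = (np.abs(u) <= c).astype(float)
    m = dpsi.mean()
    # Huber's small-sample correction factor (as in classical M-estimation).
    k = 1.0 + (p / n) * dpsi.var() / m**2
    cov = k**2 * scale**2 * (float(psi @ psi) / (n - p)) / m**2 * xtx_inv
    return beta, cov, scale


def fit(
    X: np.ndarray,
    y: np.ndarray,
    labels: list[str] | tuple[str, ...],
    method: str = "robust",
    part_order: tuple[str, ...] = PARTS,
    huber_c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> FittedModel:
    """Fit the marker model by OLS or Huber IRLS (``method``)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if method == "ols":
        beta, cov, scale = _ols(X, y)
    elif method == "robust":
        beta, cov, scale = _huber_irls(X, y, c=huber_c, tol=tol, max_iter=max_iter)
    else:
        raise ValueError(f"unknown method {method!r} (use 'robust' or 'ols')")
    return FittedModel(
        beta=beta,
        cov=cov,
        df_resid=n - p,
        scale=scale,
        method=method,
        columns=tuple(labels),
        part_order=tuple(part_order),
    )


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Predicted marker change for one reallocation, with 95% CI."""

    from_part: str
    to_part: str
    minutes: float
    delta_hat: float
    ci_low: float
    ci_high: float
    significant: bool


def _delta_ilr_contrast(
    fitted: FittedModel, base: Composition, r: Reallocation
) -> np.ndarray:
    moved = reallocate(base, r)
    dz = pivot_ilr(moved, fitted.part_order) - pivot_ilr(base, fitted.part_order)
    c = np.zeros(len(fitted.columns))
    for i, z in enumerate(dz):
        c[fitted.columns.index(f"d_ilr{i+1}")] = z
    return c


def estimate_substitution(
    fitted: FittedModel, base: Composition, r: Reallocation, level: float = 0.95
) -> SubstitutionEstimate:
    """Predicted marker change for reallocating ``r.minutes`` from one behaviour
    to another, starting from ``base`` (typically the mean baseline composition)."""
    c = _delta_ilr_contrast(fitted, base, r)
    delta = float(c @ fitted.beta)
    se = float(np.sqrt(c @ fitted.cov @ c))
    tq = stats.t.ppf((1 + level) / 2, fitted.df_resid)
    lo, hi = delta - tq * se, delta + tq * se
    return SubstitutionEstimate(
        from_part=r.from_part,
        to_part=r.to_part,
        minutes=r.minutes,
        delta_hat=delta,
        ci_low=lo,
        ci_high=hi,
        significant=not (lo <= 0.0 <= hi),
    )


def substitution_table(
    fitted: FittedModel,
    base: Composition,
    durations: tuple[float, ...] = DEFAULT_DURATIONS,
    level: float = 0.95,
) -> pd.DataFrame:
    """All feasible ordered reallocations x durations as a tidy table.

    Columns: ``duration_min, from, to, delta, ci_low, ci_high, significant``;
    infeasible cells (source behaviour shorter than the duration) are skipped.
    """
    rows = []
    import itertools

    for minutes in durations:
        for from_part, to_part in itertools.permutations(PARTS, 2):
            r = Reallocation(from_part, to_part, minutes)
            try:
                est = estimate_substitution(fitted, base, r, level)
            except ValueError:
                logger.warning(
                    "substitution table: skipping infeasible %s->%s at %g min",
                    from_part,
                    to_part,
                    minutes,
                )
                continue
            rows.append(
                {
                    "duration_min": minutes,
                    "from": from_part,
                    "to": to_part,
                    "delta": est.delta_hat,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "significant": est.significant,
                }
            )
    return pd.DataFrame(rows)
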