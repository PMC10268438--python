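"""Synthetic cohorts and count series with known ground truth.

The cohort generator draws 4-part time-use compositions from a
logistic-normal law (multivariate normal in pivot ilr coordinates, mapped back
to the simplex), which is the natural sampling model for an ilr-based
analysis and keeps every true quantity computable in closed form. Follow-up
ilr coordinates are baseline plus an independent normal change. Marker
outcomes are generated through the *same* design-matrix contract the model
module fits, so regenerating the design and multiplying by the true
coefficients reproduces the noise-free marker means exactly.

Defaults emulate the published cohort conditions: n = 296; the baseline and
follow-up centres of the composition distribution equal the printed
descriptive centres (sleep 9.13, SB 10.89, LPA 2.93, MVPA 1.05 h/day at
baseline; 8.92/11.65/2.48/0.95 at follow-up); covariate distributions follow
the sample-description table (49% girls, age ~13, zBMI 0.62 +/- 1.09,
education and pubertal frequencies, wear time 14.43 +/- 1.05 h baseline and
14.32 +/- 1.22 h follow-up). Compositional spread is calibrated so the
descriptive 95% CIs of the re-scaled geometric means match the printed
interval widths at n = 296. True effect sizes are illustrative: chosen so
60-min reallocation effects are of the order of a few mg/dl, as for
complement factors.

The count-series generator plants a per-day schedule of non-wear/SB/LPA/MVPA
blocks and draws epoch counts strictly inside the scaled cut-point bins, so
the processing pipeline can recover the schedule exactly. Random schedules
keep non-wear blocks >= 60 min and never adjacent to SB blocks, and draw SB
epochs with count >= 1 — otherwise low-count SB minutes at block edges could
legitimately be absorbed into the non-wear allowance, which is a property of
the published rule, not a detector defect.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accelerometry import CutPoints, DailySummary, EpochSeries, write_counts_csv
from .coda import inverse_pivot_ilr, pivot_ilr_array, psi_matrix
from .model import EDUCATION_LEVELS, PUBERTAL_STAGES, build_design
from .reallocation import DEFAULT_DURATIONS, Reallocation, reallocate
from .timeuse import PARTS, Composition

__all__ = [
    "BASELINE_MEAN_H",
    "FOLLOWUP_MEAN_H",
    "SimulationConfig",
    "TruthRecord",
    "simulate_cohort",
    "simulate_counts",
    "random_schedule",
    "simulate_bundle",
]

#: Printed descriptive centres of the cohort's time-use composition (h/day).
BASELINE_MEAN_H = (9.13, 10.89, 2.93, 1.05)
FOLLOWUP_MEAN_H = (8.92, 11.65, 2.48, 0.95)

# Per-part log-scale SDs calibrated so the t-based CIs of the re-scaled
# geometric means at n = 296 match the printed descriptive interval widths
# (sleep 9.03-9.24, SB 10.73-11.05, LPA 2.85-3.02, MVPA 1.00-1.09 h/day).
_LOG_SD_BASE = (0.100, 0.128, 0.250, 0.375)
# Longitudinal 3-year change is assumed about as variable again (no published
# change dispersion exists); see docs/methods.md.
_LOG_SD_CHANGE = (0.080, 0.100, 0.200, 0.300)


def _ilr_cov_from_log_sd(log_sd: tuple[float, ...]) -> np.ndarray:
    psi = psi_matrix(len(log_sd))
    return psi @ np.diag(np.square(log_sd)) @ psi.T


def _default_coefficients() -> dict[str, float]:
    coef = {
        "intercept": 40.0,
        # ilr-change block: sized so 60-min reallocations move the marker by a
        # few units (complement-factor scale); illustrative, not ground truth.
        "d_ilr1": 20.0,
        "d_ilr2": -12.0,
        "d_ilr3": 6.0,
        "b_ilr1": 3.0,
        "b_ilr2": -2.0,
        "b_ilr3": 1.0,
        "marker_base": 0.6,
        "sex": 2.0,
        "age": 0.8,
        "zbmi": 3.0,
        "d_zbmi": 4.0,
        "wear_base_h": 0.5,
        "wear_fu_h": -0.5,
    }
    for i, lvl in enumerate(EDUCATION_LEVELS[1:]):
        coef[f"edu_{lvl}"] = 0.5 * (i + 1)
    for i, s in enumerate(PUBERTAL_STAGES[1:]):
        coef[f"pub_{s}"] = 0.8 * (i + 1)
    return coef


def _choice_all_levels(rng, levels, n, probs, max_tries: int = 200) -> np.ndarray:
    """Categorical draw conditioned on every level being represented.

    The adjusted model needs every indicator category observed to be
    estimable; with a ~1% reference category a plain multinomial draw at
    n = 296 occasionally leaves it empty. Conditioning on full representation
    is a negligible distortion of the covariate law and keeps every simulated
    design full rank.
    """
    for _ in range(max_tries):
        draw = rng.choice(np.asarray(levels), size=n, p=probs)
        if len(set(draw.tolist())) == len(levels):
            return draw
    raise RuntimeError("could not draw a cohort with every covariate level present")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n: int = 296
    baseline_ilr_mean: np.ndarray = field(
        default_factory=lambda: pivot_ilr_array(np.array(BASELINE_MEAN_H))
    )
    baseline_ilr_cov: np.ndarray = field(
        default_factory=lambda: _ilr_cov_from_log_sd(_LOG_SD_BASE)
    )
    change_ilr_mean: np.ndarray = field(
        default_factory=lambda: pivot_ilr_array(np.array(FOLLOWUP_MEAN_H))
        - pivot_ilr_array(np.array(BASELINE_MEAN_H))
    )
    change_ilr_cov: np.ndarray = field(
        default_factory=lambda: _ilr_cov_from_log_sd(_LOG_SD_CHANGE)
    )
    coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    noise_sd: float = 18.0
    contamination_frac: float = 0.0
    contamination_scale: float = 10.0
    # Covariate generators (study-sample values).
    girl_prob: float = 0.49
    age_range: tuple[float, float] = (8.6, 17.0)
    education_probs: tuple[float, ...] = (4 / 296, 53 / 296, 52 / 296, 93 / 296, 94 / 296)
    pubertal_probs: tuple[float, ...] = (11 / 296, 79 / 296, 100 / 296, 77 / 296, 29 / 296)
    zbmi_mean: float = 0.62
    zbmi_sd: float = 1.09
    d_zbmi_sd: float = 0.5
    marker_base_mean: float = 89.35
    marker_base_sd: float = 27.82
    wear_base: tuple[float, float] = (14.43, 1.05)
    wear_fu: tuple[float, float] = (14.32, 1.22)
    seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_ilr_cov", "change_ilr_cov"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (3, 3) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.any(np.linalg.eigvalsh(m) < -1e-12):
                raise ValueError(f"{name} must be positive semi-definite")
        for name in ("education_probs", "pubertal_probs"):
            p = np.asarray(getattr(self, name))
            if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError(f"{name} must be a probability vector")
        if not (0.0 <= self.contamination_frac < 1.0):
            raise ValueError("contamination_frac must lie in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """Generating coefficients and the implied true substitution effects."""

    beta: pd.Series
    base: Composition
    true_effects: pd.DataFrame  # columns: duration_min, from, to, delta_true

    def true_effect(self, from_part: str, to_part: str, minutes: float) -> float:
        m = self.true_effects
        row = m[
            (m["from"] == from_part) & (m["to"] == to_part) & (m["duration_min"] == minutes)
        ]
        return float(row["delta_true"].iloc[0])


def _true_effects(
    beta: pd.Series, base: Composition, durations=DEFAULT_DURATIONS
) -> pd.DataFrame:
    import itertools

    b_dilr = beta[[f"d_ilr{i+1}" for i in range(3)]].to_numpy()
    base_z = pivot_ilr_array(base.as_array())
    rows = []
    for minutes in durations:
        for from_part, to_part in itertools.permutations(PARTS, 2):
            try:
                moved = reallocate(base, Reallocation(from_part, to_part, minutes))
            except ValueError:
                continue
            dz = pivot_ilr_array(moved.as_array()) - base_z
            rows.append(
                {
                    "duration_min": minutes,
                    "from": from_part,
                    "to": to_part,
                    "delta_true": float(b_dilr @ dz),
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig | None = None) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a cohort table plus its generating truth, reproducibly from the seed."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    # intercept + 3 d_ilr + 3 b_ilr + marker_base + sex + age + dummies + zbmi,
    # d_zbmi + wear_base, wear_fu
    n_design_cols = 10 + (len(EDUCATION_LEVELS) - 1) + 2 + (len(PUBERTAL_STAGES) - 1) + 2
    if n < n_design_cols + 2:
        raise ValueError(f"n = {n} too small for a {n_design_cols}-column design")

    b_ilr = rng.multivariate_normal(config.baseline_ilr_mean, config.baseline_ilr_cov, n)
    change = rng.multivariate_normal(config.change_ilr_mean, config.change_ilr_cov, n)
    f_ilr = b_ilr + change
    from .coda import inverse_pivot_ilr_array

    base_h = inverse_pivot_ilr_array(b_ilr)
    fu_h = inverse_pivot_ilr_array(f_ilr)

    cohort = pd.DataFrame({"participant_id": [f"P{i:04d}" for i in range(n)]})
    for j, p in enumerate(PARTS):
        cohort[f"{p}_base_h"] = base_h[:, j]
        cohort[f"{p}_fu_h"] = fu_h[:, j]
    cohort["sex"] = (rng.random(n) < config.girl_prob).astype(int)
    cohort["age"] = rng.uniform(*config.age_range, n)
    cohort["maternal_education"] = _choice_all_levels(
        rng, EDUCATION_LEVELS, n, config.education_probs
    )
    cohort["zbmi"] = rng.normal(config.zbmi_mean, config.zbmi_sd, n)
    cohort["d_zbmi"] = rng.normal(0.0, config.d_zbmi_sd, n)
    cohort["pubertal_stage"] = _choice_all_levels(
        rng, PUBERTAL_STAGES, n, config.pubertal_probs
    )
    cohort["wear_base_h"] = rng.normal(*config.wear_base, n)
    cohort["wear_fu_h"] = rng.normal(*config.wear_fu, n)
    cohort["marker_base"] = rng.normal(config.marker_base_mean, config.marker_base_sd, n)

    # Generate the outcome through the fitted model's own design contract.
    cohort["marker_fu"] = 0.0
    X, _, labels = build_design(cohort, marker="marker")
    beta = pd.Series({k: config.coefficients[k] for k in labels})
    noise = rng.normal(0.0, config.noise_sd, n)
    if config.contamination_frac > 0:
        hit = rng.random(n) < config.contamination_frac
        noise[hit] *= config.contamination_scale
    cohort["marker_fu"] = X @ beta.to_numpy() + noise

    base_centre = inverse_pivot_ilr(np.asarray(config.baseline_ilr_mean, dtype=float))
    truth = TruthRecord(
        beta=beta, base=base_centre, true_effects=_true_effects(beta, base_centre)
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Count-series simulation
# ---------------------------------------------------------------------------

Block = tuple[str, int]  # (label in {nonwear, sb, lpa, mvpa}, whole minutes)

_BLOCK_LABELS = ("nonwear", "sb", "lpa", "mvpa")


def _bin_edges(cuts: CutPoints, epoch_s: int) -> dict[str, tuple[int, int]]:
    """Inclusive integer count ranges per label, strictly inside the scaled bins."""
    f = epoch_s / 60.0
    sb_hi = int(np.ceil((cuts.sb_max_cpm + 1) * f)) - 1
    lpa_lo = sb_hi + 1
    lpa_hi = int(np.ceil(cuts.mvpa_min_cpm * f)) - 1
    mvpa_lo = lpa_hi + 1
    return {"sb": (1, sb_hi), "lpa": (lpa_lo, lpa_hi), "mvpa": (mvpa_lo, 3 * mvpa_lo)}


def simulate_counts(
    profile: list[Block],
    epoch_s: int = 60,
    seed: int = 0,
    start: dt.datetime | None = None,
    cuts: CutPoints = CutPoints(),
    max_allowance_minutes: int = 2,
) -> tuple[EpochSeries, DailySummary]:
    """Planted count series for one day plus its ground-truth daily summary.

    ``profile`` is an ordered list of (label, minutes) blocks covering at most
    24 h. Worn epochs are drawn uniformly inside the scaled cut-point bin of
    their block's label; non-wear blocks are zeros with at most
    ``max_allowance_minutes`` planted sub-100-count minutes.
    """
    if start is None:
        start = dt.datetime(2011, 10, 7, 0, 0)  # a Friday
    total_min = sum(m for _, m in profile)
    if total_min <= 0 or total_min > 1440:
        raise ValueError("profile must cover between 1 minute and 24 h")
    for label, minutes in profile:
        if label not in _BLOCK_LABELS:
            raise ValueError(f"unknown block label {label!r}")
        if minutes <= 0 or minutes != int(minutes):
            raise ValueError("block durations must be positive whole minutes")
        if label == "nonwear" and minutes < 60:
            raise ValueError("non-wear blocks must be at least 60 min to be detectable")

    rng = np.random.default_rng(seed)
    epm = 60 // epoch_s
    edges = _bin_edges(cuts, epoch_s)
    chunks: list[np.ndarray] = []
    truth_min = {"sb": 0, "lpa": 0, "mvpa": 0}
    nonwear_min = 0
    for label, minutes in profile:
        n_ep = minutes * epm
        if label == "nonwear":
            block = np.zeros(n_ep, dtype=np.int64)
            n_allow = int(rng.integers(0, max_allowance_minutes + 1))
            if n_allow:
                which = rng.choice(minutes, size=min(n_allow, minutes), replace=False)
                for m in which:
                    block[m * epm] = int(rng.integers(1, 100))
            nonwear_min += minutes
        else:
            lo, hi = edges[label]
            block = rng.integers(lo, hi + 1, size=n_ep)
            truth_min[label] += minutes
        chunks.append(block)
    series = EpochSeries("SIM", "baseline", start, epoch_s, np.concatenate(chunks))
    truth = DailySummary(
        date=start.date(),
        is_weekend=start.weekday() >= 5,
        wear_h=(total_min - nonwear_min) / 60.0,
        sb_min=float(truth_min["sb"]),
        lpa_min=float(truth_min["lpa"]),
        mvpa_min=float(truth_min["mvpa"]),
    )
    return series, truth


def random_schedule(rng: np.random.Generator, total_min: int = 1440) -> list[Block]:
    """A random day-tiling schedule that the processing rules can recover exactly.

    Non-wear blocks are >= 60 min and never adjacent to SB blocks, because an
    SB minute (per-minute total < 100 counts) bordering a long zero run can
    legitimately be swallowed by the non-wear allowance.
    """
    blocks: list[Block] = []
    remaining = total_min
    prev = None
    while remaining > 0:
        if remaining < 5:  # absorb a short tail into light activity
            blocks.append(("lpa", remaining))
            break
        options = ["sb", "lpa", "mvpa"]
        if remaining >= 60 and prev != "sb":
            options.append("nonwear")
        if prev == "nonwear":
            options = ["lpa", "mvpa"]
        label = str(rng.choice(options))
        if label == "nonwear":
            minutes = int(rng.integers(60, min(remaining, 540) + 1))
        else:
            minutes = int(rng.integers(5, min(remaining, 240) + 1))
        if 0 < remaining - minutes < 5:  # never strand an unfillable tail
            minutes = remaining
        blocks.append((label, minutes))
        remaining -= minutes
        prev = label
    return blocks


# ---------------------------------------------------------------------------
# Full input bundle for the end-to-end pipeline
# ---------------------------------------------------------------------------


def _day_profile(comp_h: np.ndarray) -> list[Block]:
    """A plausible day realising a composition: sleep as overnight non-wear,
    waking behaviours as contiguous blocks (LPA buffers keep non-wear away
    from SB). Leftover rounding minutes go to LPA."""
    sleep_m, sb_m, lpa_m, mvpa_m = (int(round(v * 60.0)) for v in comp_h)
    lpa_m += 1440 - (sleep_m + sb_m + lpa_m + mvpa_m)  # absorb rounding
    if min(sleep_m, sb_m, mvpa_m) <= 0 or lpa_m <= 2 or sleep_m < 60:
        raise ValueError(f"composition {comp_h} cannot be scheduled")
    half = lpa_m // 2
    return [
        ("nonwear", sleep_m),
        ("lpa", half),
        ("sb", sb_m),
        ("lpa", lpa_m - half),
        ("mvpa", mvpa_m),
    ]


def simulate_bundle(
    out_dir: str | Path,
    n: int = 40,
    seed: int = 0,
    n_days: int = 4,
    epoch_s: int = 60,
    config: SimulationConfig | None = None,
) -> dict:
    """Write a complete synthetic input bundle: per-participant count CSVs,
    a cohort CSV (covariates, sleep reports, markers) and a truth JSON.

    Count series start on a Friday so that ``n_days >= 2`` always includes a
    weekend day. Returns a small manifest dict.
    """
    out_dir = Path(out_dir)
    counts_dir = out_dir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig(n=n, seed=seed)
    else:
        config.n, config.seed = n, seed
    cohort, truth = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9241]))

    rows = []
    for i, row in cohort.iterrows():
        rec = {
            "participant_id": row["participant_id"],
            "sex": row["sex"],
            "age": row["age"],
            "maternal_education": row["maternal_education"],
            "zbmi": row["zbmi"],
            "d_zbmi": row["d_zbmi"],
            "pubertal_stage": row["pubertal_stage"],
            "marker_base": row["marker_base"],
            "marker_fu": row["marker_fu"],
        }
        for wave, suffix in (("baseline", "base"), ("followup", "fu")):
            comp_h = np.array([row[f"{p}_{suffix}_h"] for p in PARTS])
            profile = _day_profile(comp_h)
            day_chunks = []
            # Both waves start on a Friday so >= 2 days always include a weekend day.
            start = (
                dt.datetime(2011, 10, 7) if wave == "baseline" else dt.datetime(2013, 10, 4)
            )
            for d in range(n_days):
                day_series, _ = simulate_counts(
                    profile,
                    epoch_s=epoch_s,
                    seed=int(rng.integers(2**31)),
                    start=start + dt.timedelta(days=d),
                )
                day_chunks.append(day_series.counts)
            series = EpochSeries(
                row["participant_id"], wave, start, epoch_s, np.concatenate(day_chunks)
            )
            write_counts_csv(series, counts_dir / f"{row['participant_id']}_{wave}.csv")
            # Self-reported sleep consistent with the composition (to the second).
            sleep_s = int(round(comp_h[0] * 3600))
            bed = dt.time(23, 0)
            wake_dt = dt.datetime(2000, 1, 1, 23, 0) + dt.timedelta(seconds=sleep_s)
            rec[f"bedtime_{suffix}"] = bed.strftime("%H:%M:%S")
            rec[f"waketime_{suffix}"] = wake_dt.time().strftime("%H:%M:%S")
        rows.append(rec)

    cohort_csv = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(cohort_csv, index=False)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "beta": truth.beta.to_dict(),
                "base_composition_h": truth.base.as_array().tolist(),
                "true_effects": truth.true_effects.to_dict(orient="records"),
                "seed": seed,
            },
            indent=2,
        )
    )
    return {
        "counts_dir": str(counts_dir),
        "cohort_csv": str(cohort_csv),
        "truth_json": str(truth_path),
        "n": n,
        "seed": seed,
    }
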