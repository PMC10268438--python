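"""End-to-end orchestration: counts -> compositions -> fits -> substitution tables.

`run_all` executes the stages in order, writes CSV outputs plus a
machine-readable run manifest, and aborts on the first stage failure with the
stage name and the offending row identifiers. All randomness (none in the
deterministic stages; any future resampling) flows from the single config
seed, and identical config + inputs produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accelerometry import CutPoints, Rejection, process_series, read_counts_csv
from .coda import mean_composition, paired_pivot_ttest, rescaled_geomean_ci
from .model import build_design, fit, substitution_table
from .reallocation import DEFAULT_DURATIONS
from .timeuse import PARTS, Composition, SleepReport, build_composition, sleep_duration

__all__ = ["RunConfig", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    """Paths and parameters for a full run."""

    counts_dir: str
    cohort_csv: str
    out_dir: str
    epoch_s: int | None = None
    min_wear_h: float = 10.0
    min_days: int = 3
    min_weekend_days: int = 1
    cutpoints: CutPoints = field(default_factory=CutPoints)
    part_order: tuple[str, ...] = PARTS
    markers: tuple[str, ...] = ("marker",)
    method: str = "robust"
    durations: tuple[float, ...] = DEFAULT_DURATIONS
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "cutpoints" in raw:
            raw["cutpoints"] = CutPoints(**raw["cutpoints"])
        for key in ("part_order", "markers", "durations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("process-accel")
def _process_counts(config: RunConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    counts_dir = Path(config.counts_dir)
    rows, rejections = [], []
    for pid in cohort["participant_id"]:
        for wave in ("baseline", "followup"):
            path = counts_dir / f"{pid}_{wave}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing counts file for row {pid}/{wave}: {path}")
            series = read_counts_csv(path, pid, wave, config.epoch_s)
            result, _ = process_series(
                series,
                cuts=config.cutpoints,
                min_wear_h=config.min_wear_h,
                min_days=config.min_days,
                min_weekend_days=config.min_weekend_days,
            )
            if isinstance(result, Rejection):
                rejections.append(dataclasses.asdict(result))
            else:
                rows.append(dataclasses.asdict(result))
    activity = pd.DataFrame(rows)
    out_dir = Path(config.out_dir)
    activity.to_csv(out_dir / "activity.csv", index=False)
    pd.DataFrame(rejections, columns=["participant_id", "wave", "reason"]).to_csv(
        out_dir / "rejections.csv", index=False
    )
    return activity


@_stage("assemble")
def _assemble(config: RunConfig, cohort: pd.DataFrame, activity: pd.DataFrame) -> pd.DataFrame:
    recs = []
    for _, row in cohort.iterrows():
        pid = row["participant_id"]
        rec: dict = {"participant_id": pid}
        ok = True
        for wave, suffix in (("baseline", "base"), ("followup", "fu")):
            act = activity[
                (activity["participant_id"] == pid) & (activity["wave"] == wave)
            ]
            if act.empty:
                ok = False
                break
            report = SleepReport(
                dt.time.fromisoformat(str(row[f"bedtime_{suffix}"])),
                dt.time.fromisoformat(str(row[f"waketime_{suffix}"])),
            )
            comp = build_composition(
                sleep_duration(report),
                float(act["mean_sb_min"].iloc[0]),
                float(act["mean_lpa_min"].iloc[0]),
                float(act["mean_mvpa_min"].iloc[0]),
            )
            for p, v in zip(PARTS, comp.as_array()):
                rec[f"{p}_{suffix}_h"] = v
            rec[f"wear_{suffix}_h"] = float(act["mean_wear_h"].iloc[0])
        if ok:
            recs.append(rec)
    compositions = pd.DataFrame(recs)
    compositions.to_csv(Path(config.out_dir) / "compositions.csv", index=False)
    return compositions


@_stage("describe")
def _describe(config: RunConfig, table: pd.DataFrame) -> pd.DataFrame:
    base = table[[f"{p}_base_h" for p in PARTS]].to_numpy(dtype=float)
    fu = table[[f"{p}_fu_h" for p in PARTS]].to_numpy(dtype=float)
    mb, mf = mean_composition(base), mean_composition(fu)
    rows = []
    for j, part in enumerate(PARTS):
        test = paired_pivot_ttest(base, fu, part)
        lo_b, hi_b = rescaled_geomean_ci(base, part)
        lo_f, hi_f = rescaled_geomean_ci(fu, part)
        rows.append(
            {
                "variable": part,
                "kind": "timeuse_h",
                "baseline_mean": mb.as_array()[j],
                "baseline_lo": lo_b,
                "baseline_hi": hi_b,
                "followup_mean": mf.as_array()[j],
                "followup_lo": lo_f,
                "followup_hi": hi_f,
                "change": mf.as_array()[j] - mb.as_array()[j],
                "p_value": test.p_value,
            }
        )
    from scipy import stats

    for marker in config.markers:
        b = table[f"{marker}_base"].to_numpy(dtype=float)
        f = table[f"{marker}_fu"].to_numpy(dtype=float)
        res = stats.ttest_rel(f, b)
        rows.append(
            {
                "variable": marker,
                "kind": "marker",
                "baseline_mean": b.mean(),
                "baseline_lo": b.std(ddof=1),
                "baseline_hi": np.nan,
                "followup_mean": f.mean(),
                "followup_lo": f.std(ddof=1),
                "followup_hi": np.nan,
                "change": f.mean() - b.mean(),
                "p_value": float(res.pvalue),
            }
        )
    desc = pd.DataFrame(rows)
    desc.to_csv(Path(config.out_dir) / "descriptives.csv", index=False)
    return desc


@_stage("fit-substitute")
def _fit_and_substitute(config: RunConfig, table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    base = mean_composition(table[[f"{p}_base_h" for p in PARTS]].to_numpy(dtype=float))
    out: dict[str, pd.DataFrame] = {}
    for marker in config.markers:
        X, y, labels = build_design(table, marker=marker, part_order=config.part_order)
        fitted = fit(X, y, labels, method=config.method, part_order=config.part_order)
        tab = substitution_table(fitted, base, durations=config.durations)
        tab.insert(0, "marker", marker)
        tab.to_csv(Path(config.out_dir) / f"substitution_{marker}.csv", index=False)
        out[marker] = tab
    return out


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the run report (also written as manifest.json)."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(config.cohort_csv)
    required = ["participant_id", "sex", "age", "maternal_education", "zbmi", "d_zbmi",
                "pubertal_stage", "bedtime_base", "waketime_base", "bedtime_fu",
                "waketime_fu"] + [
        f"{m}_{s}" for m in config.markers for s in ("base", "fu")
    ]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise PipelineError(f"stage 'load-cohort' failed: missing column(s) {missing}")

    activity = _process_counts(config, cohort)
    compositions = _assemble(config, cohort, activity)
    covar_cols = [c for c in cohort.columns if not c.startswith(("bedtime", "waketime"))]
    table = compositions.merge(cohort[covar_cols], on="participant_id", how="inner")
    _describe(config, table)
    tables = _fit_and_substitute(config, table)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "inputs": {"counts_dir": config.counts_dir, "cohort_csv": config.cohort_csv},
        "parameters": {
            "epoch_s": config.epoch_s,
            "min_wear_h": config.min_wear_h,
            "min_days": config.min_days,
            "min_weekend_days": config.min_weekend_days,
            "cutpoints": dataclasses.asdict(config.cutpoints),
            "part_order": list(config.part_order),
            "markers": list(config.markers),
            "method": config.method,
            "durations": list(config.durations),
        },
        "n_analysed": int(len(table)),
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
        "n_significant": {m: int(t["significant"].sum()) for m, t in tables.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
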