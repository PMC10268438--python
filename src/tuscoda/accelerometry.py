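"""Accelerometer count processing.

Turns raw vertical-axis activity-count series into per-participant average
daily minutes of sedentary behaviour (SB), light physical activity (LPA) and
moderate-to-vigorous physical activity (MVPA), plus average wear time.

Processing rules:

* counts may be re-integrated (summed) from a finer to a coarser epoch;
* non-wear time is any run of >= 60 consecutive minutes of zero counts,
  allowing at most 2 minutes with a per-minute total below 100 counts; a
  minute at or above 100 counts, or a third nonzero minute, breaks the run;
* worn epochs are classified by cut-points expressed in counts per minute
  (SB 0-99, LPA 100-1999, MVPA >= 2000) scaled proportionally to the working
  epoch length;
* a day is valid with >= 10 h of wear; a participant-wave is retained with
  >= 3 valid days including >= 1 weekend day, behaviour durations averaged
  (unweighted) over the valid days.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "CutPoints",
    "DailySummary",
    "ParticipantActivity",
    "Rejection",
    "reintegrate",
    "detect_nonwear",
    "classify_epochs",
    "summarize_days",
    "filter_valid",
    "process_series",
    "read_counts_csv",
    "write_counts_csv",
    "LABELS",
]

logger = logging.getLogger(__name__)

#: Epoch intensity labels.
LABELS = ("SB", "LPA", "MVPA", "NONWEAR")


@dataclass(frozen=True)
class EpochSeries:
    """Timestamped activity counts at a fixed epoch length for one participant-wave."""

    participant_id: str
    wave: str
    start_time: dt.datetime
    epoch_s: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.epoch_s <= 0 or 60 % self.epoch_s != 0:
            raise ValueError(f"epoch_s must divide 60, got {self.epoch_s}")
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-d sequence")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=pd.Timedelta(seconds=self.epoch_s)
        )


@dataclass(frozen=True)
class CutPoints:
    """Intensity cut-points in counts per minute (inclusive bin edges).

    SB is [0, sb_max_cpm], LPA is [sb_max_cpm + 1, lpa_max_cpm] and MVPA is
    [mvpa_min_cpm, inf); the bins must be contiguous.
    """

    sb_max_cpm: int = 99
    lpa_max_cpm: int = 1999
    mvpa_min_cpm: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.sb_max_cpm < self.lpa_max_cpm):
            raise ValueError("need 0 <= sb_max_cpm < lpa_max_cpm")
        if self.lpa_max_cpm + 1 != self.mvpa_min_cpm:
            raise ValueError("LPA and MVPA bins must be contiguous")


@dataclass(frozen=True)
class DailySummary:
    """Wear time and behaviour durations for one calendar date."""

    date: dt.date
    is_weekend: bool
    wear_h: float
    sb_min: float
    lpa_min: float
    mvpa_min: float


@dataclass(frozen=True)
class ParticipantActivity:
    """Average daily behaviour durations over a participant-wave's valid days."""

    participant_id: str
    wave: str
    n_valid_days: int
    mean_wear_h: float
    mean_sb_min: float
    mean_lpa_min: float
    mean_mvpa_min: float


@dataclass(frozen=True)
class Rejection:
    """A participant-wave excluded by the valid-day criteria (a value, not an error)."""

    participant_id: str
    wave: str
    reason: str


def reintegrate(series: EpochSeries, target_epoch_s: int) -> EpochSeries:
    """Sum counts over consecutive blocks to a coarser epoch length.

    The target epoch must be a multiple of the source epoch and divide 60.
    A trailing partial block is dropped (and logged); total counts over the
    complete blocks are conserved.
    """
    if target_epoch_s < series.epoch_s:
        raise ValueError("cannot re-integrate to a finer epoch than the source")
    if target_epoch_s % series.epoch_s != 0 or 60 % target_epoch_s != 0:
        raise ValueError(
            f"target epoch {target_epoch_s}s must be a multiple of {series.epoch_s}s "
            "and divide 60"
        )
    ratio = target_epoch_s // series.epoch_s
    if ratio == 1:
        return series
    n_blocks = series.n_epochs // ratio
    dropped = series.n_epochs - n_blocks * ratio
    if dropped:
        logger.info(
            "reintegrate: dropping trailing partial block of %d epoch(s) for %s/%s",
            dropped,
            series.participant_id,
            series.wave,
        )
    summed = series.counts[: n_blocks * ratio].reshape(n_blocks, ratio).sum(axis=1)
    return EpochSeries(
        series.participant_id, series.wave, series.start_time, target_epoch_s, summed
    )


def _minute_totals(series: EpochSeries) -> tuple[np.ndarray, int]:
    """Per-minute count totals over complete minutes; returns (totals, epochs/min)."""
    epm = 60 // series.epoch_s
    n_min = series.n_epochs // epm
    totals = series.counts[: n_min * epm].reshape(n_min, epm).sum(axis=1)
    return totals, epm


def detect_nonwear(
    series: EpochSeries,
    window_min: int = 60,
    allowance_max: int = 2,
    allowance_cpm: int = 100,
) -> np.ndarray:
    """Boolean wear mask (True = worn), one entry per epoch.

    A minute is non-wear iff it lies inside some window of >= ``window_min``
    consecutive minutes in which no minute reaches ``allowance_cpm`` counts and
    at most ``allowance_max`` minutes are nonzero. Because every sub-window of
    a qualifying window also satisfies the count conditions, the union of all
    qualifying windows equals the union of qualifying windows of length
    exactly ``window_min``, which is what is computed here with rolling sums.
    Epochs in a trailing partial minute are never flagged non-wear.
    """
    totals, epm = _minute_totals(series)
    n_min = totals.size
    wear = np.ones(series.n_epochs, dtype=bool)
    if n_min < window_min:
        return wear
    barrier = (totals >= allowance_cpm).astype(np.int64)
    nonzero = (totals > 0).astype(np.int64)
    kernel = np.ones(window_min, dtype=np.int64)
    bar_roll = np.convolve(barrier, kernel, mode="valid")
    nz_roll = np.convolve(nonzero, kernel, mode="valid")
    qualifies = (bar_roll == 0) & (nz_roll <= allowance_max)
    # Union of qualifying windows via a difference array over minute indices.
    diff = np.zeros(n_min + 1, dtype=np.int64)
    starts = np.flatnonzero(qualifies)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + window_min, -1)
    nonwear_min = np.cumsum(diff[:-1]) > 0
    wear[: n_min * epm] = ~np.repeat(nonwear_min, epm)
    return wear


def classify_epochs(
    series: EpochSeries, wear_mask: np.ndarray, cuts: CutPoints = CutPoints()
) -> np.ndarray:
    """Label each epoch SB/LPA/MVPA/NONWEAR.

    Cut-points given in counts per minute are scaled by ``epoch_s / 60`` so the
    per-minute bins are reproduced exactly at 60-s epochs and extended
    proportionally to finer epochs (e.g. at 10 s the SB bin is counts < 100/6).
    """
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if wear_mask.shape != (series.n_epochs,):
        raise ValueError("wear mask is not aligned with the series")
    f = series.epoch_s / 60.0
    labels = np.full(series.n_epochs, "NONWEAR", dtype="<U7")
    c = series.counts
    labels[wear_mask & (c < (cuts.sb_max_cpm + 1) * f)] = "SB"
    labels[wear_mask & (c >= (cuts.sb_max_cpm + 1) * f) & (c < cuts.mvpa_min_cpm * f)] = "LPA"
    labels[wear_mask & (c >= cuts.mvpa_min_cpm * f)] = "MVPA"
    return labels


def summarize_days(series: EpochSeries, labels: np.ndarray, wear_mask: np.ndarray) -> list[DailySummary]:
    """Aggregate labelled epochs into one summary per calendar date.

    Epochs are assigned to the calendar date of their start time (days split
    at midnight); weekend = Saturday or Sunday.
    """
    labels = np.asarray(labels)
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if labels.shape != (series.n_epochs,) or wear_mask.shape != (series.n_epochs,):
        raise ValueError("labels/mask not aligned with the series")
    frame = pd.DataFrame(
        {
            "date": series.timestamps().date,
            "label": labels,
            "worn": wear_mask,
        }
    )
    out = []
    minutes_per_epoch = series.epoch_s / 60.0
    for date, grp in frame.groupby("date", sort=True):
        counts = grp["label"].value_counts()
        out.append(
            DailySummary(
                date=date,
                is_weekend=date.weekday() >= 5,
                wear_h=float(grp["worn"].sum()) * series.epoch_s / 3600.0,
                sb_min=float(counts.get("SB", 0)) * minutes_per_epoch,
                lpa_min=float(counts.get("LPA", 0)) * minutes_per_epoch,
                mvpa_min=float(counts.get("MVPA", 0)) * minutes_per_epoch,
            )
        )
    return out


def filter_valid(
    participant_id: str,
    wave: str,
    days: list[DailySummary],
    min_wear_h: float = 10.0,
    min_days: int = 3,
    min_weekend_days: int = 1,
) -> ParticipantActivity | Rejection:
    """Apply valid-day inclusion criteria and average over retained days."""
    valid = [d for d in days if d.wear_h >= min_wear_h]
    if len(valid) < min_days:
        return Rejection(
            participant_id, wave, f"only {len(valid)} day(s) with >= {min_wear_h} h wear"
        )
    n_weekend = sum(d.is_weekend for d in valid)
    if n_weekend < min_weekend_days:
        return Rejection(
            participant_id,
            wave,
            f"{n_weekend} weekend day(s) with >= {min_wear_h} h wear "
            f"(need {min_weekend_days})",
        )
    return ParticipantActivity(
        participant_id=participant_id,
        wave=wave,
        n_valid_days=len(valid),
        mean_wear_h=float(np.mean([d.wear_h for d in valid])),
        mean_sb_min=float(np.mean([d.sb_min for d in valid])),
        mean_lpa_min=float(np.mean([d.lpa_min for d in valid])),
        mean_mvpa_min=float(np.mean([d.mvpa_min for d in valid])),
    )


def process_series(
    series: EpochSeries,
    cuts: CutPoints = CutPoints(),
    min_wear_h: float = 10.0,
    min_days: int = 3,
    min_weekend_days: int = 1,
) -> tuple[ParticipantActivity | Rejection, list[DailySummary]]:
    """Full per-series pipeline: non-wear, classification, daily summaries, validity."""
    mask = detect_nonwear(series)
    labels = classify_epochs(series, mask, cuts)
    days = summarize_days(series, labels, mask)
    result = filter_valid(
        series.participant_id, series.wave, days, min_wear_h, min_days, min_weekend_days
    )
    return result, days


def read_counts_csv(
    path: str | Path, participant_id: str, wave: str, epoch_s: int | None = None
) -> EpochSeries:
    """Read a ``timestamp,counts`` CSV; epoch length inferred from the first two rows
    unless given."""
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    if epoch_s is None:
        if len(frame) < 2:
            raise ValueError("cannot infer epoch length from fewer than 2 rows")
        epoch_s = int(
            (frame["timestamp"].iloc[1] - frame["timestamp"].iloc[0]).total_seconds()
        )
    return EpochSeries(
        participant_id=participant_id,
        wave=wave,
        start_time=frame["timestamp"].iloc[0].to_pydatetime(),
        epoch_s=epoch_s,
        counts=frame["counts"].to_numpy(),
    )


def write_counts_csv(series: EpochSeries, path: str | Path) -> None:
    pd.DataFrame({"timestamp": series.timestamps(), "counts": series.counts}).to_csv(
        path, index=False
    )
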