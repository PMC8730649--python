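"""Physiological series, baseline statistics and change-from-baseline deltas.

Heart rate (bpm) and oxygen saturation (%) are exported from the bedside
monitor as a CSV keyed by subject and video-timeline time stamp. Pain
scoring needs, per scored epoch, the *maximum HR increase* over the resting
baseline mean and the *maximum SpO2 decrease* below the baseline mean —
both floored at zero, since the subscores reflect change in the painful
direction only.

Missing-data policy: malformed or out-of-range cells become missing values
with a logged warning; a baseline or epoch whose valid-sample coverage falls
below a threshold (default 50% of the expected count at the declared
sampling rate) yields missing statistics, and missingness only ever
propagates — it is never imputed away.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import ContextError, DuplicateSampleError, PhysioSchemaError

logger = logging.getLogger(__name__)

PHYSIO_COLUMNS = ["subject_id", "time_s", "heart_rate_bpm", "spo2_pct"]
CONTEXT_COLUMNS = [
    "subject_id",
    "corrected_ga_weeks",
    "corrected_ga_days",
    "behavioral_state",
]

#: Physiologically plausible ranges; values outside become missing.
HR_RANGE = (0.0, 300.0)     # exclusive bounds
SPO2_RANGE = (0.0, 100.0)   # (0, 100]

#: Default monitor export rate (Hz) when the study does not declare one.
DEFAULT_SAMPLING_RATE_HZ = 1.0

#: Minimum fraction of expected samples for a baseline/epoch statistic.
DEFAULT_COVERAGE_THRESHOLD = 0.5

#: Behavioral-state window at the start of baseline (seconds).
STATE_WINDOW_S = 15.0

#: The four ordered behavioral-state categories, from most active/awake
#: (lowest pain subscore) to deepest sleep (highest).
BEHAVIORAL_STATES = (
    "active_awake",
    "quiet_awake",
    "active_sleep",
    "quiet_sleep",
)


@dataclass(frozen=True)
class PhysioSample:
    """One monitor sample; either channel may be missing (``None``)."""

    time_s: float
    heart_rate_bpm: float | None
    spo2_pct: float | None


@dataclass(frozen=True)
class PhysioSeries:
    """Time-ordered samples for one subject."""

    subject_id: str
    samples: tuple[PhysioSample, ...]

    def __post_init__(self) -> None:
        times = [s.time_s for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DuplicateSampleError(
                f"series {self.subject_id!r}: sample times must be strictly "
                "increasing"
            )

    def window(self, interval: tuple[float, float]) -> tuple[PhysioSample, ...]:
        """Samples with time in the half-open ``interval``."""
        lo, hi = interval
        return tuple(s for s in self.samples if lo <= s.time_s < hi)


@dataclass(frozen=True)
class BaselineSummary:
    """Resting-baseline reference statistics for one subject.

    Channel means are ``None`` when that channel has no valid samples or
    coverage is below threshold. ``state_window`` is the first 15 s of the
    baseline, where behavioral state is assessed.
    """

    baseline_hr_bpm: float | None
    baseline_spo2_pct: float | None
    coverage_fraction: float
    state_window: tuple[float, float]

    @property
    def missing(self) -> bool:
        return self.baseline_hr_bpm is None and self.baseline_spo2_pct is None


@dataclass(frozen=True)
class EpochPhysioDelta:
    """Per-epoch change from baseline; ``None`` marks insufficient data."""

    phase: str
    epoch_index: int
    max_hr_increase_bpm: float | None
    max_spo2_decrease_pp: float | None


@dataclass(frozen=True)
class ContextInfo:
    """Contextual indicators fixed per subject on the procedure day."""

    corrected_ga_weeks: float
    behavioral_state: str

    def __post_init__(self) -> None:
        if not (20.0 <= self.corrected_ga_weeks <= 60.0):
            raise ContextError(
                f"corrected GA {self.corrected_ga_weeks} weeks outside "
                "plausible range [20, 60]"
            )
        if self.behavioral_state not in BEHAVIORAL_STATES:
            raise ContextError(
                f"behavioral_state {self.behavioral_state!r} not one of "
                f"{BEHAVIORAL_STATES}"
            )


def _clean_channel(
    values: pd.Series, lo: float, hi: float, *, closed_hi: bool, label: str
) -> pd.Series:
    numeric = pd.to_numeric(values, errors="coerce")
    bad_cells = numeric.isna() & values.notna()
    for idx in values.index[bad_cells]:
        logger.warning("malformed %s cell %r -> missing", label, values[idx])
    in_range = (numeric > lo) & ((numeric <= hi) if closed_hi else (numeric < hi))
    out_of_range = numeric.notna() & ~in_range
    for idx in numeric.index[out_of_range]:
        logger.warning("out-of-range %s value %s -> missing", label, numeric[idx])
    return numeric.where(in_range)


def parse_physio_csv(path_or_buf) -> list[PhysioSeries]:
    """Parse a physio CSV into one time-ordered series per subject.

    Required columns: ``subject_id, time_s, heart_rate_bpm, spo2_pct``.
    Malformed numeric cells become missing with a warning; duplicate
    (subject, time) rows are an error.
    """
    df = pd.read_csv(path_or_buf)
    missing_cols = set(PHYSIO_COLUMNS) - set(df.columns)
    if missing_cols:
        raise PhysioSchemaError(
            f"physio CSV missing columns: {sorted(missing_cols)}"
        )
    df = df.copy()
    df["time_s"] = pd.to_numeric(df["time_s"], errors="raise")
    dupes = df.duplicated(subset=["subject_id", "time_s"])
    if dupes.any():
        raise DuplicateSampleError(
            f"duplicate (subject_id, time_s) rows at index {list(df.index[dupes])}"
        )
    df["heart_rate_bpm"] = _clean_channel(
        df["heart_rate_bpm"], *HR_RANGE, closed_hi=False, label="heart_rate_bpm"
    )
    df["spo2_pct"] = _clean_channel(
        df["spo2_pct"], *SPO2_RANGE, closed_hi=True, label="spo2_pct"
    )
    series = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_s")
        samples = tuple(
            PhysioSample(
                time_s=float(t),
                heart_rate_bpm=None if pd.isna(hr) else float(hr),
                spo2_pct=None if pd.isna(sp) else float(sp),
            )
            for t, hr, sp in zip(
                grp["time_s"], grp["heart_rate_bpm"], grp["spo2_pct"]
            )
        )
        series.append(PhysioSeries(subject_id=str(sid), samples=samples))
    return series


def parse_context_csv(path_or_buf) -> dict[str, ContextInfo]:
    """Context CSV -> subject_id -> :class:`ContextInfo`.

    ``corrected_ga_weeks`` + ``corrected_ga_days`` combine to decimal weeks.
    """
    df = pd.read_csv(path_or_buf)
    missing_cols = set(CONTEXT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise PhysioSchemaError(
            f"context CSV missing columns: {sorted(missing_cols)}"
        )
    out: dict[str, ContextInfo] = {}
    for row in df.itertuples(index=False):
        out[str(row.subject_id)] = ContextInfo(
            corrected_ga_weeks=float(row.corrected_ga_weeks)
            + float(row.corrected_ga_days) / 7.0,
            behavioral_state=str(row.behavioral_state),
        )
    return out


def _coverage(
    n_valid: int, interval: tuple[float, float], sampling_rate_hz: float
) -> float:
    expected = (interval[1] - interval[0]) * sampling_rate_hz
    if expected <= 0:
        return 0.0
    return min(1.0, n_valid / expected)


def baseline_summary(
    series: PhysioSeries,
    baseline_interval: tuple[float, float],
    *,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> BaselineSummary:
    """Arithmetic-mean HR/SpO2 over the baseline interval.

    ``coverage_fraction`` is the smaller of the two channels' valid-sample
    fractions against the expected count at the declared sampling rate; a
    channel below ``coverage_threshold`` is reported missing.
    """
    window = series.window(baseline_interval)
    hr = [s.heart_rate_bpm for s in window if s.heart_rate_bpm is not None]
    sp = [s.spo2_pct for s in window if s.spo2_pct is not None]
    cov_hr = _coverage(len(hr), baseline_interval, sampling_rate_hz)
    cov_sp = _coverage(len(sp), baseline_interval, sampling_rate_hz)
    return BaselineSummary(
        baseline_hr_bpm=float(np.mean(hr)) if hr and cov_hr >= coverage_threshold else None,
        baseline_spo2_pct=float(np.mean(sp)) if sp and cov_sp >= coverage_threshold else None,
        coverage_fraction=min(cov_hr, cov_sp),
        state_window=(baseline_interval[0], baseline_interval[0] + STATE_WINDOW_S),
    )


def epoch_physio_delta(
    series: PhysioSeries,
    baseline: BaselineSummary,
    epoch_interval: tuple[float, float],
    *,
    phase: str = "",
    epoch_index: int = -1,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> EpochPhysioDelta:
    """Max HR increase / max SpO2 decrease in one epoch, floored at zero.

    A channel's delta is missing when the baseline mean is missing or the
    epoch's valid coverage for that channel is below threshold.
    """
    window = series.window(epoch_interval)
    hr = [s.heart_rate_bpm for s in window if s.heart_rate_bpm is not None]
    sp = [s.spo2_pct for s in window if s.spo2_pct is not None]
    cov_hr = _coverage(len(hr), epoch_interval, sampling_rate_hz)
    cov_sp = _coverage(len(sp), epoch_interval, sampling_rate_hz)

    hr_delta = None
    if baseline.baseline_hr_bpm is not None and hr and cov_hr >= coverage_threshold:
        hr_delta = max(0.0, max(hr) - baseline.baseline_hr_bpm)
    sp_delta = None
    if baseline.baseline_spo2_pct is not None and sp and cov_sp >= coverage_threshold:
        sp_delta = max(0.0, baseline.baseline_spo2_pct - min(sp))
    return EpochPhysioDelta(
        phase=phase,
        epoch_index=epoch_index,
        max_hr_increase_bpm=hr_delta,
        max_spo2_decrease_pp=sp_delta,
    )
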