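"""Quantized key-hold events and per-epoch presence quantification.

A coder marks a facial indicator as present by holding the coding key; each
hold is stored as a half-open interval ``[start_s, end_s)`` of video-timeline
seconds, quantized to the 0.2 s grid. This module turns a log of such holds,
plus the phase start points the coder set on the timeline, into one
presence duration and fraction per (phase, indicator, epoch) — the
measurements the facial subscores are computed from.

Conventions:

* Half-open intervals everywhere: a hold of exactly one quantum contributes
  0.2 s, and an instant sitting on an epoch boundary belongs to the later
  epoch, so nothing is double-counted.
* Overlapping holds for one indicator are unioned, not summed — presence is
  a state, not a count.
* Holds that fall entirely outside every scheduled epoch are dropped with a
  warning on the module logger, never an error: an interactive session
  cannot produce them, but replayed logs might.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import timegrid
from .errors import (
    DegenerateIntervalError,
    NegativeTimeError,
    PhaseStartError,
    UnknownIndicatorError,
    UnknownPhaseError,
)
from .templates import StudyTemplate, coding_schedule
from .timegrid import TimeGrid, DEFAULT_GRID, quantize_time

logger = logging.getLogger(__name__)

#: Integer-tick half-open interval.
TickInterval = tuple[int, int]


@dataclass(frozen=True)
class HoldEvent:
    """One key-hold: ``indicator`` present over ``[start_s, end_s)``."""

    indicator: str
    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise NegativeTimeError(f"start_s {self.start_s} < 0")
        if self.start_s >= self.end_s:
            raise DegenerateIntervalError(
                f"hold [{self.start_s}, {self.end_s}) has start >= end"
            )
        # Stored events must sit on the grid; quantize first if needed.
        timegrid.to_ticks(self.start_s)
        timegrid.to_ticks(self.end_s)

    @classmethod
    def from_raw(
        cls,
        indicator: str,
        phase: str,
        start_s: float,
        end_s: float,
        grid: TimeGrid = DEFAULT_GRID,
    ) -> "HoldEvent":
        """Quantize raw key-down/key-up times independently, then build.

        A raw hold that collapses to zero length after quantization raises
        :class:`~neopain.errors.DegenerateIntervalError`.
        """
        return cls(indicator, phase, quantize_time(start_s, grid), quantize_time(end_s, grid))

    @property
    def ticks(self) -> TickInterval:
        return (timegrid.to_ticks(self.start_s), timegrid.to_ticks(self.end_s))


@dataclass(frozen=True)
class PhaseStartSet:
    """Phase name -> start second on the video timeline, validated
    against a template: every phase present, starts strictly increasing in
    template order, and no phase span running past the next start."""

    starts: Mapping[str, float]

    def validated(self, template: StudyTemplate) -> "PhaseStartSet":
        missing = [p.name for p in template.phases if p.name not in self.starts]
        if missing:
            raise PhaseStartError(f"phase starts missing for: {missing}")
        prev_end_ticks = None
        prev_name = None
        for phase in template.phases:
            start = self.starts[phase.name]
            if start < 0:
                raise PhaseStartError(f"phase {phase.name!r} start {start} < 0")
            start_ticks = timegrid.to_ticks(start)
            if prev_end_ticks is not None and start_ticks < prev_end_ticks:
                raise PhaseStartError(
                    f"phase {phase.name!r} starts at {start} s, inside the "
                    f"span of preceding phase {prev_name!r}"
                )
            prev_end_ticks = start_ticks + phase.duration_ticks
            prev_name = phase.name
        return self

    def __getitem__(self, phase_name: str) -> float:
        try:
            return self.starts[phase_name]
        except KeyError:
            raise UnknownPhaseError(
                f"no start point recorded for phase {phase_name!r}"
            ) from None


@dataclass(frozen=True)
class EpochIndicatorResult:
    """Presence of one facial indicator in one epoch."""

    phase: str
    epoch_index: int
    indicator: str
    seconds_present: float
    fraction_present: float


def merge_intervals(
    intervals: Iterable[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Union of half-open intervals: sorted, pairwise-disjoint output.

    Adjacent intervals (end == next start) coalesce, which is the correct
    union under half-open semantics.
    """
    ticks = []
    for (a, b) in intervals:
        if a >= b:
            raise DegenerateIntervalError(f"interval [{a}, {b}) has start >= end")
        ticks.append((timegrid.to_ticks(a), timegrid.to_ticks(b)))
    merged = merge_tick_intervals(ticks)
    return [(timegrid.from_ticks(a), timegrid.from_ticks(b)) for a, b in merged]


def merge_tick_intervals(ticks: Sequence[TickInterval]) -> list[TickInterval]:
    """Sweep-line union on integer tick intervals."""
    if not ticks:
        return []
    out: list[list[int]] = []
    for a, b in sorted(ticks):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def clip_interval_to_epoch(
    interval: tuple[float, float], epoch_interval: tuple[float, float]
) -> tuple[float, float] | None:
    """Intersection of two half-open intervals; ``None`` when disjoint."""
    a = max(interval[0], epoch_interval[0])
    b = min(interval[1], epoch_interval[1])
    return (a, b) if a < b else None


def percent_time_present(
    events: Iterable[HoldEvent],
    epoch_interval: tuple[float, float],
    indicator: str,
    *,
    measure_indicators: Sequence[str] | None = None,
) -> EpochIndicatorResult:
    """Presence seconds/fraction for ``indicator`` within one epoch.

    ``seconds_present`` is the length of the union of this indicator's holds
    intersected with the epoch; the fraction divides by the epoch length.
    """
    if measure_indicators is not None and indicator not in measure_indicators:
        raise UnknownIndicatorError(
            f"{indicator!r} is not a behavioral indicator of the measure"
        )
    e0 = timegrid.to_ticks(epoch_interval[0])
    e1 = timegrid.to_ticks(epoch_interval[1])
    merged = merge_tick_intervals(
        [ev.ticks for ev in events if ev.indicator == indicator]
    )
    present = sum(
        min(b, e1) - max(a, e0)
        for a, b in merged
        if max(a, e0) < min(b, e1)
    )
    return EpochIndicatorResult(
        phase="",
        epoch_index=-1,
        indicator=indicator,
        seconds_present=timegrid.from_ticks(present),
        fraction_present=present / (e1 - e0),
    )


def compute_epoch_results(
    events: Iterable[HoldEvent],
    template: StudyTemplate,
    starts: PhaseStartSet,
) -> list[EpochIndicatorResult]:
    """Presence results for every coding pass of the template.

    Returns exactly one :class:`EpochIndicatorResult` per entry of
    :func:`~neopain.templates.coding_schedule`, zero-filled where no holds
    were logged. A hold contributes to every epoch it overlaps, so one that
    spans an epoch boundary is split and its duration conserved. Holds lying
    entirely outside the scheduled epochs of their phase are dropped and
    counted in a warning on the module logger.
    """
    starts = starts.validated(template)
    behavioral = template.measure.behavioral_indicators

    # phase -> indicator -> merged tick intervals
    by_key: dict[tuple[str, str], list[TickInterval]] = {}
    phase_names = {p.name for p in template.phases}
    n_dropped = 0
    for ev in events:
        if ev.phase not in phase_names:
            raise UnknownPhaseError(
                f"event references phase {ev.phase!r} not in template"
            )
        if ev.indicator not in behavioral:
            raise UnknownIndicatorError(
                f"event indicator {ev.indicator!r} not in measure "
                f"{template.measure.measure_id}"
            )
        by_key.setdefault((ev.phase, ev.indicator), []).append(ev.ticks)

    results: list[EpochIndicatorResult] = []
    consumed: dict[tuple[str, str], int] = {}
    spans: dict[str, tuple[int, int]] = {}
    for phase in template.phases:
        s = timegrid.to_ticks(starts[phase.name])
        spans[phase.name] = (s, s + phase.duration_ticks)

    for cp in coding_schedule(template):
        phase = template.phase(cp.phase)
        length_ticks = timegrid.to_ticks(phase.epoch_length_s)
        e0 = spans[cp.phase][0] + cp.epoch_index * length_ticks
        e1 = e0 + length_ticks
        merged = merge_tick_intervals(by_key.get((cp.phase, cp.indicator), []))
        present = sum(
            min(b, e1) - max(a, e0)
            for a, b in merged
            if max(a, e0) < min(b, e1)
        )
        results.append(
            EpochIndicatorResult(
                phase=cp.phase,
                epoch_index=cp.epoch_index,
                indicator=cp.indicator,
                seconds_present=timegrid.from_ticks(present),
                fraction_present=present / length_ticks,
            )
        )

    # Warn about holds wholly outside their phase's scheduled span.
    for (phase_name, indicator), ivs in by_key.items():
        lo, hi = spans[phase_name]
        for a, b in ivs:
            if b <= lo or a >= hi:
                n_dropped += 1
                logger.warning(
                    "dropped hold [%s, %s) for %s: outside scheduled epochs "
                    "of phase %r",
                    timegrid.from_ticks(a),
                    timegrid.from_ticks(b),
                    indicator,
                    phase_name,
                )
    if n_dropped:
        logger.warning("%d hold(s) fell outside all scheduled epochs", n_dropped)
    return results


# --- CSV interfaces ------------------------------------------------------

EVENT_COLUMNS = ["subject_id", "phase", "indicator", "start_s", "end_s"]
START_COLUMNS = ["subject_id", "phase", "start_s"]


def read_event_csv(path: str) -> dict[str, list[HoldEvent]]:
    """Event-log CSV (``subject_id, phase, indicator, start_s, end_s``)
    grouped by subject; rows are quantized on ingest."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DegenerateIntervalError(
            f"event CSV missing columns: {sorted(missing)}"
        )
    out: dict[str, list[HoldEvent]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            HoldEvent.from_raw(
                indicator=str(row.indicator),
                phase=str(row.phase),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
            )
        )
    return out


def read_starts_csv(path: str) -> dict[str, PhaseStartSet]:
    """Phase-starts CSV (``subject_id, phase, start_s``) grouped by subject."""
    df = pd.read_csv(path)
    missing = set(START_COLUMNS) - set(df.columns)
    if missing:
        raise PhaseStartError(f"starts CSV missing columns: {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), {})[str(row.phase)] = float(row.start_s)
    return {sid: PhaseStartSet(starts) for sid, starts in out.items()}
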