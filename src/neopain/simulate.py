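"""Synthetic coding sessions with known ground truth.

No recorded infant data ships with this package, so every downstream module
is exercised against simulated sessions: bout-structured facial-indicator
presence (alternating exponential on/off runs, rescaled to a target presence
fraction and snapped to the 0.2 s grid), Gaussian heart-rate/SpO2 baselines
with additive per-phase elevation/dip, and fixed contextual data.

Ground truth is defined from the *emitted* data, not the target parameters:
realized per-epoch fractions and deltas are recomputed here with direct
tick/array arithmetic after grid-snapping and value rounding, so pipeline
recovery can be asserted exactly, with no tolerance. Targets are only aimed
at; the truth is what was actually written.

All randomness flows through one ``numpy`` generator seeded from the
mandatory ``seed``; re-running with the same config is byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import timegrid
from .events import HoldEvent, PhaseStartSet, EVENT_COLUMNS, START_COLUMNS
from .physio import ContextInfo, EpochPhysioDelta, PHYSIO_COLUMNS
from .scoring import (
    PippResult,
    ScoringTable,
    SubscoreSet,
    compose_total,
    facial_subscore,
    ga_subscore,
    hr_subscore,
    spo2_subscore,
    state_subscore,
)
from .templates import (
    BROW_BULGE,
    EYE_SQUEEZE,
    NASOLABIAL_FURROW,
    StudyTemplate,
    expert_template,
)

#: Gap between the end of one phase's epochs and the next phase's start
#: marker on the simulated video timeline (seconds, on-grid).
DEFAULT_PHASE_GAP_S = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated session.

    ``presence`` maps (phase, indicator) to the target fraction of epoch
    time the indicator is held present. Physiological channels are Gaussian
    around resting means, shifted by per-phase elevation (HR) / dip (SpO2).
    """

    template: StudyTemplate
    seed: int
    presence: Mapping[tuple[str, str], float]
    bout_mean_s: float = 3.0
    baseline_hr_mean_bpm: float = 140.0
    baseline_hr_sd_bpm: float = 5.0
    hr_elevation_bpm: Mapping[str, float] = field(default_factory=dict)
    baseline_spo2_mean_pct: float = 97.0
    baseline_spo2_sd_pct: float = 1.0
    spo2_dip_pct: Mapping[str, float] = field(default_factory=dict)
    sampling_rate_hz: float = 1.0
    corrected_ga_weeks: float = 33.0
    behavioral_state: str = "active_awake"
    subject_id: str = "sim01"
    first_phase_start_s: float = 10.0
    phase_gap_s: float = DEFAULT_PHASE_GAP_S

    def __post_init__(self) -> None:
        for key, p in self.presence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"presence target {key} = {p} outside [0, 1]")
        if self.bout_mean_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("bout_mean_s and sampling_rate_hz must be positive")

    @property
    def context(self) -> ContextInfo:
        return ContextInfo(
            corrected_ga_weeks=self.corrected_ga_weeks,
            behavioral_state=self.behavioral_state,
        )


def uniform_presence(
    template: StudyTemplate, per_phase: Mapping[str, float]
) -> dict[tuple[str, str], float]:
    """Expand a per-phase target to every (phase, facial indicator) pair."""
    return {
        (phase.name, ind): per_phase[phase.name]
        for phase in template.phases
        for ind in template.measure.behavioral_indicators
    }


def default_config(seed: int, template: StudyTemplate | None = None) -> SimulationConfig:
    """A realistic heel-stick session on the expert template.

    Facial presence is near-absent at rest, strong during the stick and
    partially resolved in recovery; heart rate rises ~20 bpm and SpO2 dips
    ~6 points during the stick, with partial recovery after.
    """
    template = template or expert_template()
    per_phase: dict[str, float] = {}
    elevation: dict[str, float] = {}
    dip: dict[str, float] = {}
    for phase in template.phases:
        name = phase.name.lower()
        if name.startswith("baseline"):
            per_phase[phase.name], elevation[phase.name], dip[phase.name] = 0.05, 0.0, 0.0
        elif "stick" in name:
            per_phase[phase.name], elevation[phase.name], dip[phase.name] = 0.60, 20.0, 6.0
        else:
            per_phase[phase.name], elevation[phase.name], dip[phase.name] = 0.30, 8.0, 2.0
    return SimulationConfig(
        template=template,
        seed=seed,
        presence=uniform_presence(template, per_phase),
        hr_elevation_bpm=elevation,
        spo2_dip_pct=dip,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Realized measurements and expected scores of a simulated session."""

    #: (phase, epoch_index, indicator) -> realized presence fraction.
    fractions: Mapping[tuple[str, int, str], float]
    #: (phase, epoch_index) -> realized physiological delta.
    deltas: Mapping[tuple[str, int], EpochPhysioDelta]
    expected_results: tuple[PippResult, ...]


@dataclass(frozen=True)
class SessionBundle:
    """A complete schema-valid input set plus its ground truth."""

    config: SimulationConfig
    events: tuple[HoldEvent, ...]
    starts: PhaseStartSet
    physio: pd.DataFrame
    context: ContextInfo
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the four input CSVs plus a truth CSV; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sid = self.config.subject_id
        paths = {
            "events": out / "events.csv",
            "starts": out / "starts.csv",
            "physio": out / "physio.csv",
            "context": out / "context.csv",
            "truth": out / "truth.csv",
        }
        pd.DataFrame(
            [
                {
                    "subject_id": sid,
                    "phase": ev.phase,
                    "indicator": ev.indicator,
                    "start_s": f"{ev.start_s:.1f}",
                    "end_s": f"{ev.end_s:.1f}",
                }
                for ev in self.events
            ],
            columns=EVENT_COLUMNS,
        ).to_csv(paths["events"], index=False, lineterminator="\n")
        pd.DataFrame(
            [
                {"subject_id": sid, "phase": p.name,
                 "start_s": f"{self.starts[p.name]:.1f}"}
                for p in self.config.template.phases
            ],
            columns=START_COLUMNS,
        ).to_csv(paths["starts"], index=False, lineterminator="\n")
        self.physio.to_csv(paths["physio"], index=False, lineterminator="\n")
        ga_weeks = int(self.config.corrected_ga_weeks)
        ga_days = round((self.config.corrected_ga_weeks - ga_weeks) * 7)
        pd.DataFrame(
            [
                {
                    "subject_id": sid,
                    "corrected_ga_weeks": ga_weeks,
                    "corrected_ga_days": ga_days,
                    "behavioral_state": self.config.behavioral_state,
                }
            ]
        ).to_csv(paths["context"], index=False, lineterminator="\n")
        pd.DataFrame(
            [
                {
                    "subject_id": sid,
                    "phase": ph,
                    "epoch_index": k,
                    "indicator": ind,
                    "fraction_present": f"{frac:.4f}",
                }
                for (ph, k, ind), frac in sorted(self.truth.fractions.items())
            ]
        ).to_csv(paths["truth"], index=False, lineterminator="\n")
        return paths


def phase_starts(config: SimulationConfig) -> PhaseStartSet:
    """Deterministic phase start points with a fixed inter-phase gap."""
    starts: dict[str, float] = {}
    t = timegrid.to_ticks(config.first_phase_start_s)
    gap = timegrid.to_ticks(config.phase_gap_s)
    for phase in config.template.phases:
        starts[phase.name] = timegrid.from_ticks(t)
        t += phase.duration_ticks + gap
    return PhaseStartSet(starts)


def _bout_train(
    rng: np.random.Generator, span_ticks: int, p: float, bout_mean_s: float
) -> list[tuple[int, int]]:
    """On-intervals (ticks, phase-relative) of an alternating on/off train.

    Exponential on/off run lengths are drawn with means ``bout_mean_s`` and
    ``bout_mean_s * (1-p)/p``, rescaled so total on-time is exactly
    ``p * span`` before snapping each boundary to the grid.
    """
    span_s = timegrid.from_ticks(span_ticks)
    if p <= 0.0:
        return []
    if p >= 1.0:
        return [(0, span_ticks)]
    off_mean = bout_mean_s * (1.0 - p) / p
    starts_with_off = bool(rng.integers(0, 2))
    # Draw an alternating run-length train until it covers the span.
    segments: list[tuple[bool, float]] = []  # (is_on, duration)
    is_on = not starts_with_off
    total = 0.0
    while total < span_s or not any(on for on, _ in segments):
        d = rng.exponential(bout_mean_s if is_on else off_mean)
        segments.append((is_on, d))
        total += d
        is_on = not is_on
    # Rescale so the train is exactly span_s long with on-fraction p.
    total_on = sum(d for on, d in segments if on)
    total_off = sum(d for on, d in segments if not on)
    on_scale = p * span_s / total_on
    off_scale = (1.0 - p) * span_s / total_off if total_off > 0 else 0.0
    t = 0.0
    intervals: list[tuple[int, int]] = []
    for on, d in segments:
        if not on:
            t += d * off_scale
            continue
        a = timegrid.to_ticks(timegrid.quantize_time(min(t, span_s)))
        t += d * on_scale
        b = timegrid.to_ticks(timegrid.quantize_time(min(t, span_s)))
        if b > a:
            intervals.append((a, min(b, span_ticks)))
    # Snapping can create touching/overlapping neighbours; merge them.
    merged: list[list[int]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def simulate_events(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    starts: PhaseStartSet | None = None,
) -> tuple[list[HoldEvent], dict[tuple[str, int, str], float]]:
    """Simulate key-hold events; returns (events, realized fractions).

    Realized fractions are recomputed per epoch from the emitted on-grid
    intervals with direct tick arithmetic, not taken from the targets.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    starts = starts if starts is not None else phase_starts(config)
    events: list[HoldEvent] = []
    fractions: dict[tuple[str, int, str], float] = {}
    for phase in config.template.phases:
        phase_start_ticks = timegrid.to_ticks(starts[phase.name])
        epoch_ticks = timegrid.to_ticks(phase.epoch_length_s)
        for indicator in config.template.measure.behavioral_indicators:
            p = config.presence.get((phase.name, indicator), 0.0)
            train = _bout_train(rng, phase.duration_ticks, p, config.bout_mean_s)
            for a, b in train:
                events.append(
                    HoldEvent(
                        indicator=indicator,
                        phase=phase.name,
                        start_s=timegrid.from_ticks(phase_start_ticks + a),
                        end_s=timegrid.from_ticks(phase_start_ticks + b),
                    )
                )
            for k in range(phase.n_epochs):
                e0, e1 = k * epoch_ticks, (k + 1) * epoch_ticks
                present = sum(
                    min(b, e1) - max(a, e0)
                    for a, b in train
                    if max(a, e0) < min(b, e1)
                )
                fractions[(phase.name, k, indicator)] = present / epoch_ticks
    return events, fractions


def simulate_physio(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    starts: PhaseStartSet | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, int], EpochPhysioDelta]]:
    """Simulate the monitor export; returns (physio rows, realized deltas).

    Samples run from t=0 to the end of the last phase at the configured
    rate. Values are rounded to one decimal before truth is computed, so the
    CSV round-trips exactly. Realized deltas use the same max/min-vs-
    baseline-mean definitions as the scoring pipeline, recomputed here from
    the emitted values.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    starts = starts if starts is not None else phase_starts(config)
    template = config.template

    spans = {}
    for phase in template.phases:
        s = starts[phase.name]
        spans[phase.name] = (s, s + phase.duration_s)
    session_end = max(e for _, e in spans.values()) + config.phase_gap_s

    dt = 1.0 / config.sampling_rate_hz
    times = np.arange(0.0, session_end, dt)

    def active_phase(t: float) -> str | None:
        for name, (a, b) in spans.items():
            if a <= t < b:
                return name
        return None

    hr = rng.normal(config.baseline_hr_mean_bpm, config.baseline_hr_sd_bpm, len(times))
    sp = rng.normal(config.baseline_spo2_mean_pct, config.baseline_spo2_sd_pct, len(times))
    rows = []
    for i, t in enumerate(times):
        ph = active_phase(float(t))
        hr_i = hr[i] + (config.hr_elevation_bpm.get(ph, 0.0) if ph else 0.0)
        sp_i = sp[i] - (config.spo2_dip_pct.get(ph, 0.0) if ph else 0.0)
        rows.append(
            {
                "subject_id": config.subject_id,
                "time_s": round(float(t), 1),
                "heart_rate_bpm": round(float(np.clip(hr_i, 1.0, 299.0)), 1),
                "spo2_pct": round(float(np.clip(sp_i, 1.0, 100.0)), 1),
            }
        )
    df = pd.DataFrame(rows, columns=PHYSIO_COLUMNS)

    # Realized deltas from the emitted (rounded) values.
    t_arr = df["time_s"].to_numpy()
    hr_arr = df["heart_rate_bpm"].to_numpy()
    sp_arr = df["spo2_pct"].to_numpy()
    if not template.baseline_phases:
        raise ValueError("template has no baseline phase to reference")
    b0, b1 = spans[template.baseline_phases[0].name]
    in_base = (t_arr >= b0) & (t_arr < b1)
    base_hr = float(np.mean(hr_arr[in_base]))
    base_sp = float(np.mean(sp_arr[in_base]))

    deltas: dict[tuple[str, int], EpochPhysioDelta] = {}
    for phase in template.phases:
        a, _ = spans[phase.name]
        L = phase.epoch_length_s
        for k in range(phase.n_epochs):
            e0, e1 = a + k * L, a + (k + 1) * L
            mask = (t_arr >= e0) & (t_arr < e1)
            if not mask.any():
                deltas[(phase.name, k)] = EpochPhysioDelta(phase.name, k, None, None)
                continue
            deltas[(phase.name, k)] = EpochPhysioDelta(
                phase=phase.name,
                epoch_index=k,
                max_hr_increase_bpm=max(0.0, float(hr_arr[mask].max()) - base_hr),
                max_spo2_decrease_pp=max(0.0, base_sp - float(sp_arr[mask].min())),
            )
    return df, deltas


def expected_results(
    config: SimulationConfig,
    fractions: Mapping[tuple[str, int, str], float],
    deltas: Mapping[tuple[str, int], EpochPhysioDelta],
    table: ScoringTable,
) -> tuple[PippResult, ...]:
    """Expected per-epoch scores implied by the realized measurements."""
    template = config.template
    ga = ga_subscore(config.context, table)
    state = state_subscore(config.behavioral_state, table)
    out = []
    for phase in template.scored_phases:
        for k in range(phase.n_epochs):
            d = deltas[(phase.name, k)]
            subs = SubscoreSet(
                brow_bulge=facial_subscore(
                    fractions[(phase.name, k, BROW_BULGE)], table, BROW_BULGE
                ),
                eye_squeeze=facial_subscore(
                    fractions[(phase.name, k, EYE_SQUEEZE)], table, EYE_SQUEEZE
                ),
                nasolabial_furrow=facial_subscore(
                    fractions[(phase.name, k, NASOLABIAL_FURROW)],
                    table,
                    NASOLABIAL_FURROW,
                ),
                heart_rate=hr_subscore(d.max_hr_increase_bpm, table),
                oxygen_saturation=spo2_subscore(d.max_spo2_decrease_pp, table),
                gestational_age=ga,
                behavioral_state=state,
            )
            total, flags = compose_total(
                subs,
                template.measure.measure_id,
                conditional_contextual=table.conditional_contextual,
            )
            out.append(
                PippResult(
                    subject_id=config.subject_id,
                    phase=phase.name,
                    epoch_index=k,
                    measure_id=template.measure.measure_id,
                    subscores=subs,
                    total=total,
                    flags=flags,
                )
            )
    return tuple(out)


def simulate_session(config: SimulationConfig, table: ScoringTable) -> SessionBundle:
    """Simulate a complete session bundle with its ground truth."""
    rng = np.random.default_rng(config.seed)
    starts = phase_starts(config)
    events, fractions = simulate_events(config, rng, starts)
    physio, deltas = simulate_physio(config, rng, starts)
    truth = GroundTruth(
        fractions=fractions,
        deltas=deltas,
        expected_results=expected_results(config, fractions, deltas, table),
    )
    return SessionBundle(
        config=config,
        events=tuple(events),
        starts=starts,
        physio=physio,
        context=config.context,
        truth=truth,
    )
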