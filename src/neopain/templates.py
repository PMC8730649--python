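"""Study templates and the coding schedule derived from them.

A *study template* describes one painful-procedure recording protocol: which
pain measure is scored (PIPP or PIPP-R), and the ordered phases of the
procedure (e.g. baseline, stick, recovery), each split into fixed-length
epochs (typically 30 s). The template drives everything downstream: the
epoch grid on the video timeline, the sequence of coding passes (each epoch
is viewed once per facial indicator), and which epochs feed baseline
statistics versus pain scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from . import timegrid
from .errors import (
    DuplicatePhaseError,
    EmptyPhasesError,
    InvalidEpochCountError,
    InvalidEpochLengthError,
    MissingMeasureError,
    OffGridTimeError,
    TemplateValidationError,
    UnknownMeasureError,
)

#: Current template-document schema version.
SCHEMA_VERSION = 1

BROW_BULGE = "brow_bulge"
EYE_SQUEEZE = "eye_squeeze"
NASOLABIAL_FURROW = "nasolabial_furrow"
HEART_RATE = "heart_rate"
OXYGEN_SATURATION = "oxygen_saturation"
GESTATIONAL_AGE = "gestational_age"
BEHAVIORAL_STATE = "behavioral_state"


@dataclass(frozen=True)
class PainMeasure:
    """A multidimensional pain measure: ordered indicator lists by kind."""

    measure_id: str
    behavioral_indicators: tuple[str, ...]
    physiological_indicators: tuple[str, ...]
    contextual_indicators: tuple[str, ...]

    @property
    def all_indicators(self) -> tuple[str, ...]:
        return (
            self.behavioral_indicators
            + self.physiological_indicators
            + self.contextual_indicators
        )


_PIPP_INDICATORS = dict(
    behavioral_indicators=(BROW_BULGE, EYE_SQUEEZE, NASOLABIAL_FURROW),
    physiological_indicators=(HEART_RATE, OXYGEN_SATURATION),
    contextual_indicators=(GESTATIONAL_AGE, BEHAVIORAL_STATE),
)

#: Registry of implemented measures. Extensible in principle (plug-in
#: measures share the 0-3 subscore structure) but only PIPP and PIPP-R ship.
MEASURES: dict[str, PainMeasure] = {
    "PIPP": PainMeasure("PIPP", **_PIPP_INDICATORS),
    "PIPP-R": PainMeasure("PIPP-R", **_PIPP_INDICATORS),
}


@dataclass(frozen=True)
class Phase:
    """One procedure stage: ``n_epochs`` contiguous epochs of equal length."""

    name: str
    n_epochs: int
    epoch_length_s: float = 30.0

    def __post_init__(self) -> None:
        if not isinstance(self.n_epochs, int) or self.n_epochs < 1:
            raise InvalidEpochCountError(
                f"phase {self.name!r}: n_epochs must be a positive integer, "
                f"got {self.n_epochs!r}"
            )
        if self.epoch_length_s <= 0:
            raise InvalidEpochLengthError(
                f"phase {self.name!r}: epoch_length_s must be positive, "
                f"got {self.epoch_length_s!r}"
            )
        if not timegrid.is_on_grid(self.epoch_length_s):
            raise OffGridTimeError(
                f"phase {self.name!r}: epoch_length_s {self.epoch_length_s} "
                "is not a multiple of 0.2 s"
            )

    @property
    def duration_s(self) -> float:
        return timegrid.from_ticks(self.duration_ticks)

    @property
    def duration_ticks(self) -> int:
        return self.n_epochs * timegrid.to_ticks(self.epoch_length_s)


@dataclass(frozen=True)
class StudyTemplate:
    """A validated template: measure + ordered, uniquely-named phases."""

    template_id: str
    measure: PainMeasure
    phases: tuple[Phase, ...]
    #: Names of phases treated as resting baseline. Defaults to every phase
    #: whose name starts with "baseline" (case-insensitive).
    baseline_phase_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.phases:
            raise EmptyPhasesError(f"template {self.template_id!r} has no phases")
        names = [p.name for p in self.phases]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise DuplicatePhaseError(
                    f"template {self.template_id!r}: duplicate phase name {n!r}"
                )
            seen.add(n)
        if not self.baseline_phase_names:
            inferred = tuple(
                n for n in names if n.lower().startswith("baseline")
            )
            object.__setattr__(self, "baseline_phase_names", inferred)
        else:
            unknown = set(self.baseline_phase_names) - set(names)
            if unknown:
                raise TemplateValidationError(
                    f"baseline_phases names not in template: {sorted(unknown)}"
                )

    def phase(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def baseline_phases(self) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.name in self.baseline_phase_names)

    @property
    def scored_phases(self) -> tuple[Phase, ...]:
        """Phases whose epochs receive pain scores (non-baseline)."""
        return tuple(
            p for p in self.phases if p.name not in self.baseline_phase_names
        )


@dataclass(frozen=True)
class CodingPass:
    """One viewing of one epoch to code one facial indicator."""

    phase: str
    indicator: str
    epoch_index: int


def validate_template(doc: Mapping[str, Any]) -> StudyTemplate:
    """Build a :class:`StudyTemplate` from a parsed config document.

    The document is a mapping with keys ``template_id``, ``measure``
    (``PIPP`` | ``PIPP-R``), ``phases`` (list of ``{name, n_epochs,
    epoch_length_s}``) and optionally ``schema_version`` and
    ``baseline_phases``. Each schema violation raises its own named
    :class:`~neopain.errors.TemplateValidationError` subclass.
    """
    if not isinstance(doc, Mapping):
        raise TemplateValidationError("template document must be a mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise TemplateValidationError(
            f"unsupported template schema_version {version!r}"
        )
    if "measure" not in doc or doc["measure"] in (None, ""):
        raise MissingMeasureError("template document is missing 'measure'")
    measure_id = str(doc["measure"])
    if measure_id not in MEASURES:
        raise UnknownMeasureError(
            f"unknown measure {measure_id!r}; available: {sorted(MEASURES)}"
        )
    raw_phases = doc.get("phases") or []
    phases = []
    for raw in raw_phases:
        if not isinstance(raw, Mapping) or "name" not in raw:
            raise TemplateValidationError(f"malformed phase entry: {raw!r}")
        n_epochs = raw.get("n_epochs")
        if isinstance(n_epochs, float) and n_epochs.is_integer():
            n_epochs = int(n_epochs)
        phases.append(
            Phase(
                name=str(raw["name"]),
                n_epochs=n_epochs,
                epoch_length_s=float(raw.get("epoch_length_s", 30.0)),
            )
        )
    return StudyTemplate(
        template_id=str(doc.get("template_id", "unnamed")),
        measure=MEASURES[measure_id],
        phases=tuple(phases),
        baseline_phase_names=tuple(doc.get("baseline_phases", ())),
    )


def load_template(path: str) -> StudyTemplate:
    """Read and validate a YAML/JSON template file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return validate_template(doc)


def scheduled_duration(template: StudyTemplate) -> dict[str, float]:
    """Total scheduled coding time.

    ``per_indicator_s`` is the summed epoch time across phases (one full
    viewing of the video segments); ``total_s`` multiplies by the number of
    facial indicators, since every epoch is viewed once per indicator.
    """
    per_indicator_ticks = sum(p.duration_ticks for p in template.phases)
    n_behavioral = len(template.measure.behavioral_indicators)
    return {
        "per_indicator_s": timegrid.from_ticks(per_indicator_ticks),
        "total_s": timegrid.from_ticks(per_indicator_ticks * n_behavioral),
    }


def coding_schedule(template: StudyTemplate) -> list[CodingPass]:
    """Ordered coding passes: phase-major, then indicator, then epoch.

    Within a phase the coder works through all epochs for one facial
    indicator before switching to the next indicator, matching
    indicator-contiguous coding.
    """
    passes: list[CodingPass] = []
    for phase in template.phases:
        for indicator in template.measure.behavioral_indicators:
            for k in range(phase.n_epochs):
                passes.append(CodingPass(phase.name, indicator, k))
    return passes


def epoch_grid(phase: Phase, phase_start_s: float) -> list[tuple[float, float]]:
    """Contiguous half-open epoch intervals for a phase on the video timeline.

    Returns ``n_epochs`` intervals ``[start + k*L, start + (k+1)*L)``.
    """
    if phase_start_s < 0:
        raise OffGridTimeError(
            f"phase start must be non-negative, got {phase_start_s}"
        )
    start_ticks = timegrid.to_ticks(phase_start_s)
    length_ticks = timegrid.to_ticks(phase.epoch_length_s)
    return [
        (
            timegrid.from_ticks(start_ticks + k * length_ticks),
            timegrid.from_ticks(start_ticks + (k + 1) * length_ticks),
        )
        for k in range(phase.n_epochs)
    ]


def expert_template() -> StudyTemplate:
    """The four-phase expert-coder template.

    Two 2-epoch baselines followed by 4-epoch stick and recovery phases,
    30 s epochs, PIPP: 6 min of video per indicator, 18 min of coding.
    """
    return validate_template(
        {
            "template_id": "expert",
            "measure": "PIPP",
            "phases": [
                {"name": "baseline1", "n_epochs": 2, "epoch_length_s": 30.0},
                {"name": "baseline2", "n_epochs": 2, "epoch_length_s": 30.0},
                {"name": "stick", "n_epochs": 4, "epoch_length_s": 30.0},
                {"name": "recovery", "n_epochs": 4, "epoch_length_s": 30.0},
            ],
        }
    )


def novice_template() -> StudyTemplate:
    """The three-phase novice template: baseline, stick, recovery x 2 epochs."""
    return validate_template(
        {
            "template_id": "novice",
            "measure": "PIPP",
            "phases": [
                {"name": "baseline", "n_epochs": 2, "epoch_length_s": 30.0},
                {"name": "stick", "n_epochs": 2, "epoch_length_s": 30.0},
                {"name": "recovery", "n_epochs": 2, "epoch_length_s": 30.0},
            ],
        }
    )
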