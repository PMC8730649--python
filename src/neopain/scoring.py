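"""Subscore lookup tables and PIPP/PIPP-R total composition.

Each of the seven indicators maps through a four-bin lookup table to a
subscore 0-3 that rises with increasing change from baseline; the seven
subscores sum to a total of at most 21. Tables are configuration, loaded
from YAML and audited at load time (exactly four contiguous bins tiling the
measurement domain, subscores monotone along the axis). The defaults ship
with the package; see the provenance notes in the table files.

Missing policy: no imputation. A missing required subscore makes the total
missing, with a reason flag on the result — a pain score computed from
partial data would be misleading.

PIPP-R conditional rule: the two contextual subscores (gestational age,
behavioral state) are added only when the facial + physiological subtotal
is positive; an infant showing no behavioral or physiological response
scores 0 regardless of age or state.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .errors import (
    MeasureMismatchError,
    NegativeDeltaError,
    ScoringTableError,
    UnknownIndicatorError,
)
from .events import EpochIndicatorResult
from .physio import ContextInfo, EpochPhysioDelta
from .templates import (
    BEHAVIORAL_STATE,
    BROW_BULGE,
    EYE_SQUEEZE,
    GESTATIONAL_AGE,
    HEART_RATE,
    MEASURES,
    NASOLABIAL_FURROW,
    OXYGEN_SATURATION,
    StudyTemplate,
)

N_BINS = 4
MAX_SUBSCORE = 3
MAX_TOTAL = 21

CORE_INDICATORS = (
    BROW_BULGE,
    EYE_SQUEEZE,
    NASOLABIAL_FURROW,
    HEART_RATE,
    OXYGEN_SATURATION,
)
CONTEXTUAL_INDICATORS = (GESTATIONAL_AGE, BEHAVIORAL_STATE)


@dataclass(frozen=True)
class NumericBins:
    """Four half-open bins ``[edges[i], edges[i+1])`` over ``domain``; the
    top bin is closed at the domain maximum."""

    domain: tuple[float, float]
    edges: tuple[float, ...]
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != N_BINS + 1 or len(self.scores) != N_BINS:
            raise ScoringTableError(
                f"need exactly {N_BINS} bins ({N_BINS + 1} edges), got "
                f"{len(self.scores)} bins / {len(self.edges)} edges"
            )
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ScoringTableError(f"edges not strictly increasing: {self.edges}")
        if (self.edges[0], self.edges[-1]) != self.domain:
            raise ScoringTableError(
                f"bins {self.edges} do not tile domain {self.domain} "
                "(gap or overlap at the ends)"
            )
        if sorted(self.scores) != list(range(N_BINS)):
            raise ScoringTableError(
                f"scores must be a permutation of 0..3, got {self.scores}"
            )
        ascending = all(b > a for a, b in zip(self.scores, self.scores[1:]))
        descending = all(b < a for a, b in zip(self.scores, self.scores[1:]))
        if not (ascending or descending):
            raise ScoringTableError(
                f"scores must be monotone along the axis, got {self.scores}"
            )

    def lookup(self, value: float) -> int:
        lo, hi = self.domain
        if not (lo <= value <= hi):
            raise ScoringTableError(
                f"value {value} outside table domain [{lo}, {hi}]"
            )
        if value == hi:  # top bin closed above
            return self.scores[-1]
        for i in range(N_BINS):
            if self.edges[i] <= value < self.edges[i + 1]:
                return self.scores[i]
        raise ScoringTableError(f"no bin for value {value}")  # pragma: no cover


@dataclass(frozen=True)
class CategoricalBins:
    """Category -> subscore mapping (behavioral state)."""

    categories: Mapping[str, int]

    def __post_init__(self) -> None:
        if sorted(self.categories.values()) != list(range(N_BINS)):
            raise ScoringTableError(
                "categorical table must map exactly 4 categories onto 0..3, "
                f"got {dict(self.categories)}"
            )

    def lookup(self, category: str) -> int:
        if category not in self.categories:
            raise ScoringTableError(
                f"unknown category {category!r}; known: {sorted(self.categories)}"
            )
        return self.categories[category]


@dataclass(frozen=True)
class ScoringTable:
    """Per-indicator bins for one measure, audited on construction."""

    table_id: str
    measure_id: str
    bins: Mapping[str, NumericBins | CategoricalBins]
    conditional_contextual: bool

    def __post_init__(self) -> None:
        if self.measure_id not in MEASURES:
            raise ScoringTableError(f"unknown measure {self.measure_id!r}")
        expected = set(MEASURES[self.measure_id].all_indicators)
        if set(self.bins) != expected:
            raise ScoringTableError(
                f"table {self.table_id!r} indicators {sorted(self.bins)} != "
                f"measure indicators {sorted(expected)}"
            )

    def numeric(self, indicator: str) -> NumericBins:
        try:
            b = self.bins[indicator]
        except KeyError:
            raise UnknownIndicatorError(
                f"indicator {indicator!r} absent from table {self.table_id!r}"
            ) from None
        if not isinstance(b, NumericBins):
            raise ScoringTableError(f"indicator {indicator!r} is not numeric")
        return b


def _parse_bins(indicator: str, spec: Mapping) -> NumericBins | CategoricalBins:
    kind = spec.get("kind", "numeric")
    if kind == "categorical":
        return CategoricalBins(categories=dict(spec["categories"]))
    if kind != "numeric":
        raise ScoringTableError(f"{indicator}: unknown bin kind {kind!r}")
    edges = tuple(float(e) for e in spec["edges"])
    domain = tuple(float(d) for d in spec.get("domain", (edges[0], edges[-1])))
    return NumericBins(domain=domain, edges=edges, scores=tuple(spec["scores"]))


def parse_table(doc: Mapping) -> ScoringTable:
    """Build and audit a :class:`ScoringTable` from a parsed YAML document."""
    try:
        indicators = doc["indicators"]
    except (KeyError, TypeError):
        raise ScoringTableError("table document missing 'indicators'") from None
    return ScoringTable(
        table_id=str(doc.get("table_id", "unnamed")),
        measure_id=str(doc.get("measure", "")),
        bins={k: _parse_bins(k, v) for k, v in indicators.items()},
        conditional_contextual=bool(doc.get("conditional_contextual", False)),
    )


def load_table(path: str) -> ScoringTable:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_table(yaml.safe_load(fh))


def default_table(measure_id: str) -> ScoringTable:
    """The packaged default table for ``PIPP`` or ``PIPP-R``."""
    fname = {"PIPP": "pipp.yaml", "PIPP-R": "pipp_r.yaml"}.get(measure_id)
    if fname is None:
        raise MeasureMismatchError(f"no default table for measure {measure_id!r}")
    ref = resources.files("neopain.data.tables").joinpath(fname)
    return parse_table(yaml.safe_load(ref.read_text(encoding="utf-8")))


# --- subscore operations -------------------------------------------------

def facial_subscore(
    fraction_present: float, table: ScoringTable, indicator: str
) -> int:
    """Subscore for percent-of-epoch facial presence."""
    if not (0.0 <= fraction_present <= 1.0):
        raise ScoringTableError(
            f"fraction_present {fraction_present} outside [0, 1]"
        )
    return table.numeric(indicator).lookup(fraction_present)


def hr_subscore(
    max_hr_increase_bpm: float | None, table: ScoringTable
) -> int | None:
    """Subscore for max heart-rate increase; missing delta stays missing."""
    if max_hr_increase_bpm is None:
        return None
    if max_hr_increase_bpm < 0:
        raise NegativeDeltaError(
            f"HR increase {max_hr_increase_bpm} < 0 (floor violated upstream)"
        )
    return table.numeric(HEART_RATE).lookup(max_hr_increase_bpm)


def spo2_subscore(
    max_spo2_decrease_pp: float | None, table: ScoringTable
) -> int | None:
    """Subscore for max SpO2 decrease; missing delta stays missing."""
    if max_spo2_decrease_pp is None:
        return None
    if max_spo2_decrease_pp < 0:
        raise NegativeDeltaError(
            f"SpO2 decrease {max_spo2_decrease_pp} < 0 (floor violated upstream)"
        )
    return table.numeric(OXYGEN_SATURATION).lookup(max_spo2_decrease_pp)


def ga_subscore(context: ContextInfo, table: ScoringTable) -> int:
    """Subscore for corrected gestational age (lower GA -> higher score)."""
    return table.numeric(GESTATIONAL_AGE).lookup(context.corrected_ga_weeks)


def state_subscore(behavioral_state: str, table: ScoringTable) -> int:
    """Subscore for behavioral state (deeper sleep -> higher score)."""
    bins = table.bins[BEHAVIORAL_STATE]
    if not isinstance(bins, CategoricalBins):
        raise ScoringTableError("behavioral_state table must be categorical")
    return bins.lookup(behavioral_state)


# --- composition ---------------------------------------------------------

@dataclass(frozen=True)
class SubscoreSet:
    """The seven subscores, each 0-3 or ``None`` (missing)."""

    brow_bulge: int | None
    eye_squeeze: int | None
    nasolabial_furrow: int | None
    heart_rate: int | None
    oxygen_saturation: int | None
    gestational_age: int | None
    behavioral_state: int | None

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v is not None and v not in (0, 1, 2, 3):
                raise ScoringTableError(f"subscore {name}={v!r} not in 0..3")

    def as_dict(self) -> dict[str, int | None]:
        return {
            BROW_BULGE: self.brow_bulge,
            EYE_SQUEEZE: self.eye_squeeze,
            NASOLABIAL_FURROW: self.nasolabial_furrow,
            HEART_RATE: self.heart_rate,
            OXYGEN_SATURATION: self.oxygen_saturation,
            GESTATIONAL_AGE: self.gestational_age,
            BEHAVIORAL_STATE: self.behavioral_state,
        }

    @property
    def core(self) -> tuple[int | None, ...]:
        """Facial + physiological subscores (the five non-contextual)."""
        d = self.as_dict()
        return tuple(d[k] for k in CORE_INDICATORS)

    @property
    def contextual(self) -> tuple[int | None, ...]:
        d = self.as_dict()
        return tuple(d[k] for k in CONTEXTUAL_INDICATORS)


@dataclass(frozen=True)
class PippResult:
    """Scored epoch: seven subscores plus the composed total (0-21)."""

    subject_id: str
    phase: str
    epoch_index: int
    measure_id: str
    subscores: SubscoreSet
    total: int | None
    flags: tuple[str, ...] = ()


def compose_total(
    subscores: SubscoreSet, measure_id: str, *, conditional_contextual: bool | None = None
) -> tuple[int | None, tuple[str, ...]]:
    """Compose the total score; returns ``(total, reason_flags)``.

    PIPP sums all seven subscores. PIPP-R adds the contextual pair only when
    the facial + physiological subtotal exceeds zero (so a non-responding
    infant totals 0 even when contextual subscores are unknown). Any missing
    subscore that the rule requires makes the total missing.
    """
    if measure_id not in MEASURES:
        raise MeasureMismatchError(f"unknown measure {measure_id!r}")
    if conditional_contextual is None:
        conditional_contextual = measure_id == "PIPP-R"

    flags = tuple(
        f"missing:{name}" for name, v in subscores.as_dict().items() if v is None
    )
    core = subscores.core
    if any(v is None for v in core):
        return None, flags
    core_sum = sum(core)  # type: ignore[arg-type]

    if conditional_contextual and core_sum == 0:
        return 0, flags
    if any(v is None for v in subscores.contextual):
        return None, flags
    return core_sum + sum(subscores.contextual), flags  # type: ignore[arg-type]


def score_session(
    epoch_results: Iterable[EpochIndicatorResult],
    physio_deltas: Iterable[EpochPhysioDelta],
    context: ContextInfo | None,
    template: StudyTemplate,
    table: ScoringTable,
    *,
    subject_id: str = "",
) -> list[PippResult]:
    """One :class:`PippResult` per scored (non-baseline) epoch.

    Facial results are joined on (phase, epoch, indicator), physiological
    deltas on (phase, epoch). Join failures mark the affected subscores
    missing with a flag on that epoch's result; they are never fatal.
    Baseline-phase facial presence is accepted in the input (it is reported
    upstream) but baseline epochs are not scored.
    """
    if table.measure_id != template.measure.measure_id:
        raise MeasureMismatchError(
            f"table is for {table.measure_id!r}, template uses "
            f"{template.measure.measure_id!r}"
        )
    facial = {
        (r.phase, r.epoch_index, r.indicator): r.fraction_present
        for r in epoch_results
    }
    deltas = {(d.phase, d.epoch_index): d for d in physio_deltas}

    if context is not None:
        ga = ga_subscore(context, table)
        state = state_subscore(context.behavioral_state, table)
    else:
        ga = state = None

    out: list[PippResult] = []
    for phase in template.scored_phases:
        for k in range(phase.n_epochs):
            flags: list[str] = []
            fs: dict[str, int | None] = {}
            for ind in template.measure.behavioral_indicators:
                frac = facial.get((phase.name, k, ind))
                if frac is None:
                    flags.append(f"no_coding:{ind}")
                    fs[ind] = None
                else:
                    fs[ind] = facial_subscore(frac, table, ind)
            delta = deltas.get((phase.name, k))
            if delta is None:
                flags.append("no_physio")
                hr = sp = None
            else:
                hr = hr_subscore(delta.max_hr_increase_bpm, table)
                sp = spo2_subscore(delta.max_spo2_decrease_pp, table)
            if context is None:
                flags.append("no_context")
            subs = SubscoreSet(
                brow_bulge=fs.get(BROW_BULGE),
                eye_squeeze=fs.get(EYE_SQUEEZE),
                nasolabial_furrow=fs.get(NASOLABIAL_FURROW),
                heart_rate=hr,
                oxygen_saturation=sp,
                gestational_age=ga,
                behavioral_state=state,
            )
            total, reason = compose_total(
                subs,
                template.measure.measure_id,
                conditional_contextual=table.conditional_contextual,
            )
            out.append(
                PippResult(
                    subject_id=subject_id,
                    phase=phase.name,
                    epoch_index=k,
                    measure_id=template.measure.measure_id,
                    subscores=subs,
                    total=total,
                    flags=tuple(flags) + reason,
                )
            )
    return out
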