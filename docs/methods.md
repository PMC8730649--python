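# Methods

## Scope and model of the coding process

`neopain` models retrospective video coding of neonatal procedural pain as
a deterministic pipeline over four replayable inputs:

1. a **study template** — the pain measure (PIPP or PIPP-R) plus ordered
   phases, each with an epoch count and epoch length;
2. a **hold-event log** — half-open intervals `[start, end)` of
   video-timeline seconds during which the coder held the coding key for
   one facial indicator in one phase;
3. **phase start points** — where on the video timeline each phase begins
   (in the interactive original the coder sets these at on-screen markers;
   here they are data);
4. **physiological and contextual CSVs** — monitor samples of heart rate
   and SpO₂ keyed by subject and time, and per-subject corrected
   gestational age and behavioral state.

The engine derives the epoch grid from the template and the start points,
quantifies per-epoch facial presence, computes change-from-baseline
physiological deltas, maps all seven measurements through scoring tables to
0–3 subscores, and sums them to per-epoch totals (max 21).

## Time representation

Every boundary lives on a 0.2 s grid, matching the coding key's 200 ms
sampling. Internally times are integer *ticks* (1 tick = 0.2 s; seconds =
ticks/5), so interval union, intersection and length are exact integer
arithmetic with no floating-point drift; public APIs use seconds.
Quantization of raw key timestamps rounds to the nearest grid point, ties
away from zero, applied independently to key-down and key-up, so no input
moves by more than 0.1 s.

Intervals are half-open throughout: a one-quantum press contributes exactly
0.2 s, an instant on an epoch boundary belongs to the later epoch, and
adjacent holds coalesce under union. Overlapping holds for one indicator
are unioned, never summed — presence is a state. Holds entirely outside the
scheduled epochs are dropped with a logged warning (replay logs can contain
them; an interactive session cannot); a hold that *spans* an epoch boundary
is split, conserving total duration.

## Coding schedule

One coding pass = one viewing of one epoch for one facial indicator, so a
template schedules `Σ n_epochs × 3` passes. Pass order is phase-major, then
indicator, then epoch: within a phase the coder views all epochs for brow
bulge, then eye squeeze, then nasolabial furrow. The order is a package
convention fixed for determinism; per-indicator aggregate coding times are
consistent with indicator-contiguous passes either way.

## Physiological statistics

* Baseline statistic: arithmetic mean of HR and SpO₂ over the **first**
  baseline phase (templates may have two; the earliest resting state is
  used, configurable at the call site).
* Per-epoch deltas: `max(HR in epoch) − baseline mean` and
  `baseline mean − min(SpO₂ in epoch)`, both floored at 0, computed per
  scored epoch so each epoch owns its physiological subscores.
* Declared sampling rate: required input, default 1 Hz. Coverage of a
  window = valid samples / expected samples at that rate, per channel
  (reported as the channel minimum); a channel below the 50% coverage
  threshold yields a missing statistic. Thresholds are explicit keyword
  parameters, not hidden constants.
* Malformed or physiologically implausible cells (HR outside (0, 300) bpm,
  SpO₂ outside (0, 100] %) become missing with a logged warning; duplicate
  (subject, time) rows are an error.
* The behavioral-state window is the first 15 s of baseline; the state
  itself is an input category, one of four ordered levels from
  `active_awake` to `quiet_sleep`.

## Scoring tables and composition

Subscore breakpoints are configuration, not code: YAML tables with, per
indicator, four bins `[edges[i], edges[i+1])` (top bin closed at the domain
maximum) mapped to subscores that are monotone along the measurement axis —
ascending for facial fractions and physiological deltas, descending for
gestational age. Tables are audited at load: exactly four bins, strictly
increasing edges tiling the declared domain, scores a monotone permutation
of 0–3. The shipped defaults follow the published PIPP and PIPP-R
instruments (provenance noted in the files); studies with their own
calibrations edit the YAML.

Totals: PIPP sums all seven subscores. PIPP-R adds the contextual pair
(gestational age, behavioral state) only when the facial + physiological
subtotal is positive; when that subtotal is 0 the total is 0 even if the
contextual values are unknown. Missing data are never imputed: any missing
subscore the rule requires makes the total missing, with `missing:<name>`
reason flags on the result row. Baseline-phase epochs are coded for facial
presence (useful for group comparisons) but excluded from scoring.

## Synthetic sessions

The simulator stands in for recorded infant video. It emulates:

* **bout-structured facial presence** — alternating exponential on/off run
  lengths (mean on-bout 3 s), rescaled so each (phase, indicator) hits its
  target presence fraction exactly before grid-snapping, then snapped to
  0.2 s and merged;
* **physiology** — Gaussian samples around resting means (HR 140 ± 5 bpm,
  SpO₂ 97 ± 1%) with additive per-phase elevation/dip (defaults: +20 bpm
  and −6 points during the stick, +8 / −2 in recovery, 0 at baseline),
  emitted at 1 Hz and rounded to one decimal;
* **context** — fixed corrected GA (default 33 weeks) and state.

Ground truth is defined from the *emitted* data: realized per-epoch
fractions and deltas are recomputed inside the simulator with its own
direct tick/array arithmetic after snapping and rounding, so the test suite
can demand bit-exact recovery through the CSV round trip — the pipeline and
the simulator are independent code paths that must agree with zero
tolerance. Expected subscores apply the shared scoring tables to those
realized measurements.

What the simulator does **not** emulate: coder disagreement or reaction
latency, autocorrelated heart-rate dynamics, motion artifacts or signal
dropout structure, and any visual content. Passing tests therefore
demonstrate that the *engine* is exact and internally consistent, not that
human coding of real video is.

## Numerical and I/O choices

* Union length is checked against an independent brute-force oracle that
  samples membership on a 1 ms midpoint lattice; agreement is required to
  1e-9 s over a thousand random event sets.
* Output CSVs are RFC 4180, UTF-8, LF, header row mandatory; durations
  print with one decimal (sufficient for the 0.2 s grid), fractions with
  four. Identical inputs and seed give byte-identical outputs.
* Incremental coding output is appended row by row with flush + fsync after
  every data point, so a crash loses at most the in-flight row; final
  summaries are written atomically via temp-file rename. Truncation at any
  row boundary leaves a parseable file.
* All randomness flows through one `numpy` generator seeded explicitly;
  there is no global random state.
* Exit codes: 0 ok, 2 validation, 3 I/O, 4 join/consistency.

## Design choices where the design was open

* Baseline phases are recognized by the name prefix `baseline`
  (overridable with an explicit `baseline_phases` list in the template);
  protocols in this area conventionally name them so.
* Epochs within a phase share one length; heterogeneous epoch lengths have
  no use case in the supported protocols.
* Raw hold intervals are stored and per-epoch totals derived from them
  (rather than storing only totals), which also yields the 200 ms interval
  log useful for downstream automated-assessment work.
* The engine scores per epoch, not per phase; phase-level summaries are a
  reporting concern (`neopain report`).
* Problem sizes in the verification suite — a thousand random event sets
  against the sampling oracle, a hundred simulated sessions for recovery,
  the expert/novice protocol templates for arithmetic checks — were chosen
  to exercise every code path at desk scale; all checks are exact, so
  larger sizes would add runtime, not information.

## Known limitations

* Only PIPP and PIPP-R ship; the measure registry and table format are
  extensible but other instruments (FLACC, MBPS) are out of scope.
* No artifact rejection or filtering of physiological traces; the engine
  scores what the monitor exported.
* Clinical interpretation of totals (mild/moderate/severe cutoffs) and
  inter-rater reliability statistics are deliberately not provided.
* The PIPP-R conditional-contextual rule and all default breakpoints are
  sourced from the published instruments, not derived here; studies must
  verify the shipped tables against the instrument version they use.
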