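# neopain

A headless engine for research-grade coding and scoring of procedural pain
in neonates. It replaces the interactive parts of video-coding software with
replayable inputs: study *templates* describe the phases and 30-s epochs of
a painful procedure (e.g. heel stick); *hold events* record, at 200 ms
resolution, the intervals during which a trained coder marked each facial
pain indicator as present; physiological and contextual CSVs supply heart
rate, oxygen saturation, gestational age and behavioral state. From these
the engine computes per-epoch facial presence and composes
**PIPP** (Premature Infant Pain Profile) and **PIPP-R** scores.

It is intended for infant-pain researchers who code from video retro-
spectively and need a scriptable, testable scoring pipeline — and for
anyone who needs synthetic coding sessions with exact ground truth.

## The measure

The PIPP scores seven indicators, each on a 0–3 subscale that rises with
increasing change from baseline, summed to a maximum of 21:

| kind          | indicators                                         | measurement                           |
|---------------|----------------------------------------------------|---------------------------------------|
| behavioral    | brow bulge, eye squeeze, nasolabial furrow         | % of epoch time present               |
| physiological | heart rate, oxygen saturation                      | max increase / max decrease vs. resting baseline mean |
| contextual    | gestational age, behavioral state                  | corrected GA bands; 4 ordered state categories |

Each 30-s epoch is viewed three times, once per facial indicator; the
behavioral state is assessed in the first 15 s of the baseline phase. Under
PIPP-R the two contextual subscores are added only when the facial +
physiological subtotal is positive. Subscore breakpoints ship as editable
YAML tables (`src/neopain/data/tables/`) following the published PIPP and
PIPP-R instruments; see the provenance notes in those files.

All event times live on a 0.2 s grid (the coding key's resolution);
internally the engine works in integer ticks so interval arithmetic is
exact, and holds are treated as half-open intervals so epoch boundaries are
never double-counted.

## Worked example

Simulate a session on the built-in expert template (two 2-epoch baselines,
then 4-epoch stick and recovery phases), score it, and summarize:

```sh
neopain simulate --seed 9 --out session/
neopain score --template examples/expert_template.yaml \
    --coding session/events.csv --starts session/starts.csv \
    --physio session/physio.csv --context session/context.csv \
    --out results.csv
neopain report results.csv
```

which prints:

```
sim01 recovery: n=4 epochs, mean total=7.50, missing=0
sim01 stick: n=4 epochs, mean total=13.25, missing=0
```

Each scored epoch gets a row in `results.csv` with the seven subscores and
the total: here the simulated infant averages 13.25/21 during the heel stick
(strong facial response, ~20 bpm heart-rate rise, ~6-point SpO₂ dip) and
7.5/21 in recovery as the response partially resolves. Baseline epochs are
coded for facial presence but not scored. The same library calls are
available in Python:

```python
import neopain as npn

template = npn.expert_template()
npn.scheduled_duration(template)
# {'per_indicator_s': 360.0, 'total_s': 1080.0}   # 6 min x 3 indicators = 18 min
```

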