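# mobscore

Composite mobility scoring for older adults with lower-limb amputations of
vascular origin.

Rehabilitation assessments of amputees usually capture either what a person
*can* do in a clinic (balance, timed transfers, perceived locomotor
capability) or what they *actually* do at home and in the community — rarely
both, and rarely the personal and environmental factors in between. This
package implements a three-dimension mobility model for exactly that gap,
aimed at rehabilitation researchers and biostatisticians:

- **potential mobility** — capability measured in a clinical setting
  (Locomotor Capabilities Index, Timed Up and Go or its wheelchair-adapted
  variant, Berg Balance Test / Amputee Mobility Predictor);
- **effective mobility** — mobility realised in the person's own
  environment (Assessment of Life Habits daily activities and social roles,
  Life Space Assessment, Human Activity Profile);
- **modulators** — factors that can limit mobility past a published
  threshold (comorbidity, social support, coping, pain, obesity,
  depression, grip strength, protective foot sensation, and ten
  questionnaire risk factors).

## The scoring model

Each instrument score *x* is dichotomized against its published cut into
items *I ∈ {0, 1}* (0 = fail/negative, 1 = success/positive), e.g. TUG
fails if *t* > 14 s, LCI fails if total ≤ 21/42, BMI is a negative
modulator if > 30. Per dimension, the items actually assessed are summed
and rescaled to a common 0–4 range:

```
W = 4 · (Σ I) / n_assessed
```

so that participants with different battery lengths (missing or
inapplicable items) stay comparable. The unrounded *W* maps to a category

```
low: W < 1     moderate: 1 ≤ W < 3     high: 3 ≤ W ≤ 4
```

and the category triplet maps to a mobility profile group, effective
mobility deciding first:

- **A** — high effective mobility with jointly high potential mobility and
  positive modulators;
- **B** — high effective mobility otherwise;
- **C** — moderate effective mobility;
- **D** — low effective mobility.

Weighted scores are exact rationals internally; rounding (half-up, two
decimals) happens only at display time.

## Worked example

`python examples/score_pilot_fixture.py` scores the built-in deterministic
10-participant fixture (dichotomized outcome vectors for a heterogeneous
pilot cohort of prosthesis walkers, walking-aid users and wheelchair
users) and prints:

```
id    effective potential modulators  group
s01        2.00      0.00       1.75  C
s02        4.00      2.67       2.83  B
s03        2.00      1.33       1.90  C
s04        2.00      1.33       1.71  C
s05        3.00      0.00       2.29  B
s06        1.00      0.00       1.52  C
s07        1.00      0.00       2.10  C
s08        4.00      4.00       3.17  A
s09        1.00      0.00       1.14  C
s10        0.00      0.00       1.33  D

group sizes: {'A': 1, 'B': 2, 'C': 6, 'D': 1}
 modulator categories: {'moderate': 9, 'high': 1}
 potential categories: {'low': 6, 'moderate': 3, 'high': 1}
 effective categories: {'moderate': 6, 'high': 3, 'low': 1}
```

Each row is one participant's three weighted 0–4 scores and profile group:
s08 performs well everywhere (group A); s05 reaches high effective mobility
despite zero successful potential-mobility items (group B) — the
discrepancy the model is designed to surface; s10 is low on everything
that matters for realised mobility (group D). The 1.75 for s01 is 7
successful modulator items of 16 assessed, weighted out of four.

Other examples: `examples/dichotomize_measurements.py` (single raw
measurements against their thresholds) and `examples/simulate_and_score.py`
(a 200-participant synthetic cohort through the full CSV → profiles
pipeline).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch — the weighting-out-of-four
arithmetic for two partial-battery examples (1 of 3 items; 7 of 16 items)
and the profile-group sizes obtained by scoring the pilot fixture through
the full pipeline — and writes them as JSON.

## Layout

- `src/mobscore/registry.py` — instrument specs, threshold rules, norm
  tables, dichotomization, applicability gating, alternates groups
- `src/mobscore/scoring.py` — weighted composites, categories, profile
  groups, cohort summaries
- `src/mobscore/pilot.py` — the deterministic 10-participant fixture
- `src/mobscore/simulate.py` — configurable synthetic-cohort generator
- `src/mobscore/io.py` — cohort CSV dialect, pipeline runners, manifests
- `docs/methods.md` — model details, defaults and limitations
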