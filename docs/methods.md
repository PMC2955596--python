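# Methods

## Model

`mobscore` scores a 16-instrument assessment battery for lower-limb
vascular amputees along three dimensions — mobility **modulators**,
**potential** mobility and **effective** mobility — and groups
participants into four mobility profiles.

1. **Dichotomization.** Every instrument (or sub-item) has a fail rule on
   its native scale; evaluating a rule on an in-range value always yields
   success (1) or fail (0), never missing. Missing data propagate with a
   reason: *not evaluated* (session cut short), *not applicable*
   (instrument gated by mobility mode), *not collected* (instrument
   replaced mid-study or absent).
2. **Weighting.** Per dimension, `W = 4 · n_success / n_assessed` over the
   non-missing items, held as an exact `fractions.Fraction`. `n_assessed = 0`
   is an undefined score, not 0: the weighting rescales partial batteries,
   never absent ones, so such profiles are excluded from grouping with a
   logged reason rather than imputed.
3. **Categories.** Applied to the *unrounded* value: low `< 1`, moderate
   `1 ≤ W < 3`, high `3 ≤ W ≤ 4`. Display rounding is half-up to two
   decimals and happens only at reporting time (so 4/3 prints `1.33` but
   categorizes as the exact rational).
4. **Grouping.** Effective mobility decides first: high effective with
   jointly high potential and high (positive) modulators → A; high
   effective otherwise → B; moderate effective → C; low effective → D.
   The original pilot formed its groups empirically from ten subjects;
   this rule reproduces all observed assignments and totalizes the 27
   category triplets (e.g. high effective + high potential + moderate
   modulators → B). `assign_group` is a pure function and can be swapped
   out for a different grouping strategy.

## The battery and its thresholds

Fail conditions, taken literally from the published comparators (strict
vs inclusive matters and is covered by a boundary test sweep):

| dimension | item(s) | fail when |
|---|---|---|
| modulator | questionnaire ×10 flags | flag true (age > 60, below-knee amputation, ADL fatigue, daily cigarettes, daily alcohol, living alone/care centre, inaccessible environment, device dissatisfaction, other physical problem, lack of services) |
| modulator | Charlson | ≥ 2 |
| modulator | ISEL / MOS (one slot) | < 1/3 ; < 75/95 |
| modulator | WCQ ×3 aspects | distancing/avoidance mean > 1.5; support-seeking or reappraisal mean < 1.5 |
| modulator | BPI ×2 | Q5 > 5/10 ; Q9a > 7/10 |
| modulator | BMI | > 30 |
| modulator | GDS-30 | ≥ 11 |
| modulator | grip strength | ≤ 30th age/sex percentile cut |
| modulator | monofilament | any of 4 sites unfelt |
| potential | LCI | ≤ 21/42 |
| potential | TUG (prosthesis/aid) | > 14 s |
| potential | wheelchair TUG | > 34 s |
| potential | BBT / AMP (one slot) | < 45/56 ; < 25/47 |
| effective | LIFE-H ×2 domains | mean < 7/9 |
| effective | LSA | below the age-norm cut |
| effective | HAP (max activity score) | below the age-norm cut |

Notes on deliberately-resolved ambiguities:

- **GDS direction.** The source wording is self-contradictory; the
  conventional GDS-30 screening direction is used (depression, hence a
  negative modulator, at score ≥ 11). The rule is plain registry config
  and can be overridden.
- **Below-knee amputation** is kept as a *negative* questionnaire flag as
  listed in the battery, although amputation level is elsewhere described
  as supporting mobility; the polarity is config, not code.
- **Alternates groups.** ISEL was replaced mid-study by MOS, and BBT by
  AMP. Each pair occupies one composite slot; at most one member
  contributes per participant. If both were somehow assessed, the
  replacement instrument wins deterministically.
- **Modulator battery size.** The documented battery yields 21 modulator
  items; the originally-described maximum of 24 is not fully enumerable
  from the text. Nothing depends on the maximum: the denominator is
  always the number of items actually assessed.
- **Norm tables** (LSA, HAP, grip) ship as *synthetic placeholder* strata
  at plausible magnitudes, because the cited standards are not printed in
  the source. Replace them via `load_registry({"norms": ...})` for real
  analyses. Age bands must partition the supported range without overlap;
  lookups outside the bands are errors, never silent defaults.
- **BMI** is taken as weight/height² from recorded values; correcting for
  the missing limb's weight via anthropometric tables is out of scope.

## Pilot fixture

`generate_fixture_pilot()` returns ten participants at the
dichotomized-outcome level (the per-participant raw scores of the original
pilot are not publicly available). The vectors are constructed so that
scoring them reproduces every published aggregate exactly: potential
categories 6 low / 3 moderate / 1 high; effective weighted scores
{4/4 ×2, 3/4, 2/4 ×3, 1/4 ×3, 0/4}; modulators 9 moderate + 1 high with
the printed extremes 7/16 → 1.75 and 17/24 → 2.83 and the positive
participant at 19/24 → 3.17; groups A:1, B:2, C:6, D:1. Modulator items
use generic ids (`mod01`…`mod24`) since the exact item enumeration is not
recoverable; potential/effective vectors use real item ids. The split of
the three moderate potential-mobility participants between 1.33 and 2.67
is not published and was fixed arbitrarily (two at 1/3, one at 2/3); it
affects no published count. The fixture is seed-free; scoring it is an
exact regression test.

## Synthetic cohort generator

`generate_cohort(CohortConfig(...))` emulates a heterogeneous amputee
cohort: archetype mixture (prosthesis walker 0.4 / aid walker 0.3 /
wheelchair user 0.3), ages drawn from a truncated normal (mean 71, SD 9,
range 51–83, matching the pilot demography), 80% male, and per-item
negative-modulator prevalences chosen once at magnitudes plausible for an
elderly vascular-amputee population (high comorbidity, ~30% obesity,
frequent neuropathy and loss of grip strength, most participants over 60
and without rehabilitation services).

Sampling is *threshold-conditional*: each item first draws fail/success
with its configured probability, then draws the raw value from a truncated
normal restricted to the corresponding side of the cut (integer-scaled
instruments use integer side bounds). This makes configured prevalences
the exact expected fail rates, which the tests verify within three
binomial standard errors at n = 10⁴. Truncated normals (mean mid-scale,
SD a quarter of the scale unless overridden) were chosen for bounded
support and simplicity.

What the generator deliberately does **not** model: joint correlation
structure among instruments beyond archetype gating (no copulas — a
participant's pain and depression scores are independent given the
config), item-level instrument content, or longitudinal change. A green
simulation test therefore establishes the pipeline's statistical
contracts (prevalence recovery, gating, determinism, scale bounds), not
clinical realism of joint profiles.

Structural missingness is faithful to the source: the inapplicable TUG
variant is coded *not applicable*; the unassessed member of each
alternates pair is *not collected* (half the cohort uses the original
ISEL+BBT battery, half the replacement MOS+AMP, configurable). Random
*not evaluated* / *not collected* rates default to 2% / 1%. With the
random rates at zero, only the structural codes remain.

## Numerical choices

- Exact rational arithmetic for scores; equality and category comparisons
  never touch floats. Two-decimal half-up rounding at display only.
- Threshold comparisons use the raw float comparators — no epsilon — since
  the cuts and instrument scales are low-precision by construction.
- Cohort CSVs serialize floats via `repr` (shortest round-trip), making
  write→read an identity and simulated cohorts byte-stable per seed;
  scored outputs contain no timestamps (the run manifest carries the only
  one).
- Monofilament sham stimulations are an administration detail and not
  modelled; only the 4-site felt/unfelt vector is.

## Limitations

- The profile-group rule beyond the observed category combinations is this
  package's generalization; other totalizations are defensible.
- Placeholder norm strata mean absolute LSA/HAP/grip classifications from
  the default registry are illustrative until real standards are supplied.
- The fixture certifies aggregate reproduction, not individual raw-score
  reproduction, which is impossible without the unpublished per-participant
  table.
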