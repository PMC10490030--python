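# Methods

## The intake model

The package scores a semiquantitative FFQ: an ordered list of line items,
each with a food group, a standard portion (mass in g, or volume in mL
for juices and plant drinks), and one or more *member foods* pooled under
the item ("almonds/sunflower seeds"). The composition database stores,
per food, the content of the eight vitamin E isoforms in mg per 100 g of
edible portion, plus a separate manufacturer-fortification column
(`added_vit_e`).

For respondent *r* and item *i* with weekly serving count `s_ri`, the
daily intake vector is

    intake_r = Σ_i (s_ri / 7) · mean_{f ∈ members(i)} c_f · portion_i / 100

where `c_f` is food *f*'s per-100 g content vector. Everything is linear:
intake is homogeneous in serving counts and in portion mass, which the
property tests exploit. Accumulation runs in instrument order so outputs
are bit-reproducible. Assumptions baked into this model:

* **Unweighted pooling.** Member foods of a pooled item contribute with
  equal weight; no consumption-share weighting is attempted.
* **Density 1 for volumes.** mL portions are treated numerically as
  grams; the beverages concerned are near water density.
* **Fixed 7-day normalisation.** Servings are asked per week; no
  day-of-week weighting.
* **Missing data are errors.** Blank composition cells and (under the
  strict policy) unanswered items raise; a permissive mode maps both to
  zero with a logged warning and a per-respondent completeness fraction,
  because silent zeros bias intake downward invisibly.

One instrument row pools bread (35 g slice) with other whole-grain
products (75 g); a line item carries a single portion, so the built-in
instrument uses 75 g and records the bread slice in the household-measure
text. The three fish rows list open-ended examples and map to one
representative member food each, which puts the built-in member-food
enumeration at 67 products.

## α-tocopherol equivalents

    α-TE = 1.0·αT + 0.4·βT + 0.1·γT + 0.01·δT + 0.3·αT3 + 0.05·βT3 + 0.01·γT3 + 0·δT3

δ-tocotrienol is conventionally omitted from the equivalence (weight 0
here); users following a convention that assigns it, e.g., 0.01 can
override any weight (`ConversionWeights.with_overrides`). Added vitamin E
folds into α-TE with weight 1 by default (fortification is α-tocopherol
forms); it is never silently merged into the reported α-T column. With
all weights nonnegative and the default fold-in, α-TE ≥ α-T holds for
every vector — which is why a cohort whose mean α-TE is *below* its mean
α-T cannot arise from this formula; summary tables showing that pattern
are internally inconsistent and are not reproduced here.

## Adequacy classification

`value ≥ threshold(sex)` counts as adequate (inclusive boundary);
`value > UL` counts as exceeding the upper level (strict). Both
conventions are package choices — reference documents do not specify tie
handling — and matter only for values exactly on a limit. Each framework
is keyed to one metric (NIPH–NIH–NRI to α-TE; NIH and EFSA to α-T per
their definitional tables); user-defined frameworks load from YAML.
Percentages are kept at full precision and rounded only in report
writers.

## Agreement statistics

* **Bland–Altman**: differences are *signed* (a − b); bias is their mean;
  SD uses the n−1 denominator; limits of agreement are bias ± k·SD with
  k = 1.96. The index is 100 × (pairs strictly beyond the limits)/n;
  points exactly on a limit count as inside. `good_agreement` defaults to
  index ≤ 5% (≤10% is exposed as the "acceptable" alternative via the
  threshold argument). A zero-variance sample yields index 0 with a
  warning. Note some published tables label the bias "mean absolute
  difference" while printing signed limits symmetric about it; this
  package always means the signed bias.
* **Spearman / Mann–Whitney / Shapiro–Wilk** delegate to scipy.stats:
  midranks for ties with the t-approximation p-value; asymptotic U with
  tie and continuity corrections (appropriate at cohort scale, n ≈ 10²
  and up); Shapiro–Wilk as the gate, routing to the nonparametric path
  when either series rejects at p ≤ 0.05. Tests verify these against
  exhaustive small-n oracles (Pearson on midranks; pair counting
  #{a>b} + ½#{a=b}).

## The synthetic cohort generator

`gen_cohort` emulates a paired-method validation design. Weekly serving
counts per respondent × item are zero-inflated gamma draws; the second
"record" method observes the FFQ-implied true intake through
multiplicative lognormal noise and an optional additive per-component
bias, truncated at zero:

    record_j = max(0, true_j · e^ε + bias_j),  ε ~ N(0, σ²)

Sums and α-TE are recomputed from the noisy components, so record tables
are internally consistent. A single random stream ordered (respondent,
item) makes output identical across platforms for a fixed seed.

Defaults are fixed at a realistic adult validation cohort: **n = 447**,
**73% female**, servings ~ Gamma(1.2, 2.5) per week, **zero-inflation
0.7** (a respondent regularly consumes roughly 12 of the 41 items),
**σ = 0.35**, bias 0. Against the fixture composition database (group-
level lognormal contents: oils and nuts tocopherol-rich, whole grains
carrying the tocotrienols, β-T3 dominant; beverages diluted 20-fold)
this yields cohort means of roughly 12–13 mg/day α-T, ~22 mg/day total
tocopherols, ~0.9 mg/day total tocotrienols and ~14 mg/day α-TE — the
scale reported for adult European diets.

What the generator does **not** emulate: within-person day-to-day
variance (so no usual-intake deconvolution), correlated item preferences
(diet patterns), differential under-reporting of fats, seasonal effects,
or heaping of FFQ answers on whole and half servings. Passing tests
therefore demonstrate the pipeline's arithmetic and the estimators'
statistical behaviour under the stated model, not the field validity of
any particular questionnaire.

## Numerical choices and scale of the test problems

* Intake accumulation order is fixed; group subtotals reconcile with the
  daily total to 1e-9 relative.
* Oracle comparisons (double-loop re-summation) are asserted at 1e-12
  relative.
* Monte-Carlo checks use fixed seeds: the ~5% index check runs on 10,000
  i.i.d. normal differences with acceptance band [4, 6]; bias recovery
  uses n = 2000, σ = 0.05, tolerance ±0.2 mg (truncation at zero and the
  lognormal mean offset e^{σ²/2} are negligible at that σ). Unit and
  end-to-end tests run cohorts of 25–447 respondents; the full suite
  completes in well under a minute.

## Known limitations

* The package ships no real food-composition values; users supply their
  own table (the loader validates schema, sign, and duplicates). The
  fixture generator is synthetic and labelled as such.
* The asymptotic U and t p-values are inaccurate below n ≈ 15 per group;
  small-sample exact inference is out of scope (tests check the
  statistics, not small-n p-values).
* Only adult reference values are built in; children's and pregnancy
  DRIs, and EAR cut-point (probability-of-adequacy) methods, are out of
  scope.
* Bland–Altman here is the classical constant-bias form; regression-based
  (proportional-bias) and repeated-measures variants are not implemented.
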