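# Methods

## The stepwise attributable-fraction model

The quantity of interest is the fraction of HIV/AIDS deaths in a
population attributable to alcohol consumption *through the adherence
pathway only*: alcohol use → nonadherence to antiretroviral therapy
(ART) → increased mortality. Effects of alcohol on untreated disease
progression are outside the model, so the estimate is conservative with
respect to the total alcohol-attributable burden.

Because no single study covers the full pathway, the fraction is a
product of three components, each a function of two published inputs:

| component | formula | inputs |
|---|---|---|
| AdAF | `P_na(RR_na−1) / (1 + P_na(RR_na−1))` | nonadherence prevalence among treated patients; mortality risk ratio for nonadherence |
| NAAAF | `P_drink(RR_drink−1) / (1 + P_drink(RR_drink−1))` | current-drinker prevalence; nonadherence risk ratio for drinkers |
| PDT | `P_treat / (P_treat + HR_nontreat(1−P_treat))` | ART coverage; untreated-vs-treated mortality hazard ratio |

`AAF = AdAF · NAAAF · PDT`. AdAF appears in the literature in the
equivalent form `(P_adher + P_na·RR_na − 1)/(P_adher + P_na·RR_na)` with
`P_adher = 1 − P_na`; the package computes the simplified Levin form to
avoid cancellation, and the test suite asserts equality of the two forms
over random inputs. The complement `P_adher` is treated as deterministic
given `P_na` — no separate variance enters anywhere.

Key model assumptions: exposure is dichotomous (current drinker vs
abstainer; <95% vs ≥95% of doses), all input parameters are mutually
independent, and the prevalence of nonadherence *among drinkers* —
needed for the odds-ratio-to-relative-risk conversion — is approximated
by the whole-population nonadherence prevalence, a conservative choice.

## Variance propagation

Each component's variance is a first-order Taylor approximation in its
two inputs. For the Levin-form components,

    Var[AF] ≅ Var[P·RR] / (1 + P(RR−1))⁴,

where `Var[P·RR]` is the *exact* variance of a product of independent
variables, `Var[X]Var[Y] + E[Y]²Var[X] + E[X]²Var[Y]`. For PDT,

    Var[PDT] ≅ D_Ptreat² Var[P_treat] + D_HR² Var[HR_nontreat],

with partials `D_Ptreat = HR/(P_treat + HR(1−P_treat))²` and
`D_HR = P_treat(1−P_treat)/(P_treat + HR(1−P_treat))²` (each enters
squared, so signs are irrelevant). The AAF variance applies the product
identity twice: first to AdAF·NAAAF, then to (AdAF·NAAAF)·PDT.

Published CIs are converted to variances under an explicit reporting
assumption: ratios are log-symmetric (`Var[ln X] = ((ln U − ln L)/2z)²`,
mapped to the linear scale by `Var[X] ≅ X²Var[ln X]`), proportions are
linearly symmetric. The half-width is (full width)/2 regardless of where
the point estimate sits, so a mildly asymmetric published interval still
yields one well-defined variance. `z` defaults to 1.959964 (the standard
normal 97.5% quantile) and is configurable everywhere.

Ratio inversion (needed to turn the protective treated-vs-untreated rate
ratio 0.38 into the harmful direction, 2.63) preserves `Var[ln X]`
exactly and swaps the interval bounds. The odds-ratio→relative-risk
conversion `RR = OR/((1−P) + P·OR)` propagates variance through both
arguments with the partials `D_OR = (1−P)/((1−P)+P·OR)²` and
`D_P = OR(1−OR)/((1−P)+P·OR)²`. Note that at `OR = 1` the OR-partial is
`1−P`, the true derivative of the conversion — the variance does not
pass through unchanged even for a null association.

Uncertainty intervals are Wald-type on the fraction scale and
untruncated: a stratum with a weak effect can and should show an interval
crossing zero (the bundled North Africa/Middle East region does).

## Monte Carlo oracle

The analytic variances are validated, not assumed. The oracle samples
every input parameter independently — ratios log-normally with log-mean
`ln(value)` and log-SD `sqrt(Var[ln X])`; proportions from a normal
truncated (renormalized) to [0,1] by default, or a moment-matched beta
(`beta_matched`) for sensitivity — pushes each joint draw through the
deterministic chain, and compares the empirical variance and the central
2.5%–97.5% percentile interval with the delta-method results. The
percentile interval is reported alongside mean ± z·SD precisely because
it can expose asymmetry the delta method cannot represent.

Defaults: 200,000 draws; the seed is a required argument in the library
API (the CLI defaults to 20210214); per-stratum seeds in the full sweep
are spawned deterministically from the master seed. A sweep over all 30
bundled strata at the default size takes a few seconds on one core. The
validator gates "pass" on both variance and interval-width agreement
within a relative tolerance (default 10%).

On the bundled inputs the observed disagreement is at most ~1.6% for
variances and ~1% for widths. This is the small-coefficient-of-variation
regime where the first-order approximation is reliable; the test suite
also documents the caveat directly by scaling all input variances ×4 and
×16 and showing the delta-vs-MC discrepancy grows monotonically. For
inputs with large CVs the analytic variance should not be trusted
without re-running the oracle.

## Bundled data and units

The package ships three tables for the five African Global Burden of
Disease regions: ART coverage with lower/upper bounds (population-
weighted regional averages of 2005 country data), current-drinker
prevalence by sex × age band (men/women × 15–34/35–54/55+), and the four
risk parameters with 95% CIs. All proportions are stored internally as
fractions in [0,1]; every I/O document declares its unit explicitly
(`unit: fraction|percent`), removing the %-vs-fraction ambiguity common
in transcribed tables.

Drinker prevalences carry variance 0 by default because no interval is
published for them; the schema accepts optional lower/upper bounds for
users who have them. This means the bundled NAAAF variance reflects
`RR_drink` uncertainty only — a faithful representation of the available
inputs, not a claim that prevalence is known exactly.

The bundled `RR_drink = 1.82 (1.63, 2.04)` is consumed as published.
Applying the OR→RR conversion to the underlying adherence odds ratio of
0.604 yields ≈1.31 instead; the two are not reconcilable from the
printed inputs, so 1.82 is treated as an opaque input and the conversion
remains available for user-supplied odds ratios.

Region-level summaries in the qualitative checks use the mean AAF across
a region's six strata. This matters: a region can have the lowest
drinking prevalence yet not the lowest AAF in every matched stratum,
because low ART coverage elsewhere shrinks PDT; the region mean is the
summary under which "North Africa/Middle East has the smallest AAFs"
holds for the bundled data.

## Numerical and design choices

* AdAF/NAAAF use the simplified Levin form (better conditioned than the
  complement form near small fractions).
* Zero treatment coverage returns PDT = 0 with a logged warning rather
  than an error: under this model no treated deaths means no
  alcohol-attributable deaths via adherence.
* Zero-variance inputs propagate to exactly zero output variance and
  point-collapsed intervals; the MC oracle likewise reports exactly 0
  for constant draws (guarding against float summation noise).
* Results CSV is written with `%.17g` floats and read back with
  round-trip parsing, so write→read is the identity on every numeric
  field.
* Displayed percentages round half-to-even to two decimals in formatted
  output only; stored values keep full precision.
* Regional aggregation of country-level coverage goes through explicit
  user-supplied population weights (`weighted_coverage`); no country
  database is bundled, and the bundled regional values are used as
  given.

## What the tests do and do not show

The synthetic configurations in the tests (zero-variance parameter sets,
scaled-variance sweeps, constructed regions) exercise the estimator's
limiting behaviour and the oracle's sensitivity; they emulate the
*structure* of real inputs, not sampling noise in real surveys.
Agreement of the delta method with the Monte Carlo oracle on the bundled
inputs shows the approximation is adequate *for inputs of this
precision*; it does not validate the input estimates themselves, the
independence assumption, or the dichotomous exposure model. Known
limitations beyond that: no continuous dose–response for alcohol, no
correlated-parameter sampling, no morbidity outcomes, and no effect of
alcohol on untreated disease progression.
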