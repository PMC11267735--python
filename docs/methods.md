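# Methods

This note documents the models, conventions and numerical choices behind
`ffqval`, in the order data flow through the package.

## Instruments and their processing

**Frequency questionnaire.** The instrument is a fixed, ordered list of food
categories (108 in the packaged schema, grouped into 30 food groups)
answered on a nine-level ordinal frequency scale, plus three portion-photo
indications (levels 1–4) for the starch, protein and vegetable plates.
Levels map to representative intakes/day; the scale's endpoints are fixed
(*never* = 0, *4 times a day or more* = 4 intakes/day) and interior levels
use the arithmetic midpoint of each level's stated range: a couple of times
a year = 2/365.25, 1–3 per month = 2/30.44, once a week = 1/7, 2–3 per week
= 2.5/7, 4–6 per week = 5/7, once a day = 1, 2–3 per day = 2.5. The mapping
is data (YAML) and fully overridable, because published re-analyses differ
in these constants. Missing answers are imputed as 0 intakes/day and flagged
in provenance metadata; the alternative (pairwise deletion) is not offered
because a skipped frequency question most plausibly means *never*.

**Quality scoring.** Records are scored on the three-tier exclude scale used
by Northern-European diet databases: level 2 if any portion indication is
unanswered, level 1 if portions are complete but ≥10% of items are missing,
level 0 otherwise. The threshold comparison is `missing_fraction >= 0.10`
(weak inequality), so a record missing exactly 10% of its items is excluded.

**Portions.** Categories on a photo plate use the indicated plate's gram
value; categories with a natural unit (an egg, a glass, a slice) use that
unit's grams; all remaining categories fall back on a sex × 10-year-age-band
median table. The packaged plate grams, natural units and median table are
synthetic (order-of-magnitude realistic, marked as such); a study would
substitute its national tables. Age bands are half-open (`[30, 40)` …), so a
boundary age belongs deterministically to the band starting there. A missing
portion indication blocks nutrient estimation unless `default_impute=True`
(photo level 2), which is off by default because such records are exclude
level 2 anyway.

**Recalls.** Recall days arrive as long-format rows (participant, day, food,
grams, occasions). Foods map many-to-one onto the FFQ categories; daily
frequency per category is total occasions across days divided by the number
of completed days, and nutrients are amount-weighted composition sums
divided by days. A day with no items counts as completed if listed — a
fasting day is information. Mixed dishes count one occasion per mapped
category; how a dish decomposes is the map file's responsibility. The
validation group keeps participants with ≥4 completed days (configurable).

**Numerical convention.** Daily-frequency vectors are rounded at 1e-12 on
both the FFQ and recall paths, and food-group sums run over a C-contiguous
copy. Both choices exist so quantities that are identical by construction
are identical floats: at 1e-12 on values ≤ 4/day nothing scientific changes,
but rank ties — which tertile assignment resolves by stable participant
order — can no longer be broken by floating-point summation noise.

## Nutrients, misreporting, energy adjustment

Nutrient intake is Σ frequency × portion × content-per-gram over categories,
using a packaged synthetic composition table (energy + 14 nutrients per
100 g; energy is exactly consistent with the 4/9/4/7 kcal/g macronutrient
rule, and `check_energy_consistency` verifies any substituted table within a
configurable tolerance). Alcohol is treated as an ordinary composition
column with no special energy handling.

Resting energy expenditure uses the Henry weight-only equations by sex and
age band (18–30, 30–60, 60+), shipped in MJ/day as published and converted
at 239.006 kcal/MJ. The equation set is a config table because validation
results are sensitive to this choice. The misreporting ratio PAL = reported
energy / REE flags `severe_under` strictly below 0.7 and `implausible_over`
at or above 3.0 (weak inequality above, strict below); both thresholds are
configurable. Flagged participants are reported, highlighted, or excluded
according to the run's exclusion policy — the default reports everyone and
flags the outliers, mirroring how validation studies present both views.

Energy adjustment: the residual method regresses nutrient on energy by OLS
and adds the prediction at cohort-mean energy back to the residual (the
Willett convention — natural units preserved, zero sample correlation with
energy by construction); the density method rescales to units per
1,000 kcal, with zero-energy participants flagged NaN and excluded pairwise
downstream.

## Diet indices

Index specs are data: component group lists, cut rule (median / tertile /
quintile / range), direction, and points per rank class. Shipped defaults
follow the cited index families — rMED (9 components, tertiles 0–2, meat and
dairy reverse-scored, alcohol as a sex-specific moderate-range criterion
worth 2 points), HNFI (6 components, 1 point at/above the median), PDI (18
components, quintiles 1–5, animal groups reverse-scored) — and are defaults,
not reconstructions of any particular study's operationalisation. Cutoffs
are linear-interpolation quantiles computed within the scoring cohort and
per method (FFQ cutoffs for FFQ scores, recall cutoffs for recall scores);
values equal to a cutoff take the higher rank class (the *at/above median*
convention). A constant component degenerates to the lowest rank class for
everyone, with a warning.

## Statistics battery

**Correlations.** Spearman (average ranks for ties) for food groups, whose
intakes are right-skewed; Pearson (with Spearman alongside) for indices and
nutrients. Pairwise-complete over undefined values; zero variance yields an
undefined coefficient reported as NaN with a note rather than an error. No
multiple-testing correction is applied; p-values are reported raw.

**Tertile cross-classification.** Tertiles by ranked thirds with boundaries
at ceil(n/3) and ceil(2n/3); ties at a boundary resolve by stable input
(participant-id) order, so heavily zero-inflated foods classify
deterministically, with a warning when a tie actually straddles a boundary.
Reported: the 3×3 table, % same / adjacent / gross (opposite-extreme)
— which partition 100% — and % same within the lowest and highest reference
tertiles.

**Bland–Altman.** Differences (test − reference) against pair means. Two
intervals are reported explicitly, because method-agreement write-ups often
blur them: the 95% CI of the mean difference (t-based; the systematic-bias
band) and the conventional limits of agreement (mean ± 1.96 sd; the
individual-point band). Outside-point counts refer to the limits of
agreement. PAL-flagged participants are flagged in the exported plot data,
not removed.

**ICC.** Reproducibility of the two questionnaire administrations uses
ICC(A,k) — two-way model, absolute agreement, average of k measurements —
from ANOVA mean squares: (MSR − MSE)/(MSR + (MSC − MSE)/n), with ICC(A,1)
reported alongside. The 95% CI uses the F-based single-measure construction
with Satterthwaite degrees of freedom, stepped up to k measurements; it
matches pingouin's ICC2k to the stated tolerance in the test suite.
Qualitative bands: < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9) good,
≥ 0.9 excellent. Degenerate between-participant variance yields ICC ≤ 0,
reported as computed.

**PCA with Q².** Food-group matrices are log10(x + offset)-transformed
(offset 1.0 by default, admitting zeros) and each column centred and scaled
to unit variance (ddof = 1), so groups on different intake scales weigh
equally. Components come from the SVD with a deterministic sign convention
(largest-magnitude loading positive). R² is cumulative explained variance.
Q² = 1 − PRESS/SS with seven interleaved deletion groups over the row-major
cell sequence (*every seventh observation*, venetian blinds); cell-wise
deletion is the default and row-wise deletion is available
(`cv_pattern="rows"`). Held-out cells are predicted by refitting the
k-component model to the remaining cells via EM-style iterative imputation
(truncated-SVD refill to convergence). NIPALS-with-missing-data was
implemented first and rejected: its score regressions divide by sums over
observed loadings that can be arbitrarily small under structured
missingness, making later components blow up; the EM fit optimises the same
least-squares objective stably.

## Synthetic validation studies

The generator emulates the design of an FFQ-vs-24HDR validation study:
adults 35–64, ~61% women, measured heights/weights (BMI ~ N(26.1, 4.3²)), a
twice-administered FFQ, and six scheduled recall days with a completion
distribution under which ~76% of consenters reach the four-day rule and 93%
of those complete all six days — the study-flow shape such validation
cohorts report.

**Latent truth.** Per category, habitual frequency is log-normal
(per-category median and geometric SD in the schema resource) with a
Bernoulli never-consumer mask for episodic foods, truncated at the 4/day
scale ceiling. Half of each category's log-scale variance (configurable
`pattern_fraction`, default 0.5 over 2 factors) is shared across latent
dietary-pattern factors: real cohorts have correlated eating patterns, and
without them PCA has nothing to find. The factor construction preserves each
category's marginal log-normal law, so single-category analytics are
unaffected. The default strength puts 2-component PCA explained variance on
observed food groups in the ~20–25% range typical of food-group analyses.
True portions are log-normal around class- and sex-adjusted base portions.

**Error models.** The FFQ observes truth × bias × log-normal noise
(`ffq_noise_sd`, default 0.35 on the log scale), discretised to the nearest
of the nine mapped values with ties to the lower category; the repeat
administration redraws noise independently given truth (optional drift
factor). Portion indications are the plates nearest each participant's mean
true portion per plate class. Recall days draw Poisson occasion counts per
category per day — the within-person day-to-day variation the reference
method averages over — and day-level log-normal amount noise around the true
portion (one draw per participant-day-category cell; per-occasion draws
would add ragged bookkeeping with no effect on any computed statistic).
Generation is vectorised and bit-reproducible from (config, seed).

**Zero-error mode.** `ErrorModel.zero()` switches every noise source off and
makes recall occasions exact (possibly fractional) daily frequencies. In
this mode the generator snaps truth frequencies onto the nine scale values
and true portions onto the exactly assignable portion values
(`snap_truth_to_scale=None` applies this automatically when the error model
is exact), so both instruments reproduce truth identically and the full
pipeline must return all correlations = 1, all ICC = 1, 100% same-tertile
and zero Bland–Altman differences — the end-to-end identity the acceptance
tests verify.

**What the generator does not emulate** (hence what passing tests do not
show about real data): seasonality and weekday/weekend intake differences,
differential misreporting by BMI/sex/age, correlated FFQ errors across
categories, drift in true diet between administrations, mixed-dish mapping
ambiguity, and real food-composition error. Parameter-recovery results
certify the statistical machinery, not any particular instrument.

## Analytic predictions (`ffqval.theory`)

Conditional on a truth sample, the discretised FFQ reading's mean m(f) and
variance v(f) given a true frequency f are finite sums over the nine
discretisation cells with log-normal cell probabilities (cells are the
midpoint intervals of the mapped values; a zero truth reports *never* with
certainty). Because recall error is additive, zero-mean and independent of
FFQ error given truth:

- expected FFQ-vs-recall Pearson r = Cov(m(f), f) /
  sqrt((Var m + mean v)(Var f + mean f / k)) — the discretisation-aware
  attenuation law, reducing to the classic
  r · sqrt(σ_b²/(σ_b² + σ_w²/k)) with σ_w² = E[f] for Poisson counts;
- population ICC(A,k) of independent administrations =
  Var m / (Var m + mean v / k).

The parameter-recovery checks compare pipeline-measured statistics against
these predictions averaged over a 12-category panel of continuously consumed
foods per simulated study (n = 500, k = 6, 20 seeds, ±0.05): a single
category's Pearson estimate at n = 500 has sampling SD ≈ 0.03, so the
averaged comparison is what that Monte-Carlo design can actually resolve;
the band itself is not widened.

## Problem sizes and determinism

Default analyses run at the scale the package targets (hundreds of
participants, 108 categories): a full n = 244 study analysis takes about two
seconds, and the complete acceptance computation — including 20 × n = 500
recovery studies — well under a minute. All randomness flows from a single
integer seed through `numpy.random.default_rng`; no unordered iteration
touches any computed value, so outputs are byte-identical across runs and
platforms.

## Known limitations

- The shipped schema, portions and composition tables are synthetic stand-ins
  shaped like their real counterparts; absolute nutrient levels are
  order-of-magnitude realistic only.
- Index specs are literature-family defaults; a study replicating a specific
  published operationalisation must supply its own YAML.
- The Q² convention (cumulative 1 − PRESS/SS against the total sum of
  squares, k-component refit per deletion group) is one of several in use;
  chemometrics suites differ in per-component deflation details, so Q²
  values are comparable within this package, directionally comparable
  across software.
- ICC confidence intervals assume the balanced two-way layout with no
  missing cells; incomplete repeat data must be filtered first.
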