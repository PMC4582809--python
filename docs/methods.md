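# Methods

This note records the statistical conventions the package adopts, the
design decisions taken where the underlying methodology leaves choices
open, what the synthetic generators do and do not emulate, and known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Conceptual-structure statistics

Property norms are held as a concept × feature matrix of production
frequencies (non-negative integers; absent pairs are zero). Labels are
matched exactly as strings; the reader can optionally strip whitespace
but performs no case folding or lemma resolution.

**Distinctiveness.** `d_f = 1 / n_f`, where `n_f` is the number of
concepts listing feature *f*, so `d ∈ (0, 1]` and is strictly
decreasing in the count. This is the standard convention of
feature-based conceptual-structure models; the function is pluggable
(`distinctiveness_fn`) for variants.

**Shared features.** `n_f ≥ min_shared`, default 3.

**Significant pairwise correlations.** Pearson correlations between
shared features' production-frequency columns, computed across *all*
concepts in the norms. A pair is retained when its two-sided p < `alpha`
(default 0.05) and, by default, r > 0 (`positive_only`): negative
feature correlations are not interpreted as co-occurrence strength. The
exact significance criterion is not standardised in the literature, so
both knobs are explicit parameters.

**Correlational strength.** Feature level: the mean of a shared
feature's retained correlations with all other shared features,
norm-wide. Concept level: the mean over retained pairs *both of whose
features the concept possesses* — the concept-level statistic asks how
strongly that concept's own shared features cohere. A shared feature (or
concept) with no retained pair has strength *undefined*, represented as
NaN; undefined values never silently become 0.

**Correlation × distinctiveness.** Per concept, the unstandardised OLS
slope of feature-level correlational strength (response) on feature
distinctiveness (predictor) over the concept's features. Non-shared
features have no defined strength; by default they enter the regression
with strength 0 (`undefined_strength_as_zero`), because the measure
deliberately contrasts correlated shared features with weakly-correlated
distinctive ones — excluding distinctive features entirely would remove
the high-distinctiveness end of the regression. The flag can be turned
off to exclude them instead. The slope is undefined (NaN) with fewer
than two usable features or zero variance in distinctiveness.

**Cosine distance.** Computed over the full feature space of the norms;
for non-negative vectors it lies in [0, 1], is symmetric and
scale-invariant, and is 1 iff the vectors are proportional. A zero
vector is an error, not a 0 similarity.

## Lesion quantification

- Binarisation of interpolated warped masks uses **strict** `> 0.5`;
  the threshold convention leaves exact-0.5 voxels intact. Inputs must
  lie in [0, 1] up to 1e-6.
- Probability maps are the across-rater mean of binary drawings, so
  their values lie on {0, 1/n, …, 1} for n raters. The
  maximum-probability atlas assigns each voxel with positive maximum
  probability to the argmax ROI; exact ties are left undefined
  (background code 0), making the construction order-independent except
  at ties.
- Posterior truncation interprets the stored orientation record; under
  the default RAS convention, axis 1 is anterior–posterior with
  posterior = decreasing index. Voxels of the listed ROIs strictly
  posterior to the reference ROI's most posterior occupied coronal
  section become background.
- Damage is the mean lesion value over an ROI's voxels (= proportion
  damaged). Empty ROIs report NaN plus a flag, never 0. Left/right ROIs
  named `<name>_L` / `<name>_R` are pooled by default, matching cohorts
  that pool left- and right-lesion patients.
- Lesion volume is `(# lesioned voxels) · dx·dy·dz / 1000` cm³.
- Grids must match exactly; no resampling happens in this package
  (spatial normalisation is upstream).
- White matter is not modelled: a lesion that mostly destroys white
  matter under intact grey-matter ROIs will be under-quantified.

## Behavioural statistics

- Accuracy summaries compute participant means first, then the cell
  mean; SEM is over participants. Percentages are reported rounded to
  integers in table output, but all inference uses unrounded
  proportions.
- The **mixed-design ANOVA** uses the classical univariate contrast
  approach: each within effect is represented by orthonormal contrast
  variables over the within cells, tested against its own effect ×
  subjects-within-groups error stratum; the group effect is a one-way
  ANOVA on subject means. With unequal group sizes, purely-within
  effects use unweighted group means (Type III), matching SPSS and
  `car::Anova(type = 3)`, against which the implementation is verified
  in the tests (pingouin, which weights by group size, agrees at equal
  n). Greenhouse–Geisser correction is available for within factors
  with more than two levels and off by default. A within design must be
  balanced (every participant × cell present); missing cells are an
  error that lists them.
- t tests: pooled, Welch–Satterthwaite or paired. `tail="one"` takes
  the p in the declared direction (and flags results opposite to it).
  Zero variance in both samples with equal means returns t = 0, p = 1,
  flagged; zero variance with unequal means is an error.
- The item-wise ANCOVA treats items as observations:
  `accuracy ~ group + covariate + group:covariate` on long-format
  item × group mean accuracies; the reported interaction df follow from
  the data actually supplied rather than being forced to any particular
  published value, since the exact composition of item sets in any given
  study is not recoverable from summary tables.
- Per-participant accuracy–covariate effects are item-wise
  point-biserial Pearson correlations, Fisher transformed
  (`z = atanh r`). |r| = 1 yields infinite z; such participants are
  flagged and excluded from downstream damage correlations.
- Missing responses score 0 (logged). Tail convention: omnibus ANOVAs
  are two-tailed; directional follow-ups take an explicit one-tailed
  argument.

## Damage–effect correlations

Spearman's rho is the Pearson correlation of mid-ranks; p comes from the
t approximation with n − 2 df. At the cohort sizes this package targets
(n = 6–8) the t approximation is slightly conservative — its true
one-tailed size at n = 8 and α = 0.05 is about 4.8% by full enumeration,
which the calibration simulation confirms — and an `exact` flag computes
the permutation null by full enumeration for n ≤ 8. The partial Spearman
rank-transforms all three vectors and applies the first-order partial
Pearson formula with df = n − 3. ROIs with nonzero damage in fewer than
3 patients are excluded from correlation tables (rank correlations over
one or two informative points are uninterpretable). No multiple-testing
correction is applied by default; a Holm option exists. The hypothesised
sign of each effect's correlation with damage is declared per effect
(negative for accuracy scores, positive for damage-increases-effect
scores).

## Synthetic generators

All generators are pure functions of (config, seed); identical seeds
give identical outputs, and child seeds for repeated simulations are
spawned with `numpy.random.SeedSequence`.

**Norms.** Each domain gets its own pool of shared features; shared
features are created one at a time, each assigned to 3–5 concepts chosen
greedily by largest remaining deficit from the domain's target mean
(random tie-break), with a top-up pass widening existing features, so
the realised mean shared-feature count equals `round(n·target)/n`
exactly. Defaults: 30 living concepts at 12.7 shared features and 30
nonliving at 11.1 — the living > nonliving asymmetry that makes living
things more confusable — plus 5 unique distinctive features per concept.
Production frequencies are truncated-geometric counts on {1..30}
(p = 0.25), emulating the small positive integers of real norms. The
generator records ground-truth per-concept shared counts, which the
pipeline's feature statistics must (and do) recover exactly.

What it does **not** emulate: cross-domain feature sharing, taxonomic
features, correlated feature co-occurrence structure beyond what the
shared/distinctive split induces, or realistic feature counts per
concept (real norms are sparser and heavier-tailed). Passing tests
therefore validate the *computations*, not distributional claims about
real norms; statistics that depend on the real CSLB norms (e.g. the
close/distant cosine means of 0.69/0.20) are not reproducible here.

**Lesion cohorts.** Six disjoint ROI boxes on a 32 × 32 × 16 grid of
1 mm voxels; per-patient target damage fractions are met by filling ROI
voxels in raster order to the rounded count (a stochastic placement mode
exists), so realised fractions are exact ground truth. Default cohort: 8
patients with PRc damage 0.0–0.7 and partially co-varying neighbouring
damage. Real lesion morphology, registration error and smoothing are
deliberately out of scope.

**Behaviour.** Per participant × item Bernoulli draws with
`logit P(correct) = β₀ + β_dmg·d + β_int·d·s_i`, where `d` is PRc damage
and `s_i` the item's standardised correlation × distinctiveness slope.
Defaults β₀ = 2.75 (≈ 94% baseline accuracy, the control level),
β_dmg = −3, β_int = 3 (a strong interaction, the power-analysis
setting). Optional Gaussian logit noise and participant random
intercepts are off by default.

## Calibration and problem sizes

The simulation harnesses in `confusel.calibration` use: 400 null
cohorts (8 patients, 60 items) for the type-I rate of the one-tailed
damage-effect test; 500 label shuffles of one Gaussian dataset (30
participants, 2 within cells) for the uniformity of mixed-ANOVA group
p-values; and 200 cohorts of 8 patients × 200 items, with norms
regenerated per cohort, for power/parameter recovery. These sizes give
Monte-Carlo standard errors of about 1.1 points on the type-I
percentage and 2 points on the power percentage, small relative to the
bands being checked, while keeping the whole recomputation around a
minute on one CPU.

## Degenerate inputs and numerical choices

- Undefined statistics propagate as NaN (never silently 0), with the
  single documented exception of the slope regression's
  `undefined_strength_as_zero` flag.
- Pearson p-values use the exact t transform of r (equivalent to
  scipy's); retention thresholds are strict inequalities (`p < alpha`).
- Constant vectors are errors for correlations; zero-residual ANOVA
  strata report F = 0, p = 1 with a degeneracy flag when the effect sum
  of squares is also zero.
- Damage-fraction targets are validated to be achievable within one
  voxel at the grid resolution.
- Exact string matching throughout; naming responses are compared
  case-folded and trimmed.

## Known limitations

- The package analyses accuracy only (no reaction times) and ROI-based
  damage only (no voxel-based lesion-symptom mapping).
- Group summaries recomputed from integer-rounded per-patient tables
  can differ from summaries computed on unrounded data by up to one
  percentage point; comparisons against published summary rows should
  allow for that resolution.
- The mixed ANOVA requires a balanced within design; it does not fit
  mixed-effects models for unbalanced or trial-level data.
- The partial Spearman uses the rank-transform-then-partial-Pearson
  convention; other conventions (e.g. partialling before ranking) give
  slightly different values.
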