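# Methods

This note describes the statistical machinery implemented in
`ecmclock`, the defaults it ships with, and what the synthetic study
conditions can and cannot demonstrate.

## Data model

A cohort couples a strictly positive samples × proteins abundance
matrix (aptamer-style relative fluorescence units) with per-sample
metadata (age — years for humans, months for mice — sex, optional BMI
and cohort labels, species, parabiosis group). Samples with any
missing proteomic value are dropped at load time, so downstream models
never handle missingness; operations requiring an absent covariate fail
loudly rather than impute. Sex enters models as a 0/1 indicator (F=0,
M=1); any consistent coding gives identical fits up to the intercept.
The protein annotation table assigns each analyte a matrisome division
(core / associated / non-matrisome) and category (collagens, ECM
glycoproteins, proteoglycans; secreted factors, ECM regulators,
ECM-affiliated), plus SASP and druggability flags; division is derived
from category so the two can never disagree. Each aptamer/protein id is
treated as an independent analyte; no collapsing of duplicate aptamers
per gene is attempted.

## Aging signature

Per protein, OLS of (optionally log2) abundance on age plus covariates.
Because all proteins share one design matrix, the whole proteome is
fitted through a single solve of the normal equations; p-values come
from the two-sided t-test on the age coefficient, and FDR adjustment is
Benjamini–Hochberg over all fitted proteins. "Standardized abundance"
means per-protein z-scoring across the cohort before fitting (age stays
in natural units), which rescales effects by 1/SD without changing
p-values. Standardization operates on abundance as loaded; the `log2`
switch is exposed because the clock stage works on log2 values while
the association stage does not require it. Zero-variance proteins are
flagged and excluded from the FDR pool; a rank-deficient design raises
an error naming the covariates.

The replicated aging matreotype is the set of matrisome proteins with
q < 0.05 in both cohorts and the same effect sign. Age-group contrasts
(e.g., against a centenarian-style oldest bin) use the unpaired
two-sided Wilcoxon rank-sum on per-sample mean standardized signature
abundance, exact when the combined n ≤ 20 and tie-free, normal
approximation with tie correction otherwise, BH-adjusted over bins.

## Trajectories

Per-protein z-scores are smoothed against age by local quadratic LOESS
(tricube weights, span 0.75 — the classic defaults) evaluated on an
evenly spaced 101-point grid covering the observed age range (no
extrapolation). No installed Python library offers degree-2 LOESS, so
the local regression is implemented here and cross-checked in the test
suite against R's `stats::loess(degree = 2, span = 0.75,
surface = "direct")`, agreeing to ~1e-14. Because all proteins share
the ages, the weighted normal equations per grid point are solved once
with all proteins as right-hand sides.

Smoothed curves (not raw per-sample z-scores) are clustered:
complete-linkage agglomerative clustering on Euclidean distance between
grid curves, cut at a fixed height (default 5.0; 7.5 documented for
shorter-age-range replication cohorts). Curves enter in lexicographic
protein-id order, making assignments invariant to input order; merge
heights are verified against an O(n³) naive complete-linkage oracle.
Cluster-level matrisome enrichment is the upper-tail hypergeometric
test with the full measured proteome as background, BH over clusters.
The SASP contrast reports mean curves per (category × SASP flag) with
pointwise normal-approximation 95% bands (omitted for single-protein
strata).

## Matreotypes and enrichment statistics

**Disease matreotype.** Chapters (ICD-10-style) with at least 10
distinct phenotypes are retained. Within each retained chapter,
matrisome proteins with at least one significant association
(p < 1e-5) are ranked by distinct-phenotype count; the threshold is the
count at the ⌈n/2⌉-th largest rank and retention uses ≥, so boundary
ties can push retention above 50%. The final set intersects the
per-chapter sets. This rule is monotone: adding associations for a
protein can only improve that protein's standing.

**Chapter enrichment.** Per chapter, log2 of (fraction of matrisome
proteins associated with the chapter / same fraction among
non-matrisome proteins), with a two-sided Fisher exact test on the 2×2
membership table and Bonferroni adjustment over chapters. The exact
test is used because it is valid at any count; zero denominators yield
±∞ sentinels with the exact p still reported.

**Composition test.** Observed category (or core/associated) counts of
a signature are compared with expected counts from the full matrisome's
proportions via the chi-squared goodness-of-fit statistic. Standardized
residuals use the goodness-of-fit form (O−E)/√(E·(1−p)), which is
asymptotically standard normal, so the ±1.96 significance reading is
exact in form; the plain Pearson residual (O−E)/√E is available via
`residual_form="pearson"`. When any expected count is below 5 or the
signature has fewer than 40 proteins, the p-value comes from a seeded
2000-replicate multinomial Monte Carlo with
p = (#simulated ≥ observed + 1)/2001.

**Burden and prioritization.** Disease burden compares distinct
significant phenotype counts per protein (ECM vs non-ECM overall;
per category vs non-ECM with Bonferroni over the six categories) by
rank-sum tests. Target prioritization consumes a precomputed
Mendelian-randomization table, keeps Wald-ratio/IVW rows with p < 0.05,
and retains proteins implicated in ≥ 5 phenotypes across ≥ 3 domains,
ranked by (domains desc, phenotypes desc, id).

## Clocks

Clocks are penalized linear regressions of chronological age on log2,
z-scaled abundances, fitted as scikit-learn-style estimators.
Per permutation of `PermutationClockEnsemble`: an independent random
training subset (default 10,000 permutations; training sizes of
100–600 mirror the emulated cohorts), scaling statistics computed from
the training split only and reused to scale the test split (no
leakage), and a LASSO whose λ is the 10-fold-CV minimum over a
100-point path from λ_max down by 1e-4. Sex optionally enters as a
standardized 0/1 feature subject to the same penalty. Held-out
performance is Pearson r; a permutation whose path degenerates to the
all-zero model is flagged with r undefined and excluded from the mean.
ECM mode restricts candidates to matrisome proteins; unsupervised mode
uses the whole proteome; random clocks redraw, per permutation, as many
proteins as the paired ECM clock selected (from the full measured
proteome by default) and refit Ridge (λ by 10-fold CV over a log grid
1e-3–1e3) on the identical split.

Stability selection keeps proteins with selection frequency strictly
above 0.5 (proteins only; sex is never counted). The stable clock is a
full-data Ridge on that signature, sex excluded, with λ again by
10-fold CV and scaling statistics stored from the full training cohort.
Within-study application scales by stored training statistics; the
off-the-shelf external mode scales a target cohort by its own
statistics, for transfer across datasets whose units differ.

Age gaps are de-biased by regressing predicted on chronological age and
inverting that line: unbiased = (predicted − intercept)/slope. By
construction, regressing unbiased predictions on age returns slope 1
and intercept 0 (numerically to ~1e-12); a near-zero correction slope
(|slope| < 1e-8) raises an "uninformative clock" error. Group
contrasts on gaps use Welch's t-test (within-study) or Wilcoxon
(external validation). Case–control classification fits, per held-out
sample, an L1 logistic model with internal CV on train-scaled signature
abundances and pools the leave-one-out probabilities into one AUC.

## Cross-species and parabiosis

Human and mouse association tables are joined on shared identifiers
(synthetic data uses a common namespace; real orthology mapping is out
of scope). Signed effects are sign(effect)·(−log10 p), capped at 300
for p = 0. A protein's age association is *shared* when nominally
significant (p < 0.05) in both species with the same direction; the
cross-species effect correlation is Pearson over the shared universe.

For parabiosis, the clock ensemble is trained exclusively on
non-parabiotic controls (asserted against the ensemble's recorded train
splits; leakage raises). Each parabiotic animal's age is predicted by
every non-flagged ensemble model and averaged; ΔAge is predicted −
chronological, *raw* by default because the lm-correction is defined on
the human training cohorts — a corrected mode is available by flag.
Contrasts YH–YI and OH–OI use Welch's t-test.

## Synthetic study conditions

The generator plants known structure so every stage has ground truth:

- **Human cohorts**: default 150 individuals aged 25–80 (a
  healthy-aging-cohort scale; replication cohorts use 16–66), uniform
  ages, ~15% matrisome proteins at the published 44:195:35:344:238:171
  category proportions (largest-remainder rounding).
- **Signal**: log2 abundance = baseline + β·age + γ·(age−45)² +
  sex term + ε. Planted linear slopes |β| ∈ [0.02, 0.08] log2-units per
  year (half on matrisome proteins by default), U-shaped proteins
  preferentially core matrisome with vertex 45 y, noise ε i.i.d.
  Gaussian with SD 0.2 on the log2 scale — the scale on which the
  clocks operate, so signal-to-noise is specified where models fit.
  Coefficients are drawn from a seed-only stream, so two cohorts with
  the same seed share planted truth regardless of sample draws.
- **Mouse cohort**: ages 1–30 months, 60 controls plus four parabiosis
  groups of 8 (young at 3, old at 20 months); per-month slopes scaled
  up so effects span a comparable dynamic range. Heterochronic shifts
  act only through the planted aging proteins, whose age-dependent
  terms are evaluated at age + shift — additive movement along the
  aging axis, mirroring the interpretation that rejuvenation is visible
  through the clock's proteins.
- **Phenotype associations**: 8 chapters × 20 phenotypes, base
  association rate 0.15 with a lognormal per-protein propensity
  (SD 1 on the log-odds scale) shared across chapters and a ×2 odds
  multiplier for ECM proteins. The propensity heterogeneity is what
  makes a pan-chapter disease matreotype identifiable, and the chosen
  rates put mean distinct-phenotype burdens near the ~30 (ECM) vs ~24
  (non-ECM) range typical of phenome-wide SomaScan association atlases.

What passing tests on these conditions show: the estimators recover
exactly the structure they model — linear log2 slopes, quadratic
U-shapes, sparse linear age signal, additive parabiosis shifts. What
they do not show: robustness to batch effects, aptamer
cross-reactivity, platform bridging, non-Gaussian noise, correlated
protein modules, or non-uniform age distributions, none of which the
generator emulates. Real-data effect sizes were not available to
calibrate against; defaults were chosen once for testability at
realistic scale.

## Numerical choices and problem sizes

- λ paths and CV folds are drawn from each permutation's own seeded
  generator; a single global seed fans out to per-stage seeds by CRC32
  of the stage name, so stage results do not depend on stage order.
- Dendrogram cutting uses the inclusive distance criterion (a merge at
  exactly the cut height stays merged); tie-breaking is fixed by
  lexicographic input order.
- The test suite and the acceptance script run the ensembles at
  100–200 permutations on cohorts of 300–600 samples and 150–500
  proteins — large enough for stable selection frequencies and null
  calibration, small enough for interactive runs; `RunConfig` retains
  the 10,000-permutation default for full-scale runs.
- TSV round-trips are bit-exact (shortest round-trip float text on
  write, round-trip parsing on read).

## Known limitations

- LASSO at the CV-minimum λ is not model-selection-consistent; in
  small candidate pools, individual noise proteins can exceed the 0.5
  selection frequency. Stability selection is reliable at realistic
  pool sizes (hundreds of candidates), which is how the defaults are
  set.
- The Monte Carlo composition p-value has resolution 1/2001 and is
  itself random; it is seeded for reproducibility.
- `compare_age_groups` assumes independent samples per bin
  (cross-sectional data); no longitudinal or mixed-effects support.
- External ("off-the-shelf") clock application assumes the target
  cohort's log2 abundance distribution is comparable after
  self-scaling; platform differences beyond location/scale are not
  corrected.
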