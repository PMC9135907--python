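# Methods

## Clock model and fitting

A clock predicts a transformed age F(age) as an affine function of CpG
beta values. Fitting minimizes the glmnet-form elastic-net objective

    (1/2n) ‖y − b0 − Xb‖² + λ [ α‖b‖₁ + (1−α)/2 ‖b‖₂² ]

with α fixed at 0.5 (the ridge/lasso midpoint; deliberately not tuned, so
reported accuracy is not inflated by mixing-parameter selection).
Predictors are standardized internally to mean 0 and population sd 1 —
the glmnet convention — and coefficients are mapped back to the beta
scale before storage, so the portable model file applies directly to raw
beta values. Probes with sd ≤ 1e-12 in the training set are excluded from
the design (their standardization is undefined); they simply receive no
coefficient. Probes with any missing beta in the fitting set are dropped
with a logged count: neither elastic-net fitting nor correlation
screening has a principled per-value missing-data treatment, and imputation
is out of scope.

The penalty grid descends log-linearly from λ_max = maxⱼ |xⱼ·(y−ȳ)|/(n·α)
(the smallest penalty that zeroes all coefficients) over 30 values down to
λ_max/100. λ is chosen at the minimum mean-squared error of a seeded
tenfold internal cross-validation, stratified by tissue when several
tissues are present (balanced folds, reproducible choice); the 1-SE rule
is not used. The solver behind the objective is scikit-learn's coordinate
descent; its correctness here is verified against an independently written
coordinate-descent oracle (tests and acceptance script), with a default
duality-gap tolerance of 1e-3 for prediction-grade fits (fixed-λ fits in
verification contexts use 1e-12).

Fixed-λ edge cases: λ = 0 is solved as ordinary least squares
(minimum-norm via lstsq when rank-deficient); λ > λ_max returns the null
model with intercept ȳ.

### Cross-validation

Accuracy is estimated by leave-one-out cross-validation in which the
*entire* procedure — probe filtering, standardization, λ grid and internal
CV — is refit on each n−1 subset and the held-out sample predicted once.
Re-selecting λ inside every fold avoids the optimism of fixing λ on the
full data. Reported metrics: Pearson R between predicted and true age in
years, median absolute error (years), mean signed error (the calibration
"offset" relevant for cross-species transfer), and the regression slope of
predicted on true age; per-tissue and per-species breakdowns are computed
for groups of at least 3 samples.

A caution that the null-calibration test makes explicit: when the fitted
models are (near-)intercept-only, LOOCV predictions equal per-fold
training means, which are mechanically anti-correlated with the held-out
value — on pure noise the LOOCV R can approach −1 for a perfectly correct
implementation. The honest null reference is therefore obtained by
permuting ages and re-running the whole LOOCV procedure (B = 19
permutations; comparing the observed |R| against their maximum is an
exact level-1/20 test under exchangeability), not by shuffling the
predictions of a single run.

### Age transforms

- identity: years, used for single-species clocks.
- relative age: age / max lifespan. Maximum lifespans used for the
  bundled species are 30.8 y (vervet) and 122.5 y (human). Ages above the
  recorded maximum transform to values > 1 with a warning, never clamped.
- log-linear: F(a) = log((a+k)/(m+k)) for a ≤ m and (a−m)/(m+k) above,
  continuous and differentiable at the maturity age m with common slope
  1/(m+k). Defaults: k = 1 y, m = 5 y (vervet) and 15 y (human),
  configurable per species; these are conventional pan-mammalian-clock
  values, and any published constants can be substituted in the transform
  block of the model file. Back-transformed predictions below zero are
  reported as-is (clamping would hide miscalibration).

All transforms are strictly increasing and invert to within 1e-10 years
(property-tested).

## EWAS

Per tissue, each probe is tested with the Pearson correlation test:
t = r√(n−2)/√(1−r²), two-sided p from Student t with n−2 df,
z = sign(r)·Φ⁻¹(1−p/2). Requires n ≥ 4 and non-constant ages.
Zero-variance probes get r = 0, p = 1, z = 0 and a flag. p-values are
carried in natural-log space: a strongly age-coupled probe at n = 144
has p far below the smallest positive double, and both z and the selection
thresholds must survive that underflow. Where even `t.logsf` underflows,
the log-p is continued with the leading term of the regularized incomplete
beta at x = df/(df+t²) (relative error O(x), negligible where the branch
engages); sample correlations are clipped to the largest double below 1
so a numerically perfect probe keeps a finite, n-monotone statistic.

Tissue results are combined with Stouffer's method Z = Σwᵢzᵢ/√(Σwᵢ²).
Weights default to equal — the textbook form — with √n weighting available
by flag, since tissue sample sizes in the motivating design differ
(144/48/48) and neither choice is canonical. Probes with fewer than two
finite per-tissue z-scores are excluded with a flag. No multiple-testing
correction is applied beyond the hard selection thresholds.

Directional selection takes probes with p < 10⁻¹⁰ (configurable; a
10⁻²⁰ "plotting" threshold is also carried in the pipeline config),
splits them by sign of z, ranks by |z| descending with ties broken by
lexicographic probe id, and truncates at 500 per direction. Overlap
analysis assigns every selected probe to exactly one exclusive
membership pattern (upset-style); cells sum to the union size.

## Annotation and enrichment

Probes are assigned to the gene with the minimal absolute signed TSS
distance; distances are oriented (negative upstream in the gene's reading
direction), and equidistant ties go to the lexicographically smaller gene
id. Feature classes follow the precedence promoter > 5′ UTR > exon >
intron > downstream > intergenic, with a configurable promoter window
(default −2000..+500 bp around the TSS; the convention of TSS-window
annotators, as no single window is standard) and a 3 kb downstream
window. Coordinates are 1-based closed internally; BED12 input (0-based
half-open) is converted on read, GFF3 is taken as-is. Probes on
chromosomes absent from the gene set are flagged and classed intergenic.

Enrichment of a CpG selection against category maps (GMT files: motif →
probes or gene-set → probes) uses the exact hypergeometric upper tail
P(X ≥ k) with the background restricted first: query members outside the
background are dropped (logged) and categories are intersected with the
background. Fold enrichment is kN/(nK). The probe universe for the
background is a configurable input, not a constant, since array designs
differ in how many probes map to a given genome.

## Clustering QC

Samples are clustered hierarchically on 1 − Pearson correlation across
probes with average linkage (defaults; euclidean/complete/ward are
available). This is the standard methylation sample-QC diagnostic: in a
clean multi-tissue dataset the k = number-of-tissues cut has tissue
purity 1. Leaf order is canonicalized — tighter subtree first, ties by
smallest sample id — so dendrogram exports (newick) are identical across
input orderings. The subcluster diagnostic examines, inside each flat
cluster, whether the cluster's own top split isolates ≥ 90% of one
attribute group (e.g. animals older than a threshold) at ≥ 90% purity; it
flags, but never removes, samples — outlier exclusion is left as a
documented manual decision.

## Synthetic data generator

The generator emulates the structure of a cross-sectional multi-tissue
primate methylation study. Signal is linear on the latent M-value
(logit2) scale:

    L = baseline + tissue_offset + animal_effect + slope · T(age) + ε
    beta = 1 / (1 + 2^(−L))

with T the species' relative age, so one latent slope means the same
thing in a 30.8-y and a 122.5-y species, and the logistic map keeps every
beta strictly inside (0,1) with realistic saturation. Slope-recovery
comparisons therefore belong on the latent scale, and rank (not Pearson)
correlation of beta with age is exactly ±1 at zero noise.

Defaults, chosen once as the package's standard study conditions:
3 tissues (blood, cortex, liver) × 50 samples; 3000 probes with 150
shared + 50-per-tissue age CpGs (300 planted); slope magnitudes
|N(4, 1.5)| (floor 0.5) latent units per relative-age unit with 60%
gaining methylation; per-(probe,tissue) baseline offsets of sd 1.0 latent
units (which yields purity-1 tissue clustering); residual noise sd 0.5;
per-animal random effects of sd 0.25 shared between longitudinal
replicates; ages uniform over 0–26 y (vervet) / 0–90 y (human) — uniform
rather than colony-skewed to maximize test power; longitudinal pair gaps
uniform on 3.9–10.93 y. Gain-direction age probes are planted
preferentially in promoter/5′ UTR features (60%/20% vs 15%/5% background),
so selection-level feature distributions show the promoter-gain pattern.

These conditions reproduce the qualitative accuracy regime of real
multi-tissue primate clocks (LOOCV R ≈ 0.99, median error ≈ 2% of the age
range) and are a synthetic calibration, not biology. What passing tests
do *not* show: robustness to batch effects, cell-composition shifts,
probe-chemistry artifacts, non-uniform age distributions, or genetic
variation — none of which are simulated.

Registered fixtures (`make_fixture`): `tiny` (45 samples × 400 probes,
sub-second smoke tests), `three-tissue` (the standard recovery
conditions), `two-species` (vervet + human, shared relative-age signal),
`null` and `null-small` (no planted signal), `longitudinal` (14 replicate
pairs), `ewas` (blood arm, n = 144), `old-liver` (an extra latent offset
in liver samples older than 8.7 y, planting an age-coherent subcluster).
Every fixture is fully determined by its seed; problem sizes are kept at
the scale above so the full validation workflow runs in minutes on one
CPU.

## Numerical and design notes

- Clock model files are decimal text (`repr` floats) so round-trips are
  bit-exact and diffs auditable; the file carries the transform kind and
  all per-species constants, making predictions reproducible from the
  file alone. A declared coefficient count guards against truncation.
- Pipeline runs fork a single seed into each stage by stable labels;
  outputs carry the config hash and seed; reruns are bit-identical for
  deterministic stages.
- The elastic-net implementation is verified two ways: against the
  independent coordinate-descent oracle at fixed λ (objective within
  1e-8), and against closed-form limits (λ = 0 → OLS, λ > λ_max → null
  model).
- Known limitations: no covariate-adjusted EWAS (sex, batch), no mixed
  models for repeated measures (longitudinal replicates are used only for
  ordering checks), no array normalization or QC (inputs are assumed to
  be normalized beta values), no automated outlier removal.
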