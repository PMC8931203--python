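# Methods

## The latent-progression model

Bulk tumor RNA-seq cohorts are cross-sectional: each sample is one tumor
at one time. The working hypothesis of pseudotime analysis on such data
is that many snapshots of a shared disease course can be ordered along a
single latent axis. `bulktime` models log2 expression of gene g in
sample n as

    y_gn = eta_g + alpha_g x_n + (lambda_g + beta_g x_n) z_n + eps_gn,
    eps_gn ~ Normal(0, sigma2_g),

with a binary covariate x in {−1, +1} (coded as a contrast so the main
effect alpha and interaction beta are orthogonal), independent
Normal(0, 1/tau) priors on eta, alpha, beta, lambda, and Normal(0, 1) on
z. This is the minimal linear model whose outputs are exactly the four
quantities of interest: per-sample pseudotime z, per-gene differential
expression alpha, pseudotime dependency lambda, and covariate-pseudotime
interaction beta. It is deliberately linear: branching, nonlinear
dynamics and single-cell dropout are out of scope.

### Inference

Mean-field CAVI with factors q(eta_g), q(alpha_g), q(lambda_g),
q(beta_g), q(z_n), all Gaussian, and a point-updated sigma2_g. Each
update is the exact coordinate maximizer of the evidence lower bound
(ELBO), and the sigma2 step is the closed-form maximizer of the ELBO in
sigma2, so the ELBO is non-decreasing across sweeps; the implementation
asserts nothing weaker than that, and the test suite checks it to 1e-6
relative slack. Convergence is declared when the relative ELBO change
drops below `tol` (default 1e-6), with the ELBO evaluated every
`check_every` sweeps (default 2) — evaluating on a thinned schedule
roughly halves the cost per sweep.

Defaults and why:

- `tau = 0.01` — a diffuse prior on gene effects; the data dominate.
- `max_iter = 2000` — at tol 1e-6 a 300-sample x 400-gene cohort needs
  roughly 1 200 sweeps (the final crawl is the weakly identified
  trade-off between the scale of z and the magnitude of lambda, a
  direction the prior decides only softly). The cap is generous so that
  reference-size fits converge; hitting it returns `converged=False`
  with a warning rather than an error.
- `init_jitter = 0.01` — z is initialized deterministically and the seed
  only perturbs the start slightly; fits from different seeds agree to
  |Pearson| > 0.99 after sign alignment.

### Initialization

z starts at the first principal component of the **covariate-residualized**,
gene-standardized matrix: each gene is regressed on x first, and PC1 is
taken on the residual. The covariate is known to the model (alpha absorbs
it), so the latent axis should be sought in the variation beyond it; on
cohorts where the covariate contrast dominates total variance, PC1 of the
raw matrix *is* the covariate, and starting there sends the optimizer
into a degenerate optimum essentially orthogonal to the true axis.

### Identifiability

The likelihood is invariant to affine changes of z absorbed into the
gene effects, and to a global sign flip. After convergence z is
standardized to mean 0, sd 1; eta and alpha absorb the location shift
(eta += lambda·mu, alpha += beta·mu), lambda and beta absorb the scale;
the sign is fixed so z correlates non-negatively with the residualized
PC1. The orientation is therefore internally reproducible but arbitrary
with respect to any external truth — comparisons against a reference
axis must align signs first, which is what the tests and the acceptance
script do.

### Significance flags

A gene is called pseudotime-dependent (resp. interacting) when the
`mean ± k·sd` interval of its lambda (resp. beta) posterior excludes 0,
with k = 2 (≈95% credible test, configurable). Two caveats, both
measured in the test suite:

- Mean-field posteriors ignore the uncertainty of z itself, so the
  intervals are somewhat narrow.
- Under a pure-noise cohort the fitted axis aligns with the top noise
  direction, inflating per-gene loadings. The net false-flag rate
  depends on the genes-to-samples aspect: ~28% at 300 samples x 100
  genes, ~11% at 300 x 400, ~5–6% at 300 x 800. The selection stage
  always feeds the model many hundreds to thousands of HVGs, so real
  use sits in the near-calibrated regime; flags from small gene panels
  should be treated as exploratory.

## Highly variable genes

Per gene the sample mean m, unbiased variance v and CV² = v/m² are
computed (genes with m ≤ 0 are excluded — CV is undefined, and log2(x+1)
input makes means non-negative). A gamma-family GLM with identity link
fits the reference curve CV² ≈ a₁/m + a₀ over genes with positive CV²;
predictions are floored at 1e-8. Deviation from the curve is tested with
T = (n−1)·CV²/ĈV² against the upper tail of chi-squared with n−1 df —
the classical variance-ratio approximation — and genes with p < 0.001
are selected. The statistic is scale-invariant and p is strictly
decreasing in CV² at fixed ĈV².

The test is approximately, not exactly, calibrated: the squared sample
mean in the denominator adds variance beyond the chi-squared reference,
noticeably when CV is large relative to 1/sqrt(n). At the CV² range of
log2-scale bulk expression (CV² ≲ 0.1) the null selection rate at
p < 0.001 measures ~0.1–0.2% on 10 000-gene null simulations. A config
switch `variability_metric: cv2|cv` exists; CV² is the default because
the gamma-GLM-on-CV² reference is the canonical, numerically stable
choice, and a single CV²-deviation test is performed.

## Pseudotime transfer

Among flagged genes, Pearson correlation with fitted pseudotime splits
candidates into positive and negative groups, each sorted by |r| with
gene-id lexicographic tie-breaks for determinism; the top 100 of each
group (both truncated to availability, with a logged deficit) form the
signature, at most 200 genes. The lasso (L1-penalized least squares,
solved by cyclic coordinate descent) is trained on the signature-gene
expression: samples split 2:1 into training/validation, seeded and
stratified on pseudotime tertiles so both splits span the axis;
predictors standardized on the training split; 100 log-spaced penalties
from lambda_max (the smallest penalty zeroing every coefficient) down to
1e-4·lambda_max; penalty chosen by 10-fold cross-validated MSE within
training; coefficients mapped back to the original expression scale.
Prediction on a new cohort is a dot product keyed by gene id; signature
genes missing from the target are imputed at their training-set means
(contributing their average effect, loudly logged), and coverage below
50% is an error. Pearson (not Spearman) ranking is the default and is
exposed in config.

## Enrichment scoring

For sample j, genes are ranked (average ranks on ties) and a signature S
scores

    score(S, j) = (mean_rank(S, j) − (G+1)/2) / sqrt((G+1)(G−|S|) / (12|S|)),

the standardized mean of |S| draws without replacement from ranks
1..G — exact null mean 0 and sd 1, positive when member genes are highly
expressed, invariant to any monotone transform of the sample's values.
This is a deliberately generic single-sample statistic, not a
re-implementation of any published cell-type scoring suite (no gene-set
ensembles, no spillover compensation): downstream analyses consume
scores only through correlations with pseudotime, for which sign and
monotonicity — preserved here by construction — are the load-bearing
properties. Signatures overlapping fewer than 3 genes with the matrix,
or covering all genes (degenerate denominator), are skipped with a
warning.

Over-representation uses the hypergeometric upper tail P(X ≥ k) with
population N = |universe|, K = |set ∩ universe|, n = |query|;
Benjamini–Hochberg q-values across sets; significance requires p < 0.05
and q < 0.1. BH is used for set-level q-values while pseudotime–cell-type
correlation tables use Bonferroni — two different multiplicity contexts,
named correctly in the output.

## Clinical associations and survival

Correlations are Pearson (t-distribution p) or Spearman, pairwise-
complete with n reported; zero variance is an error, not an NaN. Group
comparisons: Welch t-test (matching R's default behaviour) or Wilcoxon
rank-sum for two groups, one-way ANOVA or Kruskal–Wallis for more;
missing labels are dropped with per-group n reported.

The survival split explores cutoffs: candidates are the observed
pseudotime values between the 10th and 90th percentiles; for each, a
two-group log-rank test (observed-minus-expected over event times with
hypergeometric variance) is computed and the cutoff minimizing p is
returned. Minimizing over cutoffs makes the reported p anti-conservative;
the result carries an explicit "cutoff-optimized, anti-conservative"
annotation rather than any correction, because the explored-cutoff
semantics is the procedure being reproduced. Kaplan–Meier curves use the
product-limit estimator and equal the empirical survivor function
exactly when nothing is censored. When both endpoints of a study are
analysed, each is optimized independently.

## Mutation burden

TMB is the per-sample count of records whose Variant_Classification is
in the MAF-convention non-synonymous set {Missense_Mutation,
Nonsense_Mutation, Nonstop_Mutation, Frame_Shift_Del, Frame_Shift_Ins,
In_Frame_Del, In_Frame_Ins, Splice_Site, Translation_Start_Site}
(configurable). Silent/intronic/UTR records are excluded; unknown
classes are excluded with one warning per class; rostered samples absent
from the table count 0; duplicate records are *not* deduplicated (no
defensible automatic rule without position/allele columns — callers
should deduplicate upstream if needed). An optional capture size (Mb)
adds a per-megabase rate.

## PET segmentation and SUV metrics

The Nestle adaptive threshold is implemented in its classical form:
within a user-supplied seed box (0-based, half-open voxel coordinates)
containing the tumor peak, I₇₀ is the mean SUV of voxels ≥ 0.7·SUVmax;
the background I_bg is the mean SUV of a 2-voxel-thick shell around the
box dilated by 2 voxels (a documented choice — vendor tools do not
publish their background definition); the threshold is T = β·I₇₀ + I_bg
with β = 0.3. The mask is the 26-connected component containing the
peak among in-box voxels ≥ T; masks touching the box boundary trigger a
truncation warning. Note the symbol collision: this deterministic β is
unrelated to the trajectory model's interaction coefficient. Metrics:
SUVmax and SUVmean over the mask, MTV = voxels·voxel-volume in mL, and
TLG = SUVmean·MTV as an exact identity. Scaling all SUVs by k > 0 scales
T and the SUV metrics by k and leaves mask and MTV unchanged; increasing
β never grows the mask.

## The synthetic cohort generator

`SimulationConfig` defaults define the study conditions used throughout
the tests:

| parameter | default | meaning |
|---|---|---|
| n_samples / n_genes | 300 / 800 | cohort size |
| frac_lambda_nonzero | 0.30 | genes with pseudotime dependency |
| frac_beta_nonzero | 0.10 | genes with covariate interaction |
| s_lambda / s_beta / s_alpha | 1.0 / 0.5 / 0.5 | effect scales (sd of nonzero draws) |
| sigma | 0.5 | residual sd on the log2 scale |
| baseline_mean / sd | 7.0 / 1.5 | eta distribution (typical log2 bulk level) |
| p_x | 0.5 | covariate balance |
| stage_cuts | 0.55, 0.78, 0.95 | z-quantile bins for stages I–IV, matching the stage mix of published lung adenocarcinoma cohorts (~54/23/16/5%) |
| h0 / gamma_surv | 1/1000 per day / 0.5 | exponential hazard h0·exp(gamma·z) |
| censoring | 0.30 | fraction of samples censored |
| tmb_a / tmb_b | log 10 / 0.3 | Poisson log-mean of non-synonymous count |
| silent_fraction | 0.30 | synonymous share of mutation records |
| suv_c0 / c1 / noise | 5.0 / 1.5 / 0.3 | tumor peak SUV vs z |
| suv_floor | 2.5 | minimum peak SUV (FDG visibility floor) |
| pet geometry | 32³ voxels, 2 mm, r = 10 mm sphere, σ_smooth = 1 voxel | tumor phantom |

Design choices: z_true is standard normal, fixing the scale/sign
conventions recovery tests need. The covariate is {−1, +1} so alpha and
beta are orthogonal contrasts. Survival is exponential — the simplest
law in which hazard rises with progression; censoring is applied by
independently censoring each sample with the configured probability at a
Uniform(0, T) fraction of its event time, which makes the censoring rate
exact and keeps the KM estimand simple. Gene-level effects can be pinned
with `gene_seed` so two cohorts share "biology" while redrawing samples
— the setting transfer studies need. Signature member genes are drawn
from the non-informative pool so that the configured slope is the set's
*only* trend along z; explicit member lists are also accepted. Mutation
records are thinned so the non-synonymous margin stays Poisson at the
configured log-mean. PET tumor peaks are floored at SUV 2.5, the
conventional visibility threshold below which a smoothed lesion cannot
be separated from background by an adaptive threshold at all — the
generator emulates delineable lesions only, mirroring studies where
every analysed tumor was segmentable.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: negative-binomial count noise and library-size
effects (expression is Gaussian on the log scale), batch and platform
effects between cohorts (transfer tests share the generative law exactly,
so real cross-platform transfer will be harder), correlated gene modules
beyond the single latent axis, scanner point-spread functions and
heterogeneous tumor uptake, and informative censoring.

## Problem sizes and numerical choices

The reference recovery cohort is 300 samples x 400 genes (30%
informative, sigma 0.5); the HVG calibration null is 10 000 genes x 100
samples; transfer uses two 300-sample cohorts with shared gene effects;
PET checks use 20–40 volumes of 32³ voxels. These sizes make the full
test suite and the acceptance script each run in about 1–2 minutes on a
single CPU while keeping every statistical check well-powered.
Numerical guards: expected CV² floored at 1e-8; sigma2 floored at 1e-8;
identity-link gamma GLM retried from an OLS start and accepted at
near-zero deviance (a noiseless curve trips the IRLS convergence flag);
lasso penalties below machine-meaningful size fall back to ordinary
least squares; degenerate enrichment denominators (signature = all
genes) are skipped; survival candidate cutoffs that empty a group are
skipped.

## Known limitations

- The trajectory model is linear and single-axis; multimodal or
  branching progression will be projected onto one direction.
- Mean-field credible intervals understate uncertainty (see the flag
  calibration numbers above).
- The explored-cutoff survival p is anti-conservative by construction
  and must not be read as a fixed-cutoff p.
- The enrichment score is a generic rank statistic; absolute score
  values are not comparable to any published cell-type scoring suite,
  only signs and orderings are.
- PET segmentation assumes a single connected lesion whose peak lies in
  the seed box; multi-lesion detection and DICOM SUV computation from
  injected dose are out of scope.
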