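# bulktime

Pseudotime trajectory inference for **bulk** tumor RNA-seq, with the
downstream analyses a tumor-progression study needs: highly variable gene
selection, a Bayesian covariate-interaction latent-progression model,
sparse-signature transfer of pseudotime to new cohorts, and association of
pseudotime with clinical stage, survival, immune-signature enrichment,
tumor mutation burden (TMB) and FDG-PET glucose-metabolism metrics.

It is written for computational biologists who want a tested, reusable
implementation of this pipeline — every stage is exercised end-to-end on
synthetic cohorts with known ground truth, so recovery, calibration and
sign-correctness are all verifiable properties rather than hopes.

## The model

Samples are tumors, not cells: each tumor is a cross-sectional snapshot of
a disease course, and the latent pseudotime `z_n` orders tumors along that
course. For gene `g`, sample `n`, binary covariate `x_n ∈ {−1,+1}`
(e.g. a histology contrast):

```
y_gn = η_g + α_g x_n + (λ_g + β_g x_n) z_n + ε_gn,   ε_gn ~ N(0, σ²_g)
```

with `N(0, τ⁻¹)` priors on the gene effects and `N(0,1)` on `z`. Here
`η` is the baseline, `α` the degree of differential expression, `λ` the
degree of pseudotime dependency, and `β` the covariate–pseudotime
interaction. Inference is mean-field coordinate-ascent variational
inference (CAVI); every update is an exact coordinate maximization of the
ELBO, which is therefore monotone and monitored for convergence
(relative change < 1e-6, evaluated every 2 sweeps). Genes with a
`mean ± 2·sd` posterior interval for `λ` (or `β`) excluding zero are
flagged as significantly pseudotime-dependent.

Around the model:

- **HVG selection** — per-gene CV² is tested against a gamma-GLM reference
  curve `CV² ≈ a₁/mean + a₀` with the variance-ratio chi-squared statistic
  `T = (n−1)·CV²/ĈV²` on `n−1` df; genes with `p < 0.001` are kept.
- **Transfer** — significant genes are ranked by Pearson correlation with
  pseudotime; the top 100 positive + top 100 negative form a signature; a
  10-fold cross-validated lasso (2:1 train/validation split) predicts
  pseudotime in a new cohort, imputing missing signature genes at training
  means.
- **Enrichment** — a per-sample standardized mean-rank score (exact null
  mean 0, sd 1) for any GMT signature collection, plus hypergeometric
  over-representation with Benjamini–Hochberg q-values.
- **Clinical** — stage group comparisons (t-test/ANOVA/Wilcoxon/Kruskal),
  Bonferroni-adjusted correlation tables, Kaplan–Meier survival with an
  explored pseudotime cutoff (log-rank p minimized over the 10th–90th
  percentile candidates, reported with its anti-conservative caveat).
- **Genomics** — TMB as the per-sample count of non-synonymous MAF records.
- **Imaging** — Nestle adaptive-threshold PET segmentation
  `T = 0.3·I₇₀ + I_bg` and SUVmax / SUVmean / MTV / TLG extraction.
- **Simulation** — a generator producing cohorts in which a known latent
  axis drives expression, stage, survival, immune trends, burden and
  uptake, so every claim above is testable.

## Worked example

`examples/02_fit_trajectory.py` simulates a 300-sample, 800-gene cohort,
selects HVGs and fits the trajectory model:

```
HVG selection: 170 / 800 genes at p < 0.001 (reference curve cv2 = 0.225/m + -0.016)
CAVI converged after 1812 sweeps; final ELBO -41403.1
|Spearman| between fitted and true pseudotime: 0.998
nonzero-lambda genes: 114 (56 up, 58 down along pseudotime)
```

A |Spearman| of 0.998 against the generator's true axis means the latent
progression ordering was recovered (the sign of a latent axis is
arbitrary); the flagged genes split into up- and downregulated programs
along progression. The other examples cover simulation
(`01_simulate_cohort.py`), cohort-to-cohort transfer
(`03_transfer_pseudotime.py`, |Spearman| 0.998 on an unseen cohort),
immune/TMB associations (`04`, Th1-like r = +0.98, M2-like r = −0.985,
TMB r = 0.703), PET metrics (`05`, segmentation Dice ≥ 0.90, SUVmax–z
r = 0.953) and stage/survival analysis (`06`, explored-cutoff log-rank
p = 8.9e-09).

## Command line

The same pipeline is available as `bulktime` subcommands, each a thin
wrapper over the library:

```
bulktime --config sim.yaml simulate --out cohort/
bulktime hvg --expr cohort/expression.tsv --out hvg.tsv --expr-out hvg_expr.tsv
bulktime --seed 1 fit --expr hvg_expr.tsv --clinical cohort/clinical.tsv --out fit/
bulktime --seed 2 transfer fit --expr hvg_expr.tsv --z fit/z.tsv \
    --fit-genes fit/genes.tsv --out model.json
bulktime transfer predict --model model.json --expr new_cohort.tsv --out zhat.tsv
bulktime enrich --expr cohort/expression.tsv --gmt cohort/signatures.gmt --out scores.tsv
bulktime tmb --maf cohort/mutations.maf --out tmb.tsv
bulktime petmetrics --nifti cohort/pet_S0000.nii --seed-box 4,28,4,28,4,28 --out suv.json
bulktime associate --z fit/z.tsv --table scores.tsv --out assoc.tsv
bulktime survive --z fit/z.tsv --clinical cohort/clinical.tsv --out km.json
```

## Scope notes

The package operates on expression matrices, clinical tables, GMT, MAF
and NIfTI files you already have; it does not download cohort data.
Cell-type scoring uses a generic rank statistic, not a re-implementation
of any published scoring suite, and over-representation runs on
user-supplied gene sets without ontology handling. See `docs/methods.md`
for modelling assumptions, parameter defaults and known limitations.
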