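"""Select highly variable genes and fit the Bayesian trajectory model.

The fit recovers per-sample pseudotime z and per-gene effects: baseline
eta, covariate effect alpha, pseudotime loading lambda, and the
covariate-pseudotime interaction beta. On synthetic data the recovered
axis can be compared with the generator's truth.
"""

import numpy as np
from scipy.stats import spearmanr

import bulktime as bt

cfg = bt.SimulationConfig(n_samples=300, n_genes=800, seed=1)
expr, clin, truth = bt.simulate_cohort(cfg)

gv = bt.select_hvgs(expr, p_cut=0.001)
hvgs = gv.selected_genes
print(f"HVG selection: {len(hvgs)} / {expr.n_genes} genes at p < 0.001 "
      f"(reference curve cv2 = {gv.curve[1]:.3f}/m + {gv.curve[0]:.3f})")

fit = bt.fit_trajectory(
    expr.subset_genes(hvgs), clin.covariate_vector(expr.sample_ids), seed=0
)
print(f"CAVI {'converged' if fit.converged else 'did not converge'} "
      f"after {fit.n_iter} sweeps; final ELBO {fit.elbo_trace[-1]:.1f}")

rho = spearmanr(fit.z_mean, truth.z_true)[0]
print(f"|Spearman| between fitted and true pseudotime: {abs(rho):.3f}")

sig = bt.significant_genes(fit, k=2)
up, down = bt.split_by_direction(fit, sig)
print(f"nonzero-lambda genes: {int(sig.nonzero_lambda.sum())} "
      f"({len(up)} up, {len(down)} down along pseudotime)")
print("A |Spearman| near 1 means the latent disease-progression ordering "
      "was recovered (sign is arbitrary).")
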