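"""Shared fixtures: seeded synthetic cohorts and their trajectory fits.

The reference recovery cohort (300 samples x 400 genes, 30% informative,
noise sd 0.5) is generated once per session and its trajectory fit is
reused by every test that needs a fitted pseudotime, to keep the suite
fast without weakening any check.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import bulktime as bt

# cohorts A and B share gene-level effects (gene_seed) but redraw samples,
# emulating two cohorts drawn from the same biology
GENE_SEED = 100
SEED_A = 11
SEED_B = 12


def recovery_config(seed: int) -> bt.SimulationConfig:
    return bt.SimulationConfig(
        n_samples=300,
        n_genes=400,
        frac_lambda_nonzero=0.3,
        sigma=0.5,
        seed=seed,
        gene_seed=GENE_SEED,
        n_pet=60,
    )


@pytest.fixture(scope="session")
def cohort_a():
    return bt.simulate_cohort(recovery_config(SEED_A))


@pytest.fixture(scope="session")
def cohort_b():
    return bt.simulate_cohort(recovery_config(SEED_B))


@pytest.fixture(scope="session")
def fit_a(cohort_a):
    """Trajectory fit on cohort A, with its wall-clock time attached."""
    expr, clin, _ = cohort_a
    t0 = time.perf_counter()
    fit = bt.fit_trajectory(expr, clin.covariate_vector(expr.sample_ids), seed=1)
    elapsed = time.perf_counter() - t0
    return fit, elapsed


def align_sign(z_est: np.ndarray, z_ref: np.ndarray) -> np.ndarray:
    """Resolve the global sign indeterminacy of a latent axis against a reference."""
    c = np.corrcoef(np.asarray(z_est, float), np.asarray(z_ref, float))[0, 1]
    return np.asarray(z_est, float) * (1.0 if c >= 0 else -1.0)
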