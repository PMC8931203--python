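"""Bayesian latent-progression (pseudotime) model with covariate interactions.

The model for log expression of gene g in sample n with binary covariate
x_n in {-1,+1} and latent pseudotime z_n is

    y_gn = eta_g + alpha_g x_n + (lambda_g + beta_g x_n) z_n + eps_gn,
    eps_gn ~ Normal(0, sigma2_g),

with Normal(0, 1/tau) priors on the gene-level effects eta (baseline),
alpha (differential expression), beta (covariate-pseudotime interaction),
lambda (pseudotime dependency), and a Normal(0,1) prior on z. Inference
is mean-field coordinate-ascent variational inference (CAVI): every
factor update is an exact coordinate maximization of the evidence lower
bound (ELBO), and sigma2_g is point-updated in closed form, so the ELBO
is non-decreasing across sweeps. Convergence is declared when the
relative ELBO change falls below ``tol``, with the ELBO evaluated every
``check_every`` sweeps.

Identifiability of the latent axis (scale, location, sign) is resolved
after convergence: z is standardized to mean 0, sd 1, its sign fixed so
that it correlates non-negatively with the first principal component,
and the gene-level effects are rescaled to compensate, leaving the
likelihood unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix

logger = logging.getLogger("bulktime")

__all__ = ["TrajectoryFit", "GeneSignificance", "fit_trajectory", "significant_genes", "split_by_direction"]


@dataclass
class TrajectoryFit:
    """Posterior summaries of the latent-progression model.

    Per sample: mean/sd of pseudotime z. Per gene: mean/sd of eta, alpha,
    beta, lambda and the noise variance sigma2. ``elbo_trace`` holds the
    recorded ELBO values (non-decreasing within numerical slack).
    """

    sample_ids: list
    gene_ids: list
    z_mean: np.ndarray
    z_sd: np.ndarray
    eta_mean: np.ndarray
    eta_sd: np.ndarray
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    lam_mean: np.ndarray
    lam_sd: np.ndarray
    sigma2: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        n, g = len(self.sample_ids), len(self.gene_ids)
        if len(self.z_mean) != n or len(self.z_sd) != n:
            raise ValueError("z summaries do not match sample count")
        for arr in (self.eta_mean, self.eta_sd, self.alpha_mean, self.alpha_sd,
                    self.beta_mean, self.beta_sd, self.lam_mean, self.lam_sd, self.sigma2):
            if len(arr) != g:
                raise ValueError("gene summaries do not match gene count")
        for arr in (self.z_sd, self.eta_sd, self.alpha_sd, self.beta_sd, self.lam_sd):
            if (np.asarray(arr) < 0).any():
                raise ValueError("negative posterior sd")


@dataclass
class GeneSignificance:
    """Credible-interval flags for nonzero pseudotime/interaction effects."""

    gene_ids: list
    nonzero_lambda: np.ndarray
    nonzero_beta: np.ndarray
    lam_lo: np.ndarray
    lam_hi: np.ndarray
    beta_lo: np.ndarray
    beta_hi: np.ndarray
    k: float


def _first_pc(y: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """First principal component scores of the gene-standardized matrix.

    When the covariate ``x`` is given, its per-gene component is projected
    out first: the model accounts for x through the alpha effects, so the
    latent axis should be initialized from the variation beyond it (PC1 of
    the raw matrix can be the covariate contrast itself).
    """
    y = y - y.mean(axis=1, keepdims=True)
    if x is not None:
        xc = x - x.mean()
        y = y - np.outer(y @ xc / (xc @ xc), xc)
    sd = y.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    ys = y / sd[:, None]
    # samples x genes SVD; scores = right singular vector of gene space
    _, _, vt = np.linalg.svd(ys, full_matrices=False)
    pc = vt[0]
    s = pc.std(ddof=0)
    return pc / (s if s > 0 else 1.0)


def fit_trajectory(
    expr_hvg: ExpressionMatrix,
    x,
    tol: float = 1e-6,
    check_every: int = 2,
    max_iter: int = 2000,
    seed: int | None = 0,
    tau: float = 0.01,
    init_jitter: float = 0.01,
) -> TrajectoryFit:
    """Fit the covariate-interaction pseudotime model by CAVI.

    Parameters
    ----------
    expr_hvg
        Expression restricted to the genes entering the model (HVGs).
    x
        Binary covariate per sample, coded {-1, +1}.
    tol
        Relative ELBO change below which convergence is declared.
    check_every
        Sweeps between ELBO evaluations (the trace is thinned by this).
    tau
        Prior precision of the gene-level effects (diffuse by default).
    init_jitter
        SD of seeded Gaussian jitter added to the principal-component
        initialization of z; the fit is deterministic given the seed.
    """
    y = np.asarray(expr_hvg.values, dtype=float)
    G, N = y.shape
    if G < 2:
        raise ValueError("need >= 2 genes")
    if N < 4:
        raise ValueError("need >= 4 samples")
    x = np.asarray(x, dtype=float)
    if x.shape != (N,):
        raise ValueError(f"covariate length {x.shape} does not match {N} samples")
    if not np.all(np.isin(x, (-1.0, 1.0))):
        raise ValueError("covariate must be coded {-1,+1}")

    rng = np.random.default_rng(seed)
    # init: z from PC1 (deterministic) plus optional seeded jitter
    mz = _first_pc(y, x)
    if init_jitter > 0:
        mz = mz + rng.normal(0.0, init_jitter, size=N)
    vz = np.full(N, 1.0)

    m_eta = y.mean(axis=1)
    v_eta = np.full(G, 1.0 / max(tau, 1e-12))
    m_alpha = np.zeros(G)
    v_alpha = v_eta.copy()
    m_lam = np.zeros(G)
    v_lam = v_eta.copy()
    m_beta = np.zeros(G)
    v_beta = v_eta.copy()
    sigma2 = np.maximum(y.var(axis=1, ddof=0), 1e-6)

    def expected_sq_resid():
        """E_q of the squared residual, G x N."""
        mc = m_lam[:, None] + m_beta[:, None] * x[None, :]
        ec2 = (
            (m_lam**2 + v_lam)[:, None]
            + 2.0 * x[None, :] * (m_lam * m_beta)[:, None]
            + (m_beta**2 + v_beta)[:, None]
        )
        ez2 = (mz**2 + vz)[None, :]
        fit_mean = m_eta[:, None] + m_alpha[:, None] * x[None, :] + mc * mz[None, :]
        return (
            (y - fit_mean) ** 2
            + v_eta[:, None]
            + v_alpha[:, None]
            + ec2 * ez2
            - mc**2 * (mz**2)[None, :]
        )

    def elbo():
        r = expected_sq_resid()
        ll = -0.5 * N * np.log(2.0 * np.pi * sigma2).sum() - 0.5 * (r / sigma2[:, None]).sum()
        def kl_gauss(m, v, prior_prec):
            # KL(N(m, v) || N(0, 1/prior_prec)) summed
            return 0.5 * np.sum(prior_prec * (v + m**2) - 1.0 - np.log(prior_prec * v))
        kl = (
            kl_gauss(m_eta, v_eta, tau)
            + kl_gauss(m_alpha, v_alpha, tau)
            + kl_gauss(m_lam, v_lam, tau)
            + kl_gauss(m_beta, v_beta, tau)
            + kl_gauss(mz, vz, 1.0)
        )
        return ll - kl

    trace = []
    converged = False
    it = 0
    prev = None
    while it < max_iter:
        it += 1
        prec = 1.0 / sigma2
        ez2 = mz**2 + vz
        sum_ez2 = ez2.sum()

        # gene-level coordinate updates (each exact given the others)
        mc = m_lam[:, None] + m_beta[:, None] * x[None, :]
        p_eta = tau + prec * N
        m_eta = prec * ((y - m_alpha[:, None] * x[None, :] - mc * mz[None, :]).sum(axis=1)) / p_eta
        v_eta = 1.0 / p_eta

        p_alpha = tau + prec * N
        m_alpha = prec * (
            (x[None, :] * (y - m_eta[:, None] - mc * mz[None, :])).sum(axis=1)
        ) / p_alpha
        v_alpha = 1.0 / p_alpha

        r0 = y - m_eta[:, None] - m_alpha[:, None] * x[None, :]
        p_lam = tau + prec * sum_ez2
        m_lam = prec * (
            (mz[None, :] * r0).sum(axis=1) - m_beta * (x * ez2).sum()
        ) / p_lam
        v_lam = 1.0 / p_lam

        p_beta = tau + prec * sum_ez2  # x^2 = 1
        m_beta = prec * (
            (x[None, :] * mz[None, :] * r0).sum(axis=1) - m_lam * (x * ez2).sum()
        ) / p_beta
        v_beta = 1.0 / p_beta

        # pseudotime update
        mc = m_lam[:, None] + m_beta[:, None] * x[None, :]
        ec2 = (
            (m_lam**2 + v_lam)[:, None]
            + 2.0 * x[None, :] * (m_lam * m_beta)[:, None]
            + (m_beta**2 + v_beta)[:, None]
        )
        pz = 1.0 + (prec[:, None] * ec2).sum(axis=0)
        r0 = y - m_eta[:, None] - m_alpha[:, None] * x[None, :]
        mz = (prec[:, None] * mc * r0).sum(axis=0) / pz
        vz = 1.0 / pz

        # closed-form noise update (maximizes the ELBO over sigma2)
        sigma2 = np.maximum(expected_sq_resid().mean(axis=1), 1e-8)

        if it % check_every == 0 or it == max_iter:
            e = elbo()
            if not np.isfinite(e):
                raise FloatingPointError(f"non-finite ELBO at iteration {it}")
            trace.append(e)
            if prev is not None:
                denom = max(abs(prev), 1.0)
                if (e - prev) / denom < tol:
                    converged = True
                    break
            prev = e
    if not converged:
        logger.warning("trajectory fit hit max_iter=%d without converging", max_iter)

    # identifiability: standardize z, fix sign against PC1, rescale effects
    mu, s = mz.mean(), mz.std(ddof=0)
    if s <= 0:
        s = 1.0
    m_eta = m_eta + m_lam * mu
    m_alpha = m_alpha + m_beta * mu
    mz = (mz - mu) / s
    vz = vz / s**2
    m_lam, v_lam = m_lam * s, v_lam * s**2
    m_beta, v_beta = m_beta * s, v_beta * s**2
    pc1 = _first_pc(y, x)
    if np.dot(mz, pc1) < 0:
        mz, m_lam, m_beta = -mz, -m_lam, -m_beta

    return TrajectoryFit(
        sample_ids=list(expr_hvg.sample_ids),
        gene_ids=list(expr_hvg.gene_ids),
        z_mean=mz,
        z_sd=np.sqrt(vz),
        eta_mean=m_eta,
        eta_sd=np.sqrt(v_eta),
        alpha_mean=m_alpha,
        alpha_sd=np.sqrt(v_alpha),
        beta_mean=m_beta,
        beta_sd=np.sqrt(v_beta),
        lam_mean=m_lam,
        lam_sd=np.sqrt(v_lam),
        sigma2=sigma2,
        elbo_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def significant_genes(fit: TrajectoryFit, k: float = 2.0) -> GeneSignificance:
    """Flag genes whose lambda (resp. beta) posterior excludes zero.

    A gene is called nonzero when 0 lies outside [mean - k*sd, mean + k*sd];
    k = 2 approximates a 95% credible test.
    """
    lam_lo = fit.lam_mean - k * fit.lam_sd
    lam_hi = fit.lam_mean + k * fit.lam_sd
    beta_lo = fit.beta_mean - k * fit.beta_sd
    beta_hi = fit.beta_mean + k * fit.beta_sd
    return GeneSignificance(
        gene_ids=list(fit.gene_ids),
        nonzero_lambda=(lam_lo > 0) | (lam_hi < 0),
        nonzero_beta=(beta_lo > 0) | (beta_hi < 0),
        lam_lo=lam_lo,
        lam_hi=lam_hi,
        beta_lo=beta_lo,
        beta_hi=beta_hi,
        k=k,
    )


def split_by_direction(fit: TrajectoryFit, sig: GeneSignificance):
    """Partition nonzero-lambda genes into up- and downregulated lists."""
    up = [g for g, f, m in zip(fit.gene_ids, sig.nonzero_lambda, fit.lam_mean) if f and m > 0]
    down = [g for g, f, m in zip(fit.gene_ids, sig.nonzero_lambda, fit.lam_mean) if f and m < 0]
    return up, down
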