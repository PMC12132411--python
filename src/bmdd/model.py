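"""Variational EM for the bimodal-Dirichlet multinomial model.

Generative model, per sample ``i`` with depth ``N_i``::

    delta_ij ~ Bernoulli(pi_j)                    (per-taxon mode indicator)
    X_i      ~ Dirichlet(alpha_{1,delta_i1}, ..., alpha_{m,delta_im})
    W_i      ~ Multinomial(N_i, X_i)

The posterior over ``(X, delta)`` is approximated by the mean field
``Dirichlet(beta_i) x prod_j Bernoulli(gamma_ij)`` fitted by coordinate
ascent (E-step), while the hyperparameters ``(pi, alpha0, alpha1)`` are
updated by maximising a Jensen surrogate of the evidence lower bound
(M-step).  The intractable term ``E[log Gamma(sum_j alpha_{j,delta_ij})]``
is bounded below by the convexity of log-gamma; that surrogate, not a
Monte-Carlo estimate, is the fitted objective throughout.

The posterior mean ``beta_ij / sum_k beta_ik`` is the imputed composition;
``posterior_sample`` draws multiple imputations from ``Dirichlet(beta_i)``.
An exact ``2^m`` enumeration oracle (`exact_posterior_mean`,
`exact_log_marginal`) is provided for validation at small ``m``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit, xlogy

from .types import (
    BMDDError,
    Composition,
    CountTable,
    FitResult,
    Hyperparams,
    VariationalState,
)

logger = logging.getLogger("bmdd")

_MAX_ENUM_TAXA = 15


@dataclass
class FitConfig:
    """Tunable knobs of the variational EM fit.

    ``tol`` is the relative change in the surrogate ELBO that stops the
    outer EM loop; ``inner_tol`` bounds the max elementwise change of
    ``gamma`` inside an E-step sweep.  ``pi_clamp`` keeps the mixture
    weights strictly inside (0, 1) so the Bernoulli log-odds stay finite,
    and ``alpha_bounds`` are the box constraints of the quasi-Newton
    M-step.  ``seed`` only matters for operations that draw random numbers
    (posterior sampling); the fit itself is deterministic.
    """

    max_iter: int = 100
    tol: float = 1e-6
    max_sweeps: int = 50
    inner_tol: float = 1e-6
    pi_clamp: float = 1e-4
    alpha_min: float = 1e-6
    alpha_max: float = 1e6
    seed: int = 0


# ---------------------------------------------------------------------------
# initialisation


def init_params(table: CountTable, config: FitConfig | None = None):
    """Deterministic initialisation of hyperparameters and variational state.

    ``gamma`` starts from a crude two-group split of each taxon's
    log relative abundance (pseudocount 0.5): entries above the taxon's
    median over samples with a nonzero count get responsibility 0.8 for the
    high mode, the rest 0.2.  ``alpha`` starts from a method-of-moments
    Dirichlet fit on the pseudocount compositions, split into a low mode at
    one tenth and a high mode at twice the fitted shape.  ``pi`` starts at
    the column means of the initial ``gamma``.
    """
    config = config or FitConfig()
    W = table.counts
    n, m = W.shape
    if m < 2:
        raise BMDDError("a composition needs at least 2 taxa")

    pseudo = (W + 0.5) / (W + 0.5).sum(axis=1, keepdims=True)
    logp = np.log(pseudo)

    gamma = np.full((n, m), 0.2)
    for j in range(m):
        nz = W[:, j] > 0
        if nz.any():
            med = np.median(logp[nz, j])
            gamma[logp[:, j] > med, j] = 0.8

    # method-of-moments Dirichlet precision from per-taxon means/variances
    mean = pseudo.mean(axis=0)
    var = pseudo.var(axis=0)
    ok = (var > 0) & (mean > 0) & (mean < 1)
    if ok.any():
        s_j = mean[ok] * (1 - mean[ok]) / var[ok] - 1.0
        s_j = s_j[s_j > 0]
        s = float(np.exp(np.mean(np.log(s_j)))) if s_j.size else float(m)
    else:
        s = float(m)
    alpha_hat = np.maximum(s * mean, 1e-4)
    alpha0 = 0.1 * alpha_hat
    alpha1 = 2.0 * alpha_hat

    pi = np.clip(gamma.mean(axis=0), config.pi_clamp, 1 - config.pi_clamp)
    hyper = Hyperparams(pi=pi, alpha0=alpha0, alpha1=alpha1)
    beta = update_beta(table, gamma, hyper)
    return hyper, VariationalState(beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# E-step pieces


def update_beta(table: CountTable, gamma: np.ndarray, hyper: Hyperparams) -> np.ndarray:
    """Closed-form Dirichlet update: ``beta = W + gamma*alpha1 + (1-gamma)*alpha0``."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != table.counts.shape:
        raise BMDDError("gamma shape does not match the count table")
    if hyper.n_taxa != table.n_taxa:
        raise BMDDError("hyperparameter length does not match the count table")
    return table.counts + gamma * hyper.alpha1 + (1 - gamma) * hyper.alpha0


def compute_h(
    beta_row: np.ndarray,
    gamma_row: np.ndarray,
    hyper: Hyperparams,
    j: int,
) -> tuple[float, float]:
    """Surrogate log-odds contributions of the two modes of taxon ``j``.

    ``h(d) = logG(alpha_{j,d} + s) + (alpha_{j,d}-1) * t - logG(alpha_{j,d})``
    where ``s`` is the expected prior mass of the other taxa under the
    current responsibilities and ``t = psi(beta_j) - psi(sum beta)`` is the
    variational mean of ``log X_j``.
    """
    beta_row = np.asarray(beta_row, dtype=float)
    gamma_row = np.asarray(gamma_row, dtype=float)
    if np.any(beta_row <= 0):
        raise BMDDError("beta must be strictly positive")
    abar = gamma_row * hyper.alpha1 + (1 - gamma_row) * hyper.alpha0
    s = float(abar.sum() - abar[j])
    t = float(digamma(beta_row[j]) - digamma(beta_row.sum()))
    a0, a1 = float(hyper.alpha0[j]), float(hyper.alpha1[j])
    h0 = gammaln(a0 + s) + (a0 - 1) * t - gammaln(a0)
    h1 = gammaln(a1 + s) + (a1 - 1) * t - gammaln(a1)
    return float(h0), float(h1)


def _gamma_sweeps(
    W: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    hyper: Hyperparams,
    inner_tol: float,
    max_sweeps: int,
    refresh_beta: bool,
):
    """Cyclic responsibility updates across taxa, vectorised across samples.

    Samples are independent rows, so each taxon update handles all rows at
    once; the result does not depend on how rows would be partitioned
    across workers.  With ``refresh_beta`` the Dirichlet parameters are
    kept coupled to the responsibilities column by column (the joint
    coordinate ascent used inside :func:`e_step`); without it ``beta`` is
    held fixed, which is the standalone :func:`update_gamma` contract.
    """
    alpha0, alpha1 = hyper.alpha0, hyper.alpha1
    lp = logit(np.clip(hyper.pi, 1e-300, 1 - 1e-16))
    gl_a0 = gammaln(alpha0)
    gl_a1 = gammaln(alpha1)
    m = W.shape[1]

    beta = beta.copy()
    gamma = gamma.copy()
    abar = gamma * alpha1 + (1 - gamma) * alpha0
    s_total = abar.sum(axis=1)
    B = beta.sum(axis=1)
    psi_B = digamma(B)

    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(m):
            s_minus = s_total - abar[:, j]
            t = digamma(beta[:, j]) - psi_B
            h1 = gammaln(alpha1[j] + s_minus) + (alpha1[j] - 1) * t - gl_a1[j]
            h0 = gammaln(alpha0[j] + s_minus) + (alpha0[j] - 1) * t - gl_a0[j]
            g_new = expit(lp[j] + h1 - h0)
            delta = np.abs(g_new - gamma[:, j]).max()
            max_delta = max(max_delta, float(delta))
            gamma[:, j] = g_new
            abar_new = g_new * alpha1[j] + (1 - g_new) * alpha0[j]
            d_abar = abar_new - abar[:, j]
            abar[:, j] = abar_new
            s_total += d_abar
            if refresh_beta:
                beta[:, j] = W[:, j] + abar_new
                B += d_abar
                psi_B = digamma(B)
        if max_delta < inner_tol:
            break
    return beta, gamma, max_delta


def update_gamma(
    table: CountTable,
    state: VariationalState,
    hyper: Hyperparams,
    inner_tol: float = 1e-6,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Responsibility sweeps at fixed ``beta`` until the max change < tol."""
    _, gamma, _ = _gamma_sweeps(
        table.counts, state.beta, state.gamma, hyper,
        inner_tol, max_sweeps, refresh_beta=False,
    )
    return gamma


def e_step(
    table: CountTable,
    state: VariationalState,
    hyper: Hyperparams,
    inner_tol: float = 1e-6,
    max_sweeps: int = 50,
) -> VariationalState:
    """Joint coordinate ascent over ``(beta, gamma)`` to convergence."""
    beta = update_beta(table, state.gamma, hyper)
    beta, gamma, max_delta = _gamma_sweeps(
        table.counts, beta, state.gamma, hyper,
        inner_tol, max_sweeps, refresh_beta=True,
    )
    if max_delta >= inner_tol:
        # near-converged sweeps are routine mid-EM; only a large residual
        # change signals a genuine problem
        level = logging.WARNING if max_delta > 1e-3 else logging.INFO
        logger.log(
            level,
            "E-step did not converge within %d sweeps (max |d gamma| = %.2e)",
            max_sweeps, max_delta,
        )
    beta = update_beta(table, gamma, hyper)  # restore exact coupling
    return VariationalState(beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# M-step pieces


def update_pi(gamma: np.ndarray, clamp: float = 1e-4) -> np.ndarray:
    """Column means of the responsibilities, clamped into (0, 1)."""
    gamma = np.asarray(gamma, dtype=float)
    return np.clip(gamma.mean(axis=0), clamp, 1 - clamp)


def alpha_objective(
    alpha0: np.ndarray,
    alpha1: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Surrogate ELBO as a function of the shape modes, with its gradient.

    With ``abar_ij = gamma_ij*alpha1_j + (1-gamma_ij)*alpha0_j`` and
    ``t_ij = psi(beta_ij) - psi(sum_k beta_ik)``::

        F = sum_i logG(sum_j abar_ij) + sum_ij (abar_ij - 1) t_ij
            - sum_ij [gamma_ij logG(alpha1_j) + (1-gamma_ij) logG(alpha0_j)]

    The gradient follows from the chain rule through ``abar`` (digamma of
    the row totals) and is returned as the length-2m vector
    ``(dF/dalpha0, dF/dalpha1)``.
    """
    alpha0 = np.asarray(alpha0, dtype=float)
    alpha1 = np.asarray(alpha1, dtype=float)
    if np.any(alpha0 <= 0) or np.any(alpha1 <= 0):
        raise BMDDError("alpha shapes must be strictly positive")
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)

    t = digamma(beta) - digamma(beta.sum(axis=1, keepdims=True))
    abar = gamma * alpha1 + (1 - gamma) * alpha0
    row = abar.sum(axis=1)

    value = float(
        gammaln(row).sum()
        + ((abar - 1) * t).sum()
        - (gamma * gammaln(alpha1) + (1 - gamma) * gammaln(alpha0)).sum()
    )

    inner = digamma(row)[:, None] + t  # d F / d abar_ij
    grad0 = ((1 - gamma) * inner).sum(axis=0) - (1 - gamma).sum(axis=0) * digamma(alpha0)
    grad1 = (gamma * inner).sum(axis=0) - gamma.sum(axis=0) * digamma(alpha1)
    return value, np.concatenate([grad0, grad1])


def m_step(
    state: VariationalState,
    hyper: Hyperparams,
    config: FitConfig | None = None,
) -> tuple[Hyperparams, VariationalState]:
    """Update ``pi`` in closed form and ``alpha`` by box-constrained L-BFGS-B.

    The optimizer is warm-started at the previous shapes.  Afterwards the
    low-mode-first labelling is restored: any taxon with ``alpha0 > alpha1``
    has its modes swapped together with ``gamma -> 1-gamma`` and
    ``pi -> 1-pi`` (a likelihood-invariant relabeling).
    """
    config = config or FitConfig()
    beta, gamma = state.beta, state.gamma
    m = gamma.shape[1]
    pi = update_pi(gamma, config.pi_clamp)

    x0 = np.concatenate([hyper.alpha0, hyper.alpha1])

    def neg(x):
        v, g = alpha_objective(x[:m], x[m:], beta, gamma)
        return -v, -g

    res = minimize(
        neg, x0, jac=True, method="L-BFGS-B",
        bounds=[(config.alpha_min, config.alpha_max)] * (2 * m),
        options={"maxiter": 200},
    )
    f0, _ = alpha_objective(hyper.alpha0, hyper.alpha1, beta, gamma)
    if np.isfinite(res.fun) and -res.fun >= f0 - 1e-8 * abs(f0):
        alpha0, alpha1 = res.x[:m].copy(), res.x[m:].copy()
    else:
        logger.warning("alpha optimisation failed (%s); keeping previous shapes",
                       res.message)
        alpha0, alpha1 = hyper.alpha0.copy(), hyper.alpha1.copy()

    swap = alpha0 > alpha1
    if swap.any():
        alpha0[swap], alpha1[swap] = alpha1[swap].copy(), alpha0[swap].copy()
        gamma = gamma.copy()
        gamma[:, swap] = 1 - gamma[:, swap]
        pi = pi.copy()
        pi[swap] = 1 - pi[swap]

    new_hyper = Hyperparams(pi=pi, alpha0=alpha0, alpha1=alpha1)
    return new_hyper, VariationalState(beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# objective


def elbo_surrogate(
    table: CountTable, state: VariationalState, hyper: Hyperparams
) -> float:
    """Jensen-surrogate evidence lower bound at the current parameters.

    Assembles ``E[log p(W, X, delta)] + entropy`` under the mean field,
    with ``E[log X_ij] = psi(beta_ij) - psi(sum_k beta_ik)`` and the
    intractable ``E[log Gamma(sum_j alpha_{j,delta_ij})]`` replaced by the
    convexity bound ``log Gamma(sum_j abar_ij)``.  The result therefore
    lower-bounds the exact log marginal likelihood ``log p(W | pi, alpha)``.
    """
    W = table.counts
    beta, gamma = state.beta, state.gamma
    N = table.depths

    B = beta.sum(axis=1)
    t = digamma(beta) - digamma(B)[:, None]

    lik = float(
        (gammaln(N + 1) - gammaln(W + 1).sum(axis=1)).sum() + (W * t).sum()
    )

    prior_x, _ = alpha_objective(hyper.alpha0, hyper.alpha1, beta, gamma)

    prior_delta = float(
        (gamma * np.log(hyper.pi) + (1 - gamma) * np.log(1 - hyper.pi)).sum()
    )

    m = beta.shape[1]
    ent_g = float(
        (gammaln(beta).sum(axis=1) - gammaln(B)
         + (B - m) * digamma(B)
         - ((beta - 1) * digamma(beta)).sum(axis=1)).sum()
    )
    ent_q = float(-(xlogy(gamma, gamma) + xlogy(1 - gamma, 1 - gamma)).sum())

    return lik + prior_x + prior_delta + ent_g + ent_q


# ---------------------------------------------------------------------------
# fitting


def fit(table: CountTable, config: FitConfig | None = None) -> FitResult:
    """Variational EM: alternate E-step and M-step until the surrogate
    ELBO stabilises.

    Deterministic given the table and configuration.  All-zero taxa are
    retained (their imputed abundance is prior-driven); a single-sample
    table is rejected because the mixture weights are unidentifiable.
    """
    config = config or FitConfig()
    if table.n_samples < 2:
        raise BMDDError("fitting needs at least 2 samples")
    zero_taxa = np.flatnonzero(table.counts.sum(axis=0) == 0)
    if zero_taxa.size:
        logger.info("retaining %d all-zero taxa (prior-driven imputation)",
                    zero_taxa.size)

    hyper, state = init_params(table, config)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        state = e_step(table, state, hyper, config.inner_tol, config.max_sweeps)
        hyper, state = m_step(state, hyper, config)
        elbo = elbo_surrogate(table, state, hyper)
        trace.append(elbo)
        logger.debug("iter %3d  surrogate ELBO %.6f", n_iter, elbo)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(elbo - prev) < config.tol * abs(prev):
                converged = True
                break
    # final E-step so the returned state is the posterior at the final
    # hyperparameters
    state = e_step(table, state, hyper, config.inner_tol, config.max_sweeps)
    return FitResult(
        hyperparams=hyper,
        state=state,
        elbo_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# imputation outputs


def posterior_mean(
    state: VariationalState,
    sample_ids=None,
    taxon_ids=None,
) -> Composition:
    """Variational posterior mean of the composition: ``beta`` row-normalised."""
    values = state.beta / state.beta.sum(axis=1, keepdims=True)
    return Composition(values=values, sample_ids=sample_ids, taxon_ids=taxon_ids)


def posterior_sample(
    state: VariationalState,
    n_draws: int,
    seed: int | np.random.SeedSequence = 0,
    sample_ids=None,
    taxon_ids=None,
) -> list[Composition]:
    """Multiple imputations: each draw samples every row from Dirichlet(beta_i)."""
    if n_draws < 1:
        raise BMDDError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        g = rng.gamma(shape=state.beta)
        g = np.maximum(g, 1e-300)
        values = g / g.sum(axis=1, keepdims=True)
        draws.append(
            Composition(values=values, sample_ids=sample_ids, taxon_ids=taxon_ids)
        )
    return draws


# ---------------------------------------------------------------------------
# exact enumeration oracle (small m only)


def _enumerate_modes(counts_row: np.ndarray, hyper: Hyperparams):
    """Log-weights and shape vectors for every mode configuration delta."""
    counts_row = np.asarray(counts_row, dtype=float)
    m = counts_row.shape[0]
    if m > _MAX_ENUM_TAXA:
        raise BMDDError(
            f"enumeration over 2^m configurations refuses m > {_MAX_ENUM_TAXA}"
        )
    masks = (
        (np.arange(2**m)[:, None] >> np.arange(m)[None, :]) & 1
    ).astype(bool)
    alpha = np.where(masks, hyper.alpha1, hyper.alpha0)  # 2^m x m
    log_prior = (
        np.where(masks, np.log(hyper.pi), np.log1p(-hyper.pi)).sum(axis=1)
    )
    N = counts_row.sum()
    A = alpha.sum(axis=1)
    log_dm = (
        gammaln(N + 1) - gammaln(counts_row + 1).sum()
        + gammaln(A) - gammaln(N + A)
        + (gammaln(counts_row + alpha) - gammaln(alpha)).sum(axis=1)
    )
    return log_prior + log_dm, alpha, A, N


def exact_posterior_mean(counts_row: np.ndarray, hyper: Hyperparams) -> np.ndarray:
    """Exact posterior mean of one sample's composition by 2^m enumeration.

    Mixes the conjugate Dirichlet-multinomial means ``(W + alpha_delta) /
    (N + sum alpha_delta)`` with posterior configuration weights accumulated
    in log space.
    """
    logw, alpha, A, N = _enumerate_modes(counts_row, hyper)
    logw = logw - logw.max()
    w = np.exp(logw)
    w /= w.sum()
    means = (np.asarray(counts_row, dtype=float) + alpha) / (N + A)[:, None]
    return w @ means


def exact_log_marginal(table: CountTable, hyper: Hyperparams) -> float:
    """Exact ``log p(W | pi, alpha)`` by enumeration, summed over samples."""
    from scipy.special import logsumexp

    total = 0.0
    for i in range(table.n_samples):
        logw, _, _, _ = _enumerate_modes(table.counts[i], hyper)
        total += float(logsumexp(logw))
    return total
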