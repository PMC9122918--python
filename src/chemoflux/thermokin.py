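"""Loglinear thermokinetic model and Bayesian inference of intrinsic
turnover numbers.

The model integrates fluxome, proteome and metabolome data: with the
enzymatic specific flux j = J/e, the flux at condition c relative to a
reference condition 0 is

    j_c = J0/e0 + sum_i a_i * ln(X_ic / X_i0)

where a_i is the *intrinsic turnover number* of metabolite i — a condition-
independent coefficient with the dimension of kcat whose sign encodes
allosteric action (positive: activation; negative: inhibition). The a_i are
inferred by Markov chain Monte Carlo under a likelihood that integrates the
normal deviation model over the flux-variability (FVA) interval of each
condition, so experimental flux uncertainty widens the tolerance instead of
being ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .datatypes import ConfigurationError

DELTA_SQ_FLOOR = 1e-12  # keeps the likelihood finite at exact fits
RHAT_THRESHOLD = 1.1


@dataclass
class ThermoProblem:
    """Inputs of the intrinsic-turnover-number inference for one reaction.

    Condition 0 is the reference: its metabolite ratios are all exactly 1
    and its specific flux J0/e0 anchors the model. FVA bounds are on the
    reaction-flux scale and are divided by the enzyme level to obtain
    specific-flux bounds.
    """

    reaction: str
    metabolites: list[str]
    conditions: list[str]
    e: np.ndarray  # enzyme level per condition, > 0
    J_obs: np.ndarray  # observed (point-estimate) flux per condition
    J_lower: np.ndarray  # FVA lower bounds
    J_upper: np.ndarray  # FVA upper bounds
    x_ratio: np.ndarray  # (n_conditions, n_metabolites), X_ic / X_i0 > 0

    def __post_init__(self) -> None:
        for name in ("e", "J_obs", "J_lower", "J_upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.x_ratio = np.atleast_2d(np.asarray(self.x_ratio, dtype=float))
        n, I = self.x_ratio.shape
        if len(self.metabolites) != I or len(self.conditions) != n:
            raise ConfigurationError("shape mismatch between ids and arrays")
        if n <= I:
            raise ConfigurationError(
                f"need more conditions ({n}) than metabolites ({I}) for the "
                "residual variance denominator n - I"
            )
        if np.any(self.e <= 0):
            raise ConfigurationError("enzyme levels must be positive")
        if np.any(self.x_ratio <= 0):
            bad = self.metabolites[int(np.argwhere(self.x_ratio <= 0)[0][1])]
            raise ConfigurationError(f"non-positive ratio for metabolite {bad!r}")
        if not np.allclose(self.x_ratio[0], 1.0, atol=1e-9):
            raise ConfigurationError("reference-condition ratios must equal 1")
        if np.any(self.J_upper < self.J_lower):
            raise ConfigurationError("FVA upper bound below lower bound")

    # -- derived quantities on the specific-flux scale --------------------
    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def j_obs(self) -> np.ndarray:
        return self.J_obs / self.e

    @property
    def j_lower(self) -> np.ndarray:
        return self.J_lower / self.e

    @property
    def j_upper(self) -> np.ndarray:
        return self.J_upper / self.e

    @property
    def j0(self) -> float:
        """Reference enzymatic specific flux J0/e0."""
        return float(self.J_obs[0] / self.e[0])

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.x_ratio)


def from_kinetic_dataset(dataset, reaction: str) -> ThermoProblem:
    """Build a :class:`ThermoProblem` from a synthetic kinetic dataset."""
    ratios = dataset.ratios[reaction]
    return ThermoProblem(
        reaction=reaction,
        metabolites=list(ratios.index),
        conditions=list(dataset.fluxes.columns),
        e=dataset.enzymes.loc[reaction].to_numpy(),
        J_obs=dataset.fluxes.loc[reaction].to_numpy(),
        J_lower=dataset.fva_lower.loc[reaction].to_numpy(),
        J_upper=dataset.fva_upper.loc[reaction].to_numpy(),
        x_ratio=ratios.to_numpy().T,
    )


def predict_specific_flux(a, problem: ThermoProblem, condition: int | None = None):
    """j_pred_c = J0/e0 + sum_i a_i ln(X_ic/X_i0)."""
    a = np.asarray(a, dtype=float)
    j = problem.j0 + problem.log_ratio @ a
    return j if condition is None else float(j[condition])


def residual_variance(a, problem: ThermoProblem) -> float:
    """delta_c^2 = sum_c (j_pred_c - j_obs_c)^2 / (n - I)."""
    resid = predict_specific_flux(a, problem) - problem.j_obs
    return float(resid @ resid) / (problem.n_conditions - problem.n_metabolites)


def _log_norm_cdf_diff(zl: np.ndarray, zu: np.ndarray) -> np.ndarray:
    """log(Phi(zu) - Phi(zl)) for zl <= zu, robust in both tails."""
    flip = (zl + zu) > 0  # reflect right-tail intervals into the left tail
    lo = np.where(flip, -zu, zl)
    hi = np.where(flip, -zl, zu)
    log_hi = log_ndtr(hi)
    log_lo = log_ndtr(lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = log_hi + np.log1p(-np.exp(log_lo - log_hi))
    out = np.where(log_lo == log_hi, -np.inf, out)
    return out


def _loglik_batch(A: np.ndarray, problem: ThermoProblem) -> np.ndarray:
    """Interval log-likelihood for a batch of parameter vectors (C, I)."""
    A = np.atleast_2d(A)
    n, I = problem.n_conditions, problem.n_metabolites
    j_pred = problem.j0 + A @ problem.log_ratio.T  # (C, n)
    resid = j_pred - problem.j_obs[None, :]
    delta_sq = np.maximum((resid**2).sum(axis=1) / (n - I), DELTA_SQ_FLOOR)
    delta = np.sqrt(delta_sq)[:, None]
    lower = problem.j_lower[None, :]
    upper = problem.j_upper[None, :]
    width = problem.j_upper - problem.j_lower  # (n,)
    zl = (lower - j_pred) / delta
    zu = (upper - j_pred) / delta
    terms = np.empty_like(j_pred)
    pos = width > 0
    if np.any(pos):
        diff = _log_norm_cdf_diff(zl[:, pos], zu[:, pos])
        terms[:, pos] = diff - np.log(width[pos])[None, :]
    if np.any(~pos):
        # degenerate interval: continuity limit is the normal log-density
        z = zl[:, ~pos]
        terms[:, ~pos] = -0.5 * z**2 - 0.5 * math.log(2 * math.pi) - np.log(delta)
    return terms.sum(axis=1)


def log_likelihood(a, problem: ThermoProblem) -> float:
    """Sum over conditions of the FVA-interval likelihood terms.

    Each term is log[(Phi_{mu=j_pred, d2}(j_upper) - Phi(j_lower)) / width];
    a zero-width interval degenerates to the normal log-density at the
    point. Returns -inf when an interval is unreachable at zero residual
    variance.
    """
    return float(_loglik_batch(np.asarray(a, dtype=float)[None, :], problem)[0])


def default_prior(
    problem: ThermoProblem, variant: str = "std"
) -> tuple[float, float]:
    """Identical Normal prior for every a_i from the observed specific flux.

    mean = mean_c(j_obs); variance = std_c(j_obs)^2 ("std", default) or the
    squared standard error std^2/n ("se"). A zero variance is floored with
    a warning-level epsilon.
    """
    if problem.n_conditions < 2:
        raise ConfigurationError("need >= 2 conditions for the prior")
    j = problem.j_obs
    mean = float(np.mean(j))
    var = float(np.var(j))
    if variant == "se":
        var = var / problem.n_conditions
    elif variant != "std":
        raise ConfigurationError(f"unknown prior variant {variant!r}")
    return mean, max(var, DELTA_SQ_FLOOR)


@dataclass
class Posterior:
    """MCMC output for one reaction's intrinsic turnover numbers."""

    parameters: list[str]
    samples: np.ndarray  # (n_chains, n_samples, I)
    mean: np.ndarray
    ci_lower: np.ndarray  # 95% equal-tailed credible interval
    ci_upper: np.ndarray
    rhat: np.ndarray
    acceptance_rate: float
    prior: tuple[float, float]
    converged: bool

    def pooled(self, i: int) -> np.ndarray:
        return self.samples[:, :, i].ravel()


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from between/within-chain variance."""
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ConfigurationError("need >= 2 chains of equal length")
    m, n = x.shape
    if n < 10:
        raise ConfigurationError("chains too short")
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else math.inf
    v_hat = (n - 1) / n * W + B / n
    # values below 1 are finite-sample noise; floor at the ideal value
    return max(float(math.sqrt(v_hat / W)), 1.0)


def mcmc_infer(
    problem: ThermoProblem,
    n_chains: int = 4,
    n_samples: int = 5000,
    thin: int = 5,
    burn_in: int = 1000,
    seed: int = 0,
    prior: tuple[float, float] | None = None,
    target_acceptance: float = 0.234,
) -> Posterior:
    """Adaptive Metropolis sampling of the posterior over the a_i.

    Gaussian random-walk proposals with a per-chain scale adapted toward
    the target acceptance during burn-in and frozen afterwards (so the
    kept samples obey detailed balance). All chains run vectorized.
    Non-convergence (any split-free R-hat >= 1.1) is flagged on the
    returned posterior, never silently discarded.
    """
    rng = np.random.default_rng(seed)
    I = problem.n_metabolites
    mu0, var0 = prior or default_prior(problem)
    sd0 = math.sqrt(var0)

    def log_post(A: np.ndarray) -> np.ndarray:
        lp = -0.5 * ((A - mu0) ** 2 / var0).sum(axis=1)
        return _loglik_batch(A, problem) + lp

    current = rng.normal(mu0, sd0, size=(n_chains, I))
    cur_lp = log_post(current)
    scale = np.full(n_chains, 2.38 / math.sqrt(I) * sd0 * 0.5)
    kept = np.empty((n_chains, n_samples, I))
    n_keep = 0
    accepted_post = 0
    proposed_post = 0
    window_acc = np.zeros(n_chains)
    total_steps = burn_in + n_samples * thin
    adapt_every = 50

    for step in range(total_steps):
        prop = current + rng.standard_normal((n_chains, I)) * scale[:, None]
        prop_lp = log_post(prop)
        log_u = np.log(rng.random(n_chains))
        accept = log_u < (prop_lp - cur_lp)
        current = np.where(accept[:, None], prop, current)
        cur_lp = np.where(accept, prop_lp, cur_lp)
        if step < burn_in:
            window_acc += accept
            if (step + 1) % adapt_every == 0:
                rate = window_acc / adapt_every
                scale *= np.exp(rate - target_acceptance)
                window_acc[:] = 0.0
        else:
            accepted_post += int(accept.sum())
            proposed_post += n_chains
            if (step - burn_in + 1) % thin == 0:
                kept[:, n_keep, :] = current
                n_keep += 1

    rhat = np.array([gelman_rubin(kept[:, :, i]) for i in range(I)])
    pooled = kept.reshape(-1, I)
    return Posterior(
        parameters=list(problem.metabolites),
        samples=kept,
        mean=pooled.mean(axis=0),
        ci_lower=np.quantile(pooled, 0.025, axis=0),
        ci_upper=np.quantile(pooled, 0.975, axis=0),
        rhat=rhat,
        acceptance_rate=accepted_post / max(proposed_post, 1),
        prior=(mu0, var0),
        converged=bool(np.all(rhat < RHAT_THRESHOLD)),
    )


def classify_effect(
    posterior: Posterior, parameter: int | str, credibility: float = 0.95
) -> str:
    """Activation/inhibition call from the credible interval's sign.

    Refuses to classify an unconverged posterior.
    """
    if not posterior.converged:
        raise RuntimeError("posterior not converged; classification refused")
    if isinstance(parameter, str):
        parameter = posterior.parameters.index(parameter)
    tail = (1 - credibility) / 2
    x = posterior.pooled(parameter)
    lo, hi = np.quantile(x, [tail, 1 - tail])
    if lo > 0:
        return "activation"
    if hi < 0:
        return "inhibition"
    return "none"
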