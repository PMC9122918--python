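"""Loglinear thermokinetics: likelihood oracle, priors, MCMC, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from chemoflux import synthdata, thermokin
from chemoflux.datatypes import ConfigurationError
from chemoflux.thermokin import (
    ThermoProblem,
    classify_effect,
    default_prior,
    from_kinetic_dataset,
    gelman_rubin,
    log_likelihood,
    mcmc_infer,
    predict_specific_flux,
    residual_variance,
)


def _problem(a_true=(1.5,), n=9, fva_halfwidth=0.05, seed=0, ratio_log_sd=0.6):
    rng = np.random.default_rng(seed)
    I = len(a_true)
    x = np.exp(rng.normal(0, ratio_log_sd, (n, I)))
    x[0] = 1.0
    e = np.exp(rng.normal(0, 0.3, n))
    j0 = 3.0
    j = j0 + np.log(x) @ np.asarray(a_true)
    J = e * j
    half = fva_halfwidth * np.abs(J)
    return ThermoProblem(
        reaction="r", metabolites=[f"m{i}" for i in range(I)],
        conditions=[f"c{i}" for i in range(n)],
        e=e, J_obs=J, J_lower=J - half, J_upper=J + half, x_ratio=x,
    )


class TestPrediction:
    def test_reference_identity(self):
        p = _problem()
        pred = predict_specific_flux(np.array([0.7]), p)
        assert pred[0] == pytest.approx(p.j0)
        unit = _problem(a_true=(2.0,), fva_halfwidth=0.0)
        unit.x_ratio[:, 0] = 1.0
        assert np.allclose(
            predict_specific_flux(np.array([5.0]), unit), unit.j0)

    def test_euler_ratio(self):
        p = _problem(a_true=(2.0,))
        p.x_ratio[3, 0] = math.e
        pred = predict_specific_flux(np.array([2.0]), p, condition=3)
        assert pred == pytest.approx(p.j0 + 2.0)

    def test_matches_independent_sum(self, rng):
        p = _problem(a_true=(0.5, -1.0, 2.0), seed=4)
        a = rng.normal(size=3)
        pred = predict_specific_flux(a, p)
        manual = np.array([
            p.j0 + sum(a[i] * math.log(p.x_ratio[c, i]) for i in range(3))
            for c in range(p.n_conditions)
        ])
        assert np.abs(pred - manual).max() < 1e-14


class TestResidualVariance:
    def test_perfect_fit_is_zero(self):
        p = _problem(a_true=(1.5,))
        assert residual_variance(np.array([1.5]), p) == pytest.approx(0.0)

    def test_quadratic_scaling(self):
        p = _problem(a_true=(1.0,))
        base = residual_variance(np.array([1.3]), p)
        # scaling residuals by k scales delta^2 by k^2: residuals are
        # linear in (a - a_true) here
        scaled = residual_variance(np.array([1.6]), p)
        assert scaled == pytest.approx(4 * base, rel=1e-9)

    def test_denominator_n_minus_i(self):
        # residuals (1, -1, 0) with n=3, I=1 -> 2/(3-1) = 1
        p = ThermoProblem(
            reaction="r", metabolites=["m"], conditions=["a", "b", "c"],
            e=np.ones(3), J_obs=np.array([3.0, 2.0, 3.0]),
            J_lower=np.array([3.0, 2.0, 3.0]), J_upper=np.array([3.0, 2.0, 3.0]),
            x_ratio=np.array([[1.0], [1.0], [1.0]]),
        )
        # j_pred = j0 = 3 everywhere; residuals (0, 1, 0) -> 1/2
        assert residual_variance(np.array([0.0]), p) == pytest.approx(0.5)

    def test_underdetermined_rejected(self):
        with pytest.raises(ConfigurationError):
            ThermoProblem(
                reaction="r", metabolites=["m1", "m2"], conditions=["a", "b"],
                e=np.ones(2), J_obs=np.ones(2), J_lower=np.ones(2),
                J_upper=np.ones(2), x_ratio=np.ones((2, 2)),
            )


class TestLikelihood:
    def test_symmetric_interval_closed_form(self):
        p = _problem(a_true=(1.5,), n=9, fva_halfwidth=0.0)
        # widen one condition symmetrically around its j_pred at a = a_true+d
        a = np.array([1.7])
        jp = predict_specific_flux(a, p)
        d2 = max(residual_variance(a, p), 1e-12)
        w = 0.4
        p.J_lower = (jp - w / 2) * p.e
        p.J_upper = (jp + w / 2) * p.e
        ll = log_likelihood(a, p)
        term = math.log((2 * stats.norm.cdf(w / 2 / math.sqrt(d2)) - 1) / w)
        assert ll == pytest.approx(p.n_conditions * term, rel=1e-9)

    def test_exact_fit_saturates_interval_terms(self):
        # at the true parameters the residual variance collapses and every
        # interval captures all the mass: ll = -sum log(width)
        p = _problem(a_true=(0.8, -0.5), n=9, fva_halfwidth=0.08, seed=5)
        ll = log_likelihood(np.array([0.8, -0.5]), p)
        assert ll == pytest.approx(
            -float(np.sum(np.log(p.j_upper - p.j_lower))), rel=1e-12)

    def test_quadrature_agreement_grid(self):
        p = _problem(a_true=(0.8, -0.5), n=9, fva_halfwidth=0.08, seed=5)
        for a in (np.array([0.6, -0.3]), np.array([0.0, 0.0]),
                  np.array([2.0, 1.0])):
            d2 = max(residual_variance(a, p), 1e-12)
            jp = predict_specific_flux(a, p)
            manual = 0.0
            for c in range(p.n_conditions):
                lo, up = p.j_lower[c], p.j_upper[c]
                xs = np.linspace(lo, up, 4001)
                integral = np.trapezoid(
                    stats.norm.pdf(xs, jp[c], math.sqrt(d2)), xs)
                manual += math.log(integral / (up - lo))
            assert log_likelihood(a, p) == pytest.approx(manual, rel=1e-6)

    def test_degenerate_interval_limit_is_logpdf(self):
        p = _problem(a_true=(1.2,), n=9, fva_halfwidth=0.0, seed=6)
        a = np.array([1.0])
        d2 = max(residual_variance(a, p), 1e-12)
        jp = predict_specific_flux(a, p)
        exact = sum(
            stats.norm.logpdf(p.j_obs[c], jp[c], math.sqrt(d2))
            for c in range(p.n_conditions)
        )
        assert log_likelihood(a, p) == pytest.approx(exact, rel=1e-12)
        # widths shrinking toward zero converge to the point limit
        for w in (1e-2, 1e-4, 1e-6, 1e-8):
            q = _problem(a_true=(1.2,), n=9, fva_halfwidth=0.0, seed=6)
            q.J_lower = q.J_obs - w * q.e / 2
            q.J_upper = q.J_obs + w * q.e / 2
            assert log_likelihood(a, q) == pytest.approx(exact, rel=1e-4)

    def test_tail_monotonicity(self):
        p = _problem(a_true=(1.0,), n=9, fva_halfwidth=0.02, seed=7)
        lls = [log_likelihood(np.array([1.0 + shift]), p)
               for shift in (0.0, 1.0, 3.0, 10.0)]
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestPrior:
    def test_summary_statistics(self):
        p = _problem(a_true=(1.0,), seed=8)
        mean, var = default_prior(p)
        assert mean == pytest.approx(float(np.mean(p.j_obs)))
        assert var == pytest.approx(float(np.var(p.j_obs)))
        mean_se, var_se = default_prior(p, variant="se")
        assert var_se == pytest.approx(var / p.n_conditions)

    def test_constant_j_obs(self):
        p = ThermoProblem(
            reaction="r", metabolites=["m"], conditions=list("abc"),
            e=np.ones(3), J_obs=np.full(3, 2.0), J_lower=np.full(3, 2.0),
            J_upper=np.full(3, 2.0), x_ratio=np.ones((3, 1)),
        )
        mean, var = default_prior(p)
        assert mean == pytest.approx(2.0)
        assert var > 0  # epsilon floor


class TestGelmanRubin:
    def test_identical_chains_give_one(self, rng):
        x = rng.normal(size=200)
        assert gelman_rubin(np.stack([x, x, x])) == pytest.approx(1.0)

    def test_disjoint_chains_diverge(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(100, 1, 200)
        assert gelman_rubin(np.stack([a, b])) > 10

    def test_textbook_formula(self, rng):
        chains = rng.normal(size=(4, 120))
        m, n = chains.shape
        W = chains.var(axis=1, ddof=1).mean()
        B = n * chains.mean(axis=1).var(ddof=1)
        expected = max(math.sqrt(((n - 1) / n * W + B / n) / W), 1.0)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-10)

    def test_single_chain_rejected(self):
        with pytest.raises(ConfigurationError):
            gelman_rubin(np.ones((1, 50)))


class TestMCMC:
    def test_flat_likelihood_recovers_prior(self):
        # all ratios 1: the likelihood is constant in a, so the posterior
        # must reproduce the prior
        n = 9
        e = np.exp(np.random.default_rng(3).normal(0, 0.2, n))
        J = 3.0 * e
        p = ThermoProblem(
            reaction="r", metabolites=["m"], conditions=[f"c{i}" for i in range(n)],
            e=e, J_obs=J, J_lower=J * 0.95, J_upper=J * 1.05,
            x_ratio=np.ones((n, 1)),
        )
        post = mcmc_infer(p, n_chains=4, n_samples=2500, thin=4, burn_in=1000,
                          seed=21)
        mu0, var0 = post.prior
        ks = stats.kstest(post.pooled(0), "norm",
                          args=(mu0, math.sqrt(var0))).statistic
        assert ks < 0.05

    def test_recovers_planted_turnover_numbers(self):
        truth = synthdata.random_true_kinetics("rx", seed=17, n_metabolites=2)
        ds = synthdata.generate_kinetic_dataset([truth], fva_halfwidth=0.02)
        prob = from_kinetic_dataset(ds, "rx")
        post = mcmc_infer(prob, seed=5)
        assert post.converged
        assert np.all(post.ci_lower <= truth.a_true)
        assert np.all(truth.a_true <= post.ci_upper)

    def test_seed_determinism_and_cross_seed_stability(self):
        truth = synthdata.random_true_kinetics("rx", seed=23, n_metabolites=1)
        ds = synthdata.generate_kinetic_dataset([truth], fva_halfwidth=0.05)
        prob = from_kinetic_dataset(ds, "rx")
        a = mcmc_infer(prob, n_samples=2000, seed=1)
        b = mcmc_infer(prob, n_samples=2000, seed=1)
        assert np.array_equal(a.samples, b.samples)
        c = mcmc_infer(prob, n_samples=2000, seed=2)
        pooled = a.pooled(0)
        mcse = pooled.std() / math.sqrt(200)  # generous ESS >= 200
        assert abs(a.mean[0] - c.mean[0]) < 3 * mcse + 0.05

    def test_posterior_interval_sanity(self):
        truth = synthdata.random_true_kinetics("rx", seed=29, n_metabolites=2)
        ds = synthdata.generate_kinetic_dataset([truth], fva_halfwidth=0.05)
        post = mcmc_infer(from_kinetic_dataset(ds, "rx"),
                          n_samples=2000, seed=9)
        assert np.all(post.ci_lower <= post.ci_upper)
        assert np.all(post.rhat >= 1 - 1e-6)
        assert np.all(post.mean >= post.samples.min(axis=(0, 1)))
        assert np.all(post.mean <= post.samples.max(axis=(0, 1)))


class TestClassification:
    def _posterior_with_interval(self, lo, hi):
        rng = np.random.default_rng(0)
        mid = (lo + hi) / 2
        sd = max((hi - lo) / 3.92, 1e-6)
        samples = rng.normal(mid, sd, size=(4, 2000, 1))
        return thermokin.Posterior(
            parameters=["m"], samples=samples, mean=np.array([mid]),
            ci_lower=np.array([lo]), ci_upper=np.array([hi]),
            rhat=np.array([1.0]), acceptance_rate=0.3, prior=(0.0, 1.0),
            converged=True,
        )

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.2, 1.4, "activation"), (-1.4, -0.2, "inhibition"),
         (-0.1, 0.3, "none")],
    )
    def test_sign_calls(self, lo, hi, expected):
        post = self._posterior_with_interval(lo, hi)
        assert classify_effect(post, 0) == expected

    def test_unconverged_refused(self):
        post = self._posterior_with_interval(0.2, 1.4)
        post.converged = False
        with pytest.raises(RuntimeError, match="refused"):
            classify_effect(post, 0)
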