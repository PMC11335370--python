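"""Population model: hyper-priors, conjugate blocks, divergence detection."""

import copy
import math

import numpy as np
import pytest
from scipy import stats

import silkpop as sp
from silkpop.bayes_population import _wishart_bugs

FAST = sp.MCMCConfig(n_iter=6000, n_burn=3000, n_chains=2, seed=0)


@pytest.fixture(scope="module")
def cohort7():
    sc = sp.scenario_from_preset("plasma-like", n_patients=7)
    pats, extras = sp.simulate_cohort(sc, seed=2)
    return pats, extras["truth"]


class TestInformativePrior:
    def test_mean_and_reciprocal_variance(self):
        ests = {
            "a": sp.KineticParams(lam=math.exp(-1.0), kc=math.exp(-2.0)),
            "b": sp.KineticParams(lam=math.exp(-2.0), kc=math.exp(-4.0)),
        }
        hyper = sp.build_informative_prior(ests)
        assert hyper.mu[1] == pytest.approx(-3.0)
        assert hyper.mu[0] == pytest.approx(-1.5)
        # sample variance of (-2, -4) is 2 -> precision 1/2
        assert hyper.sigma_inv[1, 1] == pytest.approx(0.5)
        assert hyper.mode == "informative"
        # Wishart settings unchanged from the vague defaults
        assert np.allclose(hyper.wishart_R, np.diag([0.175, 0.175]))

    def test_identical_estimates_rejected(self):
        ests = {k: sp.KineticParams(lam=0.1, kc=0.2) for k in "abc"}
        with pytest.raises(ValueError):
            sp.build_informative_prior(ests)

    def test_vague_mode_ignores_estimates(self):
        vague = sp.PopulationHyperPrior()
        assert vague.mode == "vague"
        assert vague.sigma_inv[0, 0] == pytest.approx(1e-4)


class TestJointDensity:
    def _state(self, cohort, rng):
        K = len(cohort)
        return {
            "mu_theta": np.array([-3.0, -2.3]),
            "omega": np.array([[0.05, 0.01], [0.01, 0.05]]),
            "theta": np.array([[-3.0, -2.3]] * K) + 0.05 * rng.standard_normal((K, 2)),
            "shifts": 0.002 * rng.standard_normal(K),
            "sigma": 0.01,
        }

    def test_patient_permutation_invariance(self, cohort7):
        cohort, _ = cohort7
        rng = np.random.default_rng(0)
        state = self._state(cohort, rng)
        hyper = sp.PopulationHyperPrior()
        a = sp.log_posterior_population(state, cohort, hyper)
        perm = [3, 1, 0, 2, 6, 5, 4]
        state_p = dict(state, theta=state["theta"][perm], shifts=state["shifts"][perm])
        cohort_p = [cohort[i] for i in perm]
        b = sp.log_posterior_population(state_p, cohort_p, hyper)
        assert a == pytest.approx(b, rel=1e-12)

    def test_shift_structure_of_likelihood(self, cohort7):
        """Adding a constant to one patient's RIAs and shift leaves the
        likelihood terms unchanged (only the shift prior moves)."""
        cohort, _ = cohort7
        rng = np.random.default_rng(1)
        # huge shift-prior variance isolates the likelihood terms
        hyper = sp.PopulationHyperPrior(var_s=1e12)
        state = self._state(cohort, rng)
        a = sp.log_posterior_population(state, cohort, hyper)
        cohort2 = copy.deepcopy(cohort)
        cohort2[0].ria = cohort2[0].ria + 0.05
        state2 = copy.deepcopy(state)
        state2["shifts"][0] -= 0.05
        b = sp.log_posterior_population(state2, cohort2, hyper)
        assert a == pytest.approx(b, rel=1e-9)

    def test_invalid_states_return_minus_inf(self, cohort7):
        cohort, _ = cohort7
        rng = np.random.default_rng(2)
        state = self._state(cohort, rng)
        hyper = sp.PopulationHyperPrior()
        bad_sigma = dict(state, sigma=-1.0)
        assert sp.log_posterior_population(bad_sigma, cohort, hyper) == -math.inf
        bad_omega = dict(state, omega=np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert sp.log_posterior_population(bad_omega, cohort, hyper) == -math.inf

    def test_single_patient_huge_omega_nests_individual_model(self, cohort7):
        """With one patient, a fixed huge Omega and flat hyper-priors, log
        density differences in (theta, s) match the individual model."""
        cohort, _ = cohort7
        pat = cohort[0]
        hyper = sp.PopulationHyperPrior(var_s=1e-3)
        prior = sp.PriorSpec(mu_llam=0.0, var_llam=1e8, mu_lkc=0.0, var_lkc=1e8,
                             var_s=1e-3)
        omega = np.eye(2) * 1e8
        mu = np.zeros(2)

        def pop_lp(theta, s, sigma):
            state = {"mu_theta": mu, "omega": omega,
                     "theta": np.array([theta]), "shifts": np.array([s]),
                     "sigma": sigma}
            return sp.log_posterior_population(state, [pat], hyper)

        s1a = ((-3.0, -2.3), 0.002, 0.01)
        s1b = ((-2.8, -2.5), -0.003, 0.01)
        d_pop = pop_lp(*s1a) - pop_lp(*s1b)
        d_ind = (
            sp.log_posterior((*s1a[0], s1a[1], s1a[2]), pat.times, pat.ria,
                             pat.weights, prior)
            - sp.log_posterior((*s1b[0], s1b[1], s1b[2]), pat.times, pat.ria,
                               pat.weights, prior)
        )
        assert d_pop == pytest.approx(d_ind, rel=1e-6, abs=1e-6)


class TestWishartConvention:
    def test_prior_moment_matches_bugs_expectation(self):
        R = np.array([[0.2, 0.05], [0.05, 0.3]])
        df = 4.0
        rng = np.random.default_rng(7)
        draws = np.mean([_wishart_bugs(R, df, rng) for _ in range(100_000)], axis=0)
        assert np.allclose(draws, df * np.linalg.inv(R), rtol=0.02)

    def test_agrees_with_scipy_parameterization(self):
        R = np.diag([0.175, 0.175])
        df = 2.0
        rng = np.random.default_rng(8)
        ours = np.mean([_wishart_bugs(R, df, rng) for _ in range(50_000)], axis=0)
        theirs = stats.wishart(df=df, scale=np.linalg.inv(R)).mean()
        assert np.allclose(ours, theirs, rtol=0.03, atol=0.15)


@pytest.fixture(scope="module")
def tiny():
    sc = sp.scenario_from_preset("plasma-like", n_patients=2, t_spacing=9.0,
                                 duplicates=1)
    pats, extras = sp.simulate_cohort(sc, seed=5)
    hyper = sp.PopulationHyperPrior(mu=np.array([-3.0, -2.3]),
                                    sigma_inv=np.diag([1.0, 1.0]))
    state = {
        "mu_theta": np.array([-3.0, -2.3]),
        "omega": np.array([[0.05, 0.01], [0.01, 0.05]]),
        "theta": np.array([[-3.1, -2.2], [-2.9, -2.4]]),
        "shifts": np.array([0.004, -0.002]),
        "sigma": 0.012,
    }
    return pats, hyper, state


class TestConjugateBlocksAgainstGrid:
    """Gibbs full conditionals vs brute-force densities on a tiny instance."""

    def _grid_density(self, xs, lp_fn):
        logd = np.array([lp_fn(x) for x in xs])
        d = np.exp(logd - logd.max())
        return d / np.trapezoid(d, xs)

    def test_shift_full_conditional(self, tiny):
        pats, hyper, state = tiny
        pat = pats[0]
        from silkpop.kinetics import beta_values
        beta = beta_values(*state["theta"][0], pat.times)
        sigma2 = state["sigma"] ** 2
        prec = 1.0 / hyper.var_s + pat.weights.sum() / sigma2
        mean = (hyper.mu_s / hyper.var_s
                + float(np.dot(pat.weights, beta - pat.ria)) / sigma2) / prec

        def lp(s):
            st = copy.deepcopy(state)
            st["shifts"][0] = s
            return sp.log_posterior_population(st, pats, hyper)

        xs = np.linspace(mean - 5 / math.sqrt(prec), mean + 5 / math.sqrt(prec), 800)
        dens = self._grid_density(xs, lp)
        expected = stats.norm.pdf(xs, mean, 1.0 / math.sqrt(prec))
        assert np.max(np.abs(dens - expected)) / expected.max() < 1e-3

    def test_sigma_full_conditional(self, tiny):
        pats, hyper, state = tiny
        from silkpop.kinetics import beta_values
        wss = 0.0
        n_tot = 0
        for k, pat in enumerate(pats):
            beta = beta_values(*state["theta"][k], pat.times)
            resid = pat.ria - (beta - state["shifts"][k])
            wss += float(np.dot(pat.weights, resid ** 2))
            n_tot += pat.times.size
        shape = hyper.gamma_shape + 0.5 * n_tot
        rate = hyper.gamma_rate + 0.5 * wss

        def lp(tau):
            st = dict(state, sigma=tau ** -0.5)
            return sp.log_posterior_population(st, pats, hyper)

        mode = shape / rate
        xs = np.linspace(max(mode - 6 * math.sqrt(shape) / rate, 1e-6),
                         mode + 8 * math.sqrt(shape) / rate, 1500)
        dens = self._grid_density(xs, lp)
        expected = stats.gamma.pdf(xs, a=shape, scale=1.0 / rate)
        assert np.max(np.abs(dens - expected)) / expected.max() < 2e-3

    def test_mu_theta_full_conditional(self, tiny):
        pats, hyper, state = tiny
        omega_inv = np.linalg.inv(state["omega"])
        K = len(pats)
        prec = hyper.sigma_inv + K * omega_inv
        cov = np.linalg.inv(prec)
        mean = cov @ (hyper.sigma_inv @ hyper.mu
                      + omega_inv @ state["theta"].sum(axis=0))

        def lp(x):
            st = dict(state, mu_theta=np.array([x, mean[1]]))
            return sp.log_posterior_population(st, pats, hyper)

        sd0 = math.sqrt(cov[0, 0])
        xs = np.linspace(mean[0] - 5 * sd0, mean[0] + 5 * sd0, 800)
        dens = self._grid_density(xs, lp)
        # conditional slice of the bivariate normal at mu2 = mean2
        cond_sd = math.sqrt(1.0 / prec[0, 0])
        expected = stats.norm.pdf(xs, mean[0], cond_sd)
        assert np.max(np.abs(dens - expected)) / expected.max() < 1e-3


class TestDivergenceDetection:
    def _stationary(self, rng, n=2000):
        return 0.1 * rng.standard_normal((2, n, 2)) + np.array([-3.0, -2.3])

    def test_stationary_chains_not_flagged(self):
        rng = np.random.default_rng(0)
        verdict = sp.detect_divergence(self._stationary(rng))
        assert not verdict["diverged"]

    def test_opposite_drift_flagged(self):
        rng = np.random.default_rng(1)
        chains = self._stationary(rng)
        n = chains.shape[1]
        drift = 0.004 * np.arange(n)
        chains[0, :, 0] += drift
        chains[0, :, 1] -= drift
        verdict = sp.detect_divergence(chains)
        assert verdict["diverged"]
        assert verdict["details"][0]["reason"] == "opposite-drift"

    def test_sanity_bound_flagged(self):
        rng = np.random.default_rng(2)
        chains = self._stationary(rng)
        chains[1, -5:, 0] = 20.0
        verdict = sp.detect_divergence(chains)
        assert verdict["diverged"]
        assert any(d["reason"] == "sanity-bound" for d in verdict["details"])

    def test_bounded_oscillation_not_flagged(self):
        n = 2000
        osc = np.sin(np.linspace(0, 40 * np.pi, n))
        chains = np.stack([np.stack([osc, -osc], axis=1)] * 2)
        verdict = sp.detect_divergence(chains + np.array([-3.0, -2.3]))
        assert not verdict["diverged"]


class TestPopulationSampler:
    def test_same_seed_reproduces_draws(self, cohort7):
        cohort, _ = cohort7
        cfg = sp.MCMCConfig(n_iter=1500, n_burn=700, seed=3)
        hyper = sp.PopulationHyperPrior()
        a = sp.sample_population(cohort, hyper, cfg, divergence_check=False)
        b = sp.sample_population(cohort, hyper, cfg, divergence_check=False)
        assert np.array_equal(a.mu_theta, b.mu_theta)
        assert np.array_equal(a.omega, b.omega)

    def test_omega_draws_symmetric_positive_definite(self, cohort7):
        cohort, _ = cohort7
        cfg = sp.MCMCConfig(n_iter=1500, n_burn=700, seed=4)
        post = sp.sample_population(cohort, sp.PopulationHyperPrior(), cfg,
                                    divergence_check=False)
        om = post.flat("omega")
        assert np.allclose(om, np.swapaxes(om, 1, 2))
        eig = np.linalg.eigvalsh(om)
        assert np.all(eig > 0)

    def test_near_identical_patients_shrink_to_population_mean(self):
        """With Omega ~ 0 in truth, posterior patient means huddle around
        the population mean more tightly than the observation noise."""
        sc = sp.scenario_from_preset("plasma-like", n_patients=5,
                                     omega=np.zeros((2, 2)))
        pats, extras = sp.simulate_cohort(sc, seed=6)
        post = sp.sample_population(pats, sp.PopulationHyperPrior(), FAST)
        th = post.flat("theta")
        per_patient_means = th.mean(axis=0)
        spread = per_patient_means.std(axis=0)
        assert np.all(spread < 0.05)

    def test_qnb_start_requires_estimates(self, cohort7):
        cohort, _ = cohort7
        stripped = [copy.deepcopy(p) for p in cohort]
        for p in stripped:
            p.qnb_estimate = None
        with pytest.raises(ValueError):
            sp.sample_population(stripped, sp.PopulationHyperPrior(), FAST,
                                 init="qnb-start")

    def test_recovers_population_mean_in_credible_interval(self, cohort7):
        cohort, truth = cohort7
        post = sp.sample_population(cohort, sp.PopulationHyperPrior(), FAST)
        mu = post.flat("mu_theta")
        for j in range(2):
            lo, hi = np.percentile(mu[:, j], [2.5, 97.5])
            assert lo <= truth["mu_theta"][j] <= hi
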