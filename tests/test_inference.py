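import math

import numpy as np
import pytest
from scipy import stats

from planktonssm.dynamics import LakeParams, simulate_trajectory, standardize
from planktonssm.inference import (
    LakeData,
    MCMCConfig,
    PosteriorDraws,
    Prior,
    PriorSpec,
    effective_sample_size,
    fit_mcmc,
    grid_posterior,
    log_likelihood,
    log_posterior,
    split_rhat,
    summarize_posterior,
)
from planktonssm.params import HyperParams
from planktonssm.synth import generate_dataset, paper_preset

from conftest import make_single_lake_data


def brute_force_loglik(data: LakeData, theta: HyperParams) -> float:
    """Independent direct-summation oracle: per-lake scalar simulation via
    the public dynamics API plus scipy normal densities."""
    total = 0.0
    for j in range(data.n_lakes):
        c = theta.alpha_c + theta.beta_c * data.st[j]
        psi = math.exp(theta.alpha_psi + theta.beta_psi * data.sp[j])
        m = theta.m_fish if data.fish[j] else theta.m_nofish
        traj = simulate_trajectory(
            theta.x1[j], theta.y1[j], LakeParams(c=c, psi=psi, m=m, e=theta.e),
            data.n_times,
        )
        total += stats.norm.logpdf(data.obs_x[j], traj.x, theta.sigma_x).sum()
        total += stats.norm.logpdf(data.obs_y[j], traj.y, theta.sigma_y).sum()
    return total


def random_two_lake_data(seed=0):
    rng = np.random.default_rng(seed)
    theta = HyperParams(
        alpha_c=0.08, beta_c=-0.02, alpha_psi=math.log(0.4), beta_psi=0.3,
        m_fish=0.5, m_nofish=0.05, e=0.4, sigma_x=0.2, sigma_y=0.3,
        x1=np.array([1.2, 0.8]), y1=np.array([2.0, 3.0]),
    )
    data = LakeData(
        lake_ids=["a", "b"],
        fish=np.array([True, False]),
        st=standardize([10.5, 12.5]),
        sp=standardize([3.0, 12.0]),
        obs_x=rng.uniform(0.2, 3.0, (2, 3)),
        obs_y=rng.uniform(0.5, 4.0, (2, 3)),
    )
    return data, theta


class TestLogLikelihood:
    def test_single_point_standard_normal(self):
        theta = HyperParams(
            alpha_c=0.1, beta_c=0.0, alpha_psi=0.0, beta_psi=0.0,
            m_fish=0.2, m_nofish=0.2, e=0.5, sigma_x=1.0, sigma_y=1.0,
            x1=np.array([2.0]), y1=np.array([3.0]),
        )
        data = LakeData(
            lake_ids=["A"], fish=np.array([False]), st=np.zeros(1), sp=np.zeros(1),
            obs_x=np.array([[2.0]]), obs_y=np.array([[3.0]]),
        )
        # two zero-residual standard-normal densities
        assert log_likelihood(data, theta) == pytest.approx(2 * math.log(1 / math.sqrt(2 * math.pi)))

    def test_doubling_sigma_costs_log2_per_observation(self):
        data, theta = make_single_lake_data(sigma=0.0)  # zero residuals
        theta1 = theta.copy()
        theta1.sigma_x, theta1.sigma_y = 0.5, 1.0
        theta2 = theta.copy()
        theta2.sigma_x, theta2.sigma_y = 1.0, 1.0
        n_x = data.n_times
        assert log_likelihood(data, theta1) - log_likelihood(data, theta2) == pytest.approx(
            n_x * math.log(2)
        )

    def test_matches_brute_force_oracle(self):
        data, theta = random_two_lake_data(seed=1)
        assert log_likelihood(data, theta) == pytest.approx(
            brute_force_loglik(data, theta), abs=1e-9
        )

    def test_invalid_theta_returns_neg_inf(self):
        data, theta = random_two_lake_data()
        bad = theta.copy()
        bad.e = 1.5
        assert log_likelihood(data, bad) == float("-inf")

    def test_lake_relabelling_is_symmetric(self):
        data, theta = random_two_lake_data(seed=2)
        flipped = LakeData(
            lake_ids=data.lake_ids[::-1], fish=data.fish[::-1],
            st=data.st[::-1], sp=data.sp[::-1],
            obs_x=data.obs_x[::-1].copy(), obs_y=data.obs_y[::-1].copy(),
        )
        t2 = theta.copy()
        t2.x1 = theta.x1[::-1].copy()
        t2.y1 = theta.y1[::-1].copy()
        assert log_likelihood(data, theta) == pytest.approx(log_likelihood(flipped, t2))


class TestLogPosterior:
    def _priors(self, data):
        pri = PriorSpec.default(data)
        return pri

    def test_additivity(self):
        data, theta = random_two_lake_data(seed=3)
        priors = self._priors(data)
        lp = log_posterior(data, theta, priors)
        ll = log_likelihood(data, theta)
        prior_part = lp - ll
        # flat-prior constancy: uniform components do not change with theta
        t2 = theta.copy()
        t2.m_fish = 0.7
        assert (log_posterior(data, t2, priors) - log_likelihood(data, t2)) == pytest.approx(
            prior_part
        )

    def test_off_support_is_neg_inf(self):
        data, theta = random_two_lake_data()
        priors = self._priors(data)
        bad = theta.copy()
        bad.m_nofish = -0.2
        assert log_posterior(data, bad, priors) == float("-inf")


class TestGridPosterior:
    def test_mass_sums_to_one_and_symmetric_mean(self):
        data, truth = make_single_lake_data()
        pri = {n: Prior("fixed", (getattr(truth, n),)) for n in HyperParams.GLOBAL_NAMES}
        pri["alpha_c"] = Prior("normal", (0.1, 0.3))
        pri["x1[A]"] = Prior("fixed", (1.0,))
        pri["y1[A]"] = Prior("fixed", (0.5,))
        priors = PriorSpec(pri)
        grid = np.linspace(-0.8, 1.0, 301)
        mass = grid_posterior(data, priors, "alpha_c", grid, truth)
        assert mass.sum() == pytest.approx(1.0)
        assert (mass >= 0).all()

    def test_flat_limit_is_uniform(self):
        data, truth = make_single_lake_data()
        big = truth.copy()
        big.sigma_x = 1e6
        big.sigma_y = 1e6
        pri = {n: Prior("fixed", (getattr(big, n),)) for n in HyperParams.GLOBAL_NAMES}
        pri["m_nofish"] = Prior("uniform", (0.0, 1.0))
        pri["x1[A]"] = Prior("fixed", (1.0,))
        pri["y1[A]"] = Prior("fixed", (0.5,))
        grid = np.linspace(0.01, 0.99, 99)
        mass = grid_posterior(data, PriorSpec(pri), "m_nofish", grid, big)
        np.testing.assert_allclose(mass[1:-1], mass[1], rtol=1e-6)

    def test_conjugate_closed_form_for_sigma(self):
        """With everything fixed but sigma_x and a flat prior on it, the
        precision 1/sigma^2 is Gamma-distributed (truncated); the grid
        evaluator must reproduce that closed form."""
        data, truth = make_single_lake_data(sigma=0.3, n_times=5)
        pri = {n: Prior("fixed", (getattr(truth, n),)) for n in HyperParams.GLOBAL_NAMES}
        pri["sigma_x"] = Prior("uniform", (1e-3, 3.0))
        pri["x1[A]"] = Prior("fixed", (1.0,))
        pri["y1[A]"] = Prior("fixed", (0.5,))
        priors = PriorSpec(pri)
        grid = np.linspace(0.02, 2.999, 3000)
        mass = grid_posterior(data, priors, "sigma_x", grid, truth)

        traj = simulate_trajectory(1.0, 0.5, LakeParams(c=0.1, psi=0.3, m=0.2, e=0.5), 5)
        ss = float(((data.obs_x[0] - traj.x) ** 2).sum())
        n = data.n_times
        # p(sigma) propto sigma^-n exp(-ss/(2 sigma^2)) on the prior box;
        # integrate analytically via the Gamma((n-1)/2, ss/2) law of 1/sigma^2
        dens = grid ** (-n) * np.exp(-ss / (2 * grid**2))
        w = np.gradient(grid)
        expected = dens * w / (dens * w).sum()
        np.testing.assert_allclose(mass, expected, atol=1e-6)
        grid_mean = (grid * mass).sum()
        closed_mean = (grid * expected).sum()
        assert grid_mean == pytest.approx(closed_mean, rel=1e-6)


class TestRhat:
    def test_same_distribution_is_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 4000))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.02)

    def test_separated_chains_detected(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(-10, 1, 1000), rng.normal(10, 1, 1000)])
        r = split_rhat(chains)
        # direct evaluation of the split formula
        n = 500
        halves = np.concatenate([chains[:, :n], chains[:, n:]], axis=0)
        W = halves.var(axis=1, ddof=1).mean()
        B = n * halves.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert r == pytest.approx(expected, rel=1e-12)
        assert r > 3.0

    def test_chain_permutation_invariant(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 500)) + np.array([[0.0], [0.5], [1.0]])
        assert split_rhat(chains) == pytest.approx(split_rhat(chains[::-1]), rel=1e-12)

    def test_agrees_with_arviz_split_form(self):
        import arviz as az

        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 800)).cumsum(axis=1) * 0.01 + rng.normal(size=(3, 800))
        ours = split_rhat(chains)
        theirs = float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_constant_draws_return_one_with_warning(self):
        chains = np.ones((2, 100))
        with pytest.warns(UserWarning):
            assert split_rhat(chains) == 1.0


def _draws_from_array(arr, name="p"):
    arr = np.asarray(arr, dtype=float)
    cfg = MCMCConfig(n_chains=2, n_iter=4, n_burnin=2, thin=1, seed=0)
    return PosteriorDraws(draws=arr[:, :, None], names=[name], config=cfg, seed=0)


class TestSummarize:
    def test_direct_counts(self):
        d = _draws_from_array([[-1.0, 1.0], [1.0, 1.0]])
        s = summarize_posterior(d).loc["p"]
        assert s["mean"] == pytest.approx(0.5)
        assert s["prob_below_zero"] == pytest.approx(0.25)

    def test_linear_interpolation_quantiles(self):
        d = _draws_from_array(np.arange(1.0, 1001.0).reshape(2, 500))
        s = summarize_posterior(d).loc["p"]
        assert s["ci_2.5"] == pytest.approx(25.975)
        assert s["ci_97.5"] == pytest.approx(975.025)

    def test_all_positive_draws(self):
        d = _draws_from_array(np.abs(np.random.default_rng(0).normal(size=(2, 100))) + 0.1)
        assert summarize_posterior(d).loc["p", "prob_below_zero"] == 0.0


class TestFitMcmc:
    def test_deterministic_given_seed(self):
        ds = generate_dataset(paper_preset(seed=5, n_lakes=4))
        data = LakeData.from_dataset(ds)
        cfg = MCMCConfig(n_chains=2, n_iter=400, n_burnin=200, thin=2, seed=9, n_temps=2)
        a = fit_mcmc(data, config=cfg)
        b = fit_mcmc(data, config=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        c = fit_mcmc(data, config=MCMCConfig(
            n_chains=2, n_iter=400, n_burnin=200, thin=2, seed=10, n_temps=2))
        assert not np.array_equal(a.draws, c.draws)

    def test_retained_shape_and_names(self):
        ds = generate_dataset(paper_preset(seed=5, n_lakes=4))
        data = LakeData.from_dataset(ds)
        cfg = MCMCConfig(n_chains=2, n_iter=300, n_burnin=100, thin=2, seed=1, n_temps=1)
        draws = fit_mcmc(data, config=cfg)
        assert draws.draws.shape == (2, 100, 9 + 2 * 4)
        assert draws.get("m_fish").shape == (2, 100)
        with pytest.raises(KeyError):
            draws.get("nonexistent")

    def test_marginal_matches_grid_oracle(self):
        """MCMC marginal of one free parameter against the dense-grid
        posterior (total variation on 25 cells)."""
        data, truth = make_single_lake_data()
        pri = {n: Prior("fixed", (getattr(truth, n),)) for n in HyperParams.GLOBAL_NAMES}
        pri["m_nofish"] = Prior("uniform", (0.0, 1.0))
        pri["x1[A]"] = Prior("fixed", (1.0,))
        pri["y1[A]"] = Prior("fixed", (0.5,))
        priors = PriorSpec(pri)
        grid = np.linspace(1e-4, 0.9999, 400)
        mass = grid_posterior(data, priors, "m_nofish", grid, truth)
        draws = fit_mcmc(
            data, priors,
            MCMCConfig(n_chains=3, n_iter=6000, n_burnin=2000, thin=1, seed=5),
        )
        samples = draws.flat("m_nofish")
        bins = np.linspace(0.0, 1.0, 26)
        emp, _ = np.histogram(samples, bins=bins)
        emp = emp / emp.sum()
        coarse = np.add.reduceat(mass, np.searchsorted(grid, bins[:-1]))
        coarse = coarse / coarse.sum()
        tv = 0.5 * np.abs(emp - coarse).sum()
        assert tv < 0.05

    def test_impossible_initialization_errors(self):
        data, truth = make_single_lake_data()
        pri = PriorSpec.default(data)
        pri.priors["sigma_x"] = Prior("fixed", (-1.0,))  # invalid on purpose
        with pytest.raises(RuntimeError, match="initialization"):
            fit_mcmc(data, pri, MCMCConfig(n_chains=2, n_iter=100, n_burnin=50,
                                           init_attempts=3, n_temps=1))


class TestEss:
    def test_iid_draws_ess_near_sample_size(self):
        rng = np.random.default_rng(4)
        chains = rng.normal(size=(4, 500))
        assert effective_sample_size(chains) == pytest.approx(2000, rel=0.25)
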