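"""Step-model likelihood, the collapsed Gibbs/Metropolis sampler, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from amhcut import (
    McmcConfig,
    PriorSpec,
    StepGenParams,
    StepModelParams,
    generate_step_data,
    gelman_rubin,
    log_likelihood,
    psi_optimize,
    sample_posterior,
    summarize_posterior,
)

FAST = McmcConfig(n_chains=2, n_iter=6000, n_burnin=1000, seed=0)


class TestLogLikelihood:
    def test_perfect_separation_probability_one(self, six_point_step):
        x, d = six_point_step
        params = StepModelParams(c=3.5, theta_pos=1.0, theta_neg=0.0)
        assert log_likelihood(x, d, params) == 0.0

    def test_hand_computed_two_points(self):
        params = StepModelParams(c=3.0, theta_pos=0.8, theta_neg=0.2)
        ll = log_likelihood(np.array([1.0, 5.0]), np.array([0, 1]), params)
        assert ll == pytest.approx(np.log(0.8) + np.log(0.8))

    def test_impossible_outcome_is_neg_inf(self):
        params = StepModelParams(c=3.0, theta_pos=0.0, theta_neg=0.2)
        ll = log_likelihood(np.array([1.0, 5.0]), np.array([0, 1]), params)
        assert ll == -np.inf

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.array([]), np.array([]), StepModelParams(1, 0.5, 0.5))


class TestConjugacyOracle:
    """With c fixed the sampler is pure conjugate Gibbs: marginals must
    match the closed-form Beta posteriors."""

    def test_posterior_means_match_beta(self, six_point_step):
        x, d = six_point_step
        chains = sample_posterior(
            x, d, PriorSpec.uninformative(),
            McmcConfig(n_chains=2, n_iter=12000, n_burnin=2000, seed=5),
            fixed_cutoff=4.0,
        )
        # above c=4: x in {4,5,6}, all diseased -> Beta(4,1), mean 4/5
        # below: none diseased -> Beta(1,4), mean 1/5
        assert chains.theta_pos.mean() == pytest.approx(4 / 5, abs=0.02)
        assert chains.theta_neg.mean() == pytest.approx(1 / 5, abs=0.02)

    def test_ks_distance_to_closed_form(self, six_point_step):
        x, d = six_point_step
        chains = sample_posterior(
            x, d, PriorSpec.uninformative(),
            McmcConfig(n_chains=2, n_iter=12000, n_burnin=2000, seed=5),
            fixed_cutoff=4.0,
        )
        ks_pos = stats.kstest(chains.theta_pos.ravel(), stats.beta(4, 1).cdf).statistic
        ks_neg = stats.kstest(chains.theta_neg.ravel(), stats.beta(1, 4).cdf).statistic
        assert ks_pos < 0.05 and ks_neg < 0.05


class TestPriorOnly:
    """Likelihood switched off: the sampler must reproduce each prior."""

    @pytest.mark.parametrize("kind", ["uninformative", "informative", "mixture"])
    def test_prior_means_recovered(self, kind, six_point_step):
        x, d = six_point_step
        prior = {
            "uninformative": PriorSpec.uninformative,
            "informative": PriorSpec.informative,
            "mixture": PriorSpec.mixture,
        }[kind]()
        chains = sample_posterior(x, d, prior, FAST, prior_only=True)
        if kind == "uninformative":
            assert chains.theta_pos.mean() == pytest.approx(0.5, abs=0.02)
            assert chains.c.mean() == pytest.approx(3.5, abs=0.1)  # Uniform(1,6)
        elif kind == "informative":
            assert chains.theta_pos.mean() == pytest.approx(0.95, abs=0.02)
        else:
            assert chains.theta_pos.mean() == pytest.approx(0.725, abs=0.02)


class TestParameterRecovery:
    def test_recovers_step_truth(self, step_data_2000):
        x = step_data_2000.x.to_numpy()
        d = step_data_2000.d.to_numpy()
        summ = summarize_posterior(sample_posterior(x, d, config=FAST))
        assert summ.cutoff.mean == pytest.approx(4.5, abs=0.15)
        assert summ.ppv.mean == pytest.approx(0.95, abs=0.03)
        assert summ.npv.mean == pytest.approx(0.85, abs=0.03)
        lo, hi = summ.cutoff.ci_lower, summ.cutoff.ci_upper
        assert chains_support_ok(x, lo, hi)

    def test_posterior_support_within_data_range(self, step_data_2000):
        x = step_data_2000.x.to_numpy()
        d = step_data_2000.d.to_numpy()
        chains = sample_posterior(x, d, config=FAST)
        assert chains.c.min() >= x.min() and chains.c.max() <= x.max()

    def test_informative_prior_beats_psi_at_tiny_n(self):
        # prior sharply centered at truth vs PSI on the same 10 points
        wins = 0
        prior = PriorSpec.informative(ppv=0.95, npv=0.85, cutoff=4.5, cutoff_sd=0.25)
        cfg = McmcConfig(n_chains=2, n_iter=2500, n_burnin=500)
        n_rep = 200
        for rep in range(n_rep):
            data = generate_step_data(StepGenParams(n=10, seed=50_000 + rep))
            x, d = data.x.to_numpy(), data.d.to_numpy()
            if len(np.unique(d)) < 2 or len(np.unique(x)) < 2:
                n_rep -= 1
                continue
            from dataclasses import replace
            summ = summarize_posterior(
                sample_posterior(x, d, prior, replace(cfg, seed=rep)), min_draws=1000
            )
            psi = psi_optimize(x, d)
            if abs(summ.cutoff.mean - 4.5) < abs(psi.cutoff - 4.5):
                wins += 1
        assert wins / n_rep >= 0.8


def chains_support_ok(x, lo, hi):
    return x.min() <= lo <= hi <= x.max()


class TestDiagnostics:
    def test_constant_chains_rhat_one(self):
        chains = np.full((2, 100), 3.14)
        assert gelman_rubin(chains) == 1.0

    def test_iid_chains_rhat_small(self):
        rng = np.random.default_rng(8)
        chains = rng.normal(size=(4, 2000))
        assert gelman_rubin(chains) < 1.05

    def test_disjoint_chains_rhat_large(self):
        rng = np.random.default_rng(8)
        chains = np.vstack(
            [rng.normal(0, 1, 1000), rng.normal(50, 1, 1000)]
        )
        assert gelman_rubin(chains) > 1.1

    def test_summary_orders_and_flags(self, step_data_2000):
        x = step_data_2000.x.to_numpy()
        d = step_data_2000.d.to_numpy()
        summ = summarize_posterior(sample_posterior(x, d, config=FAST))
        for s in (summ.cutoff, summ.ppv, summ.npv):
            assert s.ci_lower <= s.median <= s.ci_upper
            assert s.rhat >= 1.0 - 1e-6
        assert summ.converged

    def test_insufficient_draws_rejected(self, six_point_step):
        x, d = six_point_step
        chains = sample_posterior(
            x, d, config=McmcConfig(n_chains=2, n_iter=700, n_burnin=500, seed=1)
        )
        with pytest.raises(ValueError):
            summarize_posterior(chains)


class TestValidation:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior(np.array([1.0, 2, 3, 4]), np.zeros(4, int))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, n_burnin=100).validate()
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1).validate()
        with pytest.raises(ValueError):
            McmcConfig(proposal_sd=-1.0).validate()

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(beta_pos=(0.0, 1.0)).validate()
        with pytest.raises(ValueError):
            PriorSpec.mixture(weight=1.5)
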