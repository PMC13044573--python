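import math

import numpy as np
import pytest
from scipy import stats

from cmgipd import (
    EstimateSet,
    ModelConfig,
    SimulationSetting,
    aarbias,
    arrmse,
    arsd,
    dic,
    fit,
    generate_dataset,
    method_spec,
    psrmse,
    replicate,
    scaled_neighborhood,
)
from cmgipd.sampler import McmcSettings, PosteriorDraws

from conftest import TINY_SETTING, UNIT_MCMC


def brute_force_metrics(gamma_hat, gamma_true):
    """Loop-level recomputation of the replicate metrics."""
    R, d = gamma_hat.shape
    denom = sum(abs(g) for g in gamma_true) / d
    sq = sum(
        (gamma_hat[r, k] - gamma_true[k]) ** 2
        for r in range(R)
        for k in range(d)
    )
    rmse = math.sqrt(sq / (R * d)) / denom
    bias = (
        sum(
            abs(sum(gamma_hat[r, k] for r in range(R)) / R - gamma_true[k])
            for k in range(d)
        )
        / d
        / denom
    )
    means = [sum(gamma_hat[r, k] for r in range(R)) / R for k in range(d)]
    sd = (
        math.sqrt(
            sum(
                (gamma_hat[r, k] - means[k]) ** 2
                for r in range(R)
                for k in range(d)
            )
            / (R * d)
        )
        / denom
    )
    return rmse, bias, sd


class TestReplicateMetrics:
    @pytest.mark.parametrize(
        "gamma_hat, gamma_true, expected",
        [
            ([[3.0]], [2.0], 0.5),
            ([[2.0]], [2.0], 0.0),
            ([[1.0, 2.0], [1.0, 0.0]], [1.0, 1.0], math.sqrt(0.5)),
        ],
    )
    def test_arrmse_hand_examples(self, gamma_hat, gamma_true, expected):
        est = EstimateSet(gamma_hat=gamma_hat, gamma_true=gamma_true)
        assert arrmse(est) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "gamma_hat, gamma_true, expected",
        [
            ([[3.0]], [2.0], 0.5),
            ([[1.2], [0.8]], [1.0], 0.0),  # symmetric around truth
            ([[0.5], [1.1]], [1.0], 0.2),
        ],
    )
    def test_aarbias_hand_examples(self, gamma_hat, gamma_true, expected):
        est = EstimateSet(gamma_hat=gamma_hat, gamma_true=gamma_true)
        assert aarbias(est) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "gamma_hat, gamma_true, expected",
        [
            ([[0.7], [0.7]], [1.0], 0.0),
            ([[0.0], [2.0]], [1.0], 1.0),
        ],
    )
    def test_arsd_hand_examples(self, gamma_hat, gamma_true, expected):
        est = EstimateSet(gamma_hat=gamma_hat, gamma_true=gamma_true)
        assert arsd(est) == pytest.approx(expected)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            R = int(rng.integers(2, 7))
            d = int(rng.integers(1, 5))
            truth = rng.normal(size=d)
            truth[0] = 1.0  # keep the denominator nonzero
            hats = rng.normal(size=(R, d))
            est = EstimateSet(gamma_hat=hats, gamma_true=truth)
            rmse, bias, sd = brute_force_metrics(hats, truth)
            assert arrmse(est) == pytest.approx(rmse, rel=1e-12)
            assert aarbias(est) == pytest.approx(bias, rel=1e-12)
            assert arsd(est) == pytest.approx(sd, rel=1e-12)

    def test_per_moderator_mse_decomposition(self):
        # before the relative aggregation: MSE_k = Var_k + Bias_k^2
        rng = np.random.default_rng(9)
        hats = rng.normal(size=(30, 4))
        truth = rng.normal(size=4)
        mse = np.mean((hats - truth) ** 2, axis=0)
        var = np.var(hats, axis=0)
        bias2 = (hats.mean(axis=0) - truth) ** 2
        np.testing.assert_allclose(mse, var + bias2, rtol=1e-10)

    def test_all_zero_truth_is_undefined(self):
        est = EstimateSet(gamma_hat=[[1.0]], gamma_true=[0.0])
        with pytest.raises(ValueError, match="all-zero"):
            arrmse(est)

    def test_arsd_needs_replication(self):
        est = EstimateSet(gamma_hat=[[1.0]], gamma_true=[1.0])
        with pytest.raises(ValueError, match="2 replicates"):
            arsd(est)

    def test_moderator_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        hats = rng.normal(size=(5, 4))
        truth = np.array([1.0, 0.5, 0.0, 2.0])
        perm = np.array([2, 0, 3, 1])
        a = EstimateSet(gamma_hat=hats, gamma_true=truth)
        b = EstimateSet(gamma_hat=hats[:, perm], gamma_true=truth[perm])
        for m in (arrmse, aarbias, arsd):
            assert m(a) == pytest.approx(m(b), rel=1e-12)


class TestPSRMSE:
    def _est(self, **kw):
        defaults = dict(
            gamma_hat=np.zeros((1, 0)),
            gamma_true=np.zeros(0),
            alpha_hat=[1.0],
            alpha_true=3.0,
            Xem=np.zeros((4, 0)),
            t=np.array([1.0, 1.0, 0.0, 0.0]),
        )
        defaults.update(kw)
        return EstimateSet(**defaults)

    def test_hand_norm_no_moderators(self):
        # error vector (2,2,0,0): ||.|| / N = 2*sqrt(2)/4
        est = self._est()
        assert psrmse(est) == pytest.approx(2 * math.sqrt(2) / 4)

    def test_perfect_estimates_give_zero(self):
        rng = np.random.default_rng(2)
        Xem = rng.normal(size=(6, 2))
        est = EstimateSet(
            gamma_hat=[[1.0, -1.0]],
            gamma_true=[1.0, -1.0],
            alpha_hat=[3.0],
            alpha_true=3.0,
            Xem=Xem,
            t=np.repeat([1.0, 0.0], 3),
        )
        assert psrmse(est) == 0.0
        assert psrmse(est, include_em_only=True) == 0.0

    def test_em_only_bounded_when_alpha_exact(self):
        rng = np.random.default_rng(4)
        Xem = rng.normal(size=(10, 2))
        est = EstimateSet(
            gamma_hat=[[0.2, 0.1]],
            gamma_true=[1.0, -1.0],
            alpha_hat=[3.0],
            alpha_true=3.0,
            Xem=Xem,
            t=np.repeat([1.0, 0.0], 5),
        )
        assert psrmse(est, include_em_only=True) <= psrmse(est) + 1e-12

    def test_participant_reordering_invariance(self):
        rng = np.random.default_rng(5)
        Xem = rng.normal(size=(8, 2))
        t = np.repeat([1.0, 0.0], 4)
        perm = rng.permutation(8)
        a = EstimateSet(
            gamma_hat=[[0.5, 0.5]], gamma_true=[1.0, 0.0],
            alpha_hat=[2.0], alpha_true=3.0, Xem=Xem, t=t,
        )
        b = EstimateSet(
            gamma_hat=[[0.5, 0.5]], gamma_true=[1.0, 0.0],
            alpha_hat=[2.0], alpha_true=3.0, Xem=Xem[perm], t=t[perm],
        )
        assert psrmse(a) == pytest.approx(psrmse(b), rel=1e-12)


class TestScaledNeighborhood:
    def test_standard_normal_not_important(self):
        rng = np.random.default_rng(0)
        p, flag = scaled_neighborhood(rng.normal(size=200_000))
        assert p == pytest.approx(2 * stats.norm.cdf(1) - 1, abs=0.01)
        assert not flag

    def test_far_from_null_important(self):
        rng = np.random.default_rng(1)
        p, flag = scaled_neighborhood(rng.normal(10.0, 1.0, size=50_000))
        assert p < 0.001 and flag

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 1.0, size=10_000)
        assert scaled_neighborhood(x)[0] == scaled_neighborhood(-x)[0]

    def test_all_zero_draws(self):
        assert scaled_neighborhood(np.zeros(10)) == (1.0, False)

    def test_degenerate_nonzero_draws_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            scaled_neighborhood(np.full(10, 3.0))


class TestDIC:
    def _fit(self, data, config, method="Flat", seed=0, mcmc=None):
        return fit(
            data, config, method_spec(method), mcmc or UNIT_MCMC, seed=seed
        )

    def test_degenerate_posterior_has_zero_pd(self):
        # all draws identical -> pD = 0 and DIC equals the plug-in deviance
        data, _ = generate_dataset(TINY_SETTING, seed=0)
        config = ModelConfig(
            include_main_random_effects=False,
            include_moderation_random_effects=False,
        )
        params = {
            "mu": np.full((2, 5), 1.0),
            "alpha": np.full((2, 5), 2.0),
            "beta": np.full((2, 5, 2), 0.5),
            "gamma": np.full((2, 5, 2), 0.1),
            "sigma2": np.full((2, 5, 3), 2.0),
        }
        draws = PosteriorDraws(
            params=params,
            settings=McmcSettings(n_chains=2, n_iter=10, burn_in=0, thin=2),
            seed=0,
            spec_name="Flat",
        )
        val = dic(draws, data, config)
        # recompute the plug-in deviance independently
        from cmgipd.data_model import build_design

        des = build_design(data, config)
        theta = np.concatenate([[1.0, 2.0], [0.5, 0.5], [0.1, 0.1]])
        mean = des.W @ theta
        s2 = 2.0
        dev = float(
            np.sum(np.log(2 * np.pi * s2) + (data.y - mean) ** 2 / s2)
        )
        assert val == pytest.approx(dev, rel=1e-10)

    def test_prefers_model_without_absent_random_effects(self):
        # truth has no between-trial moderation variability; DIC should
        # usually prefer dropping u_i
        wins = 0
        for r, (data, _) in enumerate(replicate(TINY_SETTING, 5, base_seed=21)):
            with_re = self._fit(
                data, ModelConfig(), seed=100 + r
            )
            without_re = self._fit(
                data,
                ModelConfig(include_moderation_random_effects=False),
                seed=200 + r,
            )
            d_with = dic(with_re, data, ModelConfig())
            d_without = dic(
                without_re,
                data,
                ModelConfig(include_moderation_random_effects=False),
            )
            wins += d_without < d_with
        assert wins >= 3

    def test_pure_noise_moderator_increases_dic_on_average(self):
        # covariates 0 and 1 moderate; covariate 2 has a zero true gamma
        setting = SimulationSetting(
            variability="none",
            sparsity="high",
            correlation="none",
            strength="strong",
            I=3,
            n_range=(40, 50),
            p=3,
            beta=(1.0, -0.5, 0.8),
            sigma=(2.0, 2.0, 2.0),
            tau_mu=1.0,
            tau_alpha=1.0,
        )
        diffs = []
        for r, (data, _) in enumerate(replicate(setting, 20, base_seed=33)):
            small = ModelConfig(
                moderator_indices=(0, 1),
                include_moderation_random_effects=False,
            )
            big = ModelConfig(
                moderator_indices=(0, 1, 2),
                include_moderation_random_effects=False,
            )
            d_small = dic(self._fit(data, small, seed=300 + r), data, small)
            d_big = dic(self._fit(data, big, seed=300 + r), data, big)
            diffs.append(d_big - d_small)
        assert np.mean(diffs) > 0
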