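"""Power model, quasi-Bernoulli likelihood, and posterior quadrature."""

import math

import numpy as np
import pytest

from quasicrm import (
    ETScale,
    SkeletonModel,
    TrialData,
    integrate_posterior,
    model_prob,
    quasi_log_likelihood,
    saturated_qmle,
)
from oracles import grid_posterior, log_quasi_likelihood_grid, random_small_dataset

SKEL = (0.11, 0.25, 0.40, 0.55, 0.70, 0.85)
THETA = 0.47 / 1.5


class TestPowerModel:
    @pytest.mark.parametrize("p, alpha, expected", [
        (0.25, 0.0, 0.25),
        (0.25, math.log(2.0), 0.0625),
    ])
    def test_values(self, p, alpha, expected):
        assert model_prob(p, alpha) == pytest.approx(expected, rel=1e-12)

    def test_monotone_limits(self):
        assert model_prob(0.5, -30.0) == pytest.approx(1.0, abs=1e-9)
        assert model_prob(0.5, 6.0) == pytest.approx(0.0, abs=1e-9)
        # strictly increasing in the skeleton value at fixed alpha
        vals = [model_prob(p, 0.7) for p in (0.1, 0.3, 0.5, 0.9)]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_boundary_skeleton(self):
        for p in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                model_prob(p, 0.0)


class TestQuasiLogLikelihood:
    def test_binary_record(self):
        data = TrialData.from_scores([2], [1.0], n_doses=3)
        ll = quasi_log_likelihood(data, (0.1, 0.5, 0.9))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_fractional_record(self):
        """A grade-2 event (score 0.5/1.5) contributes pi^(1/3) (1-pi)^(2/3)."""
        data = TrialData.from_scores([1], [1 / 3], n_doses=1)
        ll = quasi_log_likelihood(data, (0.2,))
        assert ll == pytest.approx((1 / 3) * math.log(0.2) + (2 / 3) * math.log(0.8),
                                   abs=1e-12)

    def test_empty_data_is_zero(self):
        assert quasi_log_likelihood(TrialData(4), (0.1, 0.2, 0.3, 0.4)) == 0.0

    def test_matches_binomial_when_binary(self, rng):
        n_j, Y_j, doses, y = random_small_dataset(rng, scores=(0.0, 1.0))
        data = TrialData.from_scores(doses, y, n_doses=6)
        pi = np.linspace(0.1, 0.8, 6)
        expected = float(np.sum(Y_j * np.log(pi) + (n_j - Y_j) * np.log1p(-pi)))
        assert quasi_log_likelihood(data, pi) == pytest.approx(expected, rel=1e-12)


class TestSaturatedQmle:
    def test_observed_mean_and_undefined_marker(self):
        data = TrialData.from_scores([3, 3, 3], [0.0, 1 / 3, 2 / 3], n_doses=4)
        out = saturated_qmle(data)
        assert out[2] == pytest.approx(1 / 3)
        assert np.isnan(out[[0, 1, 3]]).all()

    def test_dominates_power_model_fits(self, rng):
        """The per-dose score mean attains a quasi-log-likelihood at least as
        large as any power-model fit (grid search over alpha)."""
        for _ in range(25):
            n_j, Y_j, doses, y = random_small_dataset(rng)
            if not len(doses):
                continue
            data = TrialData.from_scores(doses, y, n_doses=6)
            sat = saturated_qmle(data)
            sat_ll = quasi_log_likelihood(data, np.clip(np.nan_to_num(sat, nan=0.5),
                                                        1e-12, 1 - 1e-12))
            grid_ll = log_quasi_likelihood_grid(
                np.linspace(-6, 6, 1001), SKEL, n_j, Y_j)
            assert sat_ll >= grid_ll.max() - 1e-9


class TestIntegratePosterior:
    def test_empty_data_gives_prior(self):
        model = SkeletonModel(SKEL)
        post = integrate_posterior(model, TrialData(6), target_norm=THETA)
        assert post.marginal_lik == pytest.approx(1.0, abs=1e-12)
        _, prior_mean, prior_over = grid_posterior(SKEL, np.zeros(6), np.zeros(6),
                                                   target_norm=THETA)
        assert np.asarray(post.post_probs) == pytest.approx(prior_mean, rel=1e-8)
        assert post.prob_overdose_d1 == pytest.approx(prior_over, rel=1e-6)

    def test_posterior_curve_strictly_increasing(self, rng):
        model = SkeletonModel(SKEL)
        for _ in range(10):
            _, _, doses, y = random_small_dataset(rng)
            data = TrialData.from_scores(doses, y, n_doses=6)
            post = integrate_posterior(model, data)
            assert np.all(np.diff(post.post_probs) > 0)

    def test_toxic_record_raises_curve(self):
        model = SkeletonModel(SKEL)
        base = integrate_posterior(model, TrialData(6)).post_probs
        bumped = integrate_posterior(
            model, TrialData.from_scores([1], [1.0], n_doses=6)).post_probs
        assert np.all(np.asarray(bumped) > np.asarray(base))

    def test_adding_records_moves_curve_monotonically(self, rng):
        """Appending a fully toxic record never lowers any dose's estimate;
        appending a clean record never raises one."""
        model = SkeletonModel(SKEL)
        for _ in range(10):
            _, _, doses, y = random_small_dataset(rng, max_n=10)
            data = TrialData.from_scores(doses, y, n_doses=6)
            base = np.asarray(integrate_posterior(model, data).post_probs)
            dose = int(rng.integers(1, 7))
            up = TrialData.from_scores(list(doses) + [dose], list(y) + [1.0], 6)
            down = TrialData.from_scores(list(doses) + [dose], list(y) + [0.0], 6)
            assert np.all(np.asarray(integrate_posterior(model, up).post_probs)
                          >= base - 1e-12)
            assert np.all(np.asarray(integrate_posterior(model, down).post_probs)
                          <= base + 1e-12)

    def test_binary_weights_reproduce_dlt_crm(self):
        """Dichotomising grades via weights (0, 0, s_max, s_max) must equal the
        engine run on the corresponding binary DLT indicators."""
        dlt_scale = ETScale((0.0, 0.0, 1.5, 1.5), 1.5)
        records = [(1, 0), (2, 1), (3, 2), (3, 3), (4, 1), (4, 2)]
        graded = TrialData(6, dlt_scale)
        for d, g in records:
            graded.add(d, g)
        binary = TrialData.from_scores([d for d, _ in records],
                                       [1.0 if g >= 2 else 0.0 for _, g in records], 6)
        model = SkeletonModel(SKEL)
        a = integrate_posterior(model, graded, target_norm=THETA)
        b = integrate_posterior(model, binary, target_norm=THETA)
        assert a.log_marginal == pytest.approx(b.log_marginal, abs=1e-14)
        assert a.post_probs == pytest.approx(b.post_probs, abs=1e-14)

    def test_mismatched_dose_count_rejected(self):
        with pytest.raises(ValueError):
            integrate_posterior(SkeletonModel((0.2, 0.4)), TrialData(3))


class TestDataContainer:
    def test_sufficient_statistics(self, small_data):
        assert small_data.n == 8
        assert small_data.counts().sum() == 8
        assert np.all(small_data.score_sums() <= small_data.counts())
        frame = small_data.to_frame()
        assert list(frame.columns) == ["patient", "dose", "grade", "et_score", "y"]
        assert frame["y"].between(0, 1).all()

    def test_rejects_bad_records(self):
        data = TrialData(3)
        with pytest.raises(ValueError):
            data.add(4, 0)
        with pytest.raises(ValueError):
            data.add(1, 9)
        with pytest.raises(ValueError):
            data.add_score(1, 1.2)
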