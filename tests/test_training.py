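"""Penalties, penalized fitting, and cross-validated strength selection."""

import numpy as np
import pytest

from mhnet import (
    Dataset,
    MutualHazardNetwork,
    PenaltySpec,
    ValidationError,
    cross_validate,
    fit,
    log_likelihood,
    marginal_distribution_full,
    penalty_value_and_gradient,
    sample_dataset,
)

from conftest import make_catalog, random_model


class TestPenaltyValues:
    @pytest.mark.parametrize("kind", ["l1", "l2", "symmetric"])
    def test_zero_theta_zero_value(self, kind):
        m = MutualHazardNetwork.zeros(make_catalog(3))
        value, grad = penalty_value_and_gradient(m, PenaltySpec(kind, 1.0))
        assert value == pytest.approx(0.0, abs=1e-8)
        assert grad.shape == m.log_theta.shape

    def test_l2_squares_off_diagonal(self):
        m = MutualHazardNetwork.zeros(make_catalog(2))
        m.log_theta[0, 1] = 2.0
        value, _ = penalty_value_and_gradient(m, PenaltySpec("l2", 1.0))
        assert value == pytest.approx(4.0)

    def test_diagonal_never_penalized(self):
        m = MutualHazardNetwork.zeros(make_catalog(3))
        np.fill_diagonal(m.log_theta[:3], 7.0)
        for kind in ("l1", "l2", "symmetric"):
            value, grad = penalty_value_and_gradient(m, PenaltySpec(kind, 1.0))
            assert value == pytest.approx(0.0, abs=1e-8)
            assert np.all(grad[np.arange(3), np.arange(3)] == 0.0)

    def test_symmetric_pair_group_norm(self):
        m = MutualHazardNetwork.zeros(make_catalog(2))
        m.log_theta[0, 1], m.log_theta[1, 0] = 3.0, 4.0
        value, _ = penalty_value_and_gradient(
            m, PenaltySpec("symmetric", 1.0, smoothing=1e-10)
        )
        assert value == pytest.approx(5.0)

    def test_observation_row_switch(self):
        m = MutualHazardNetwork.zeros(make_catalog(2))
        m.log_theta[2, 0] = 3.0
        on, _ = penalty_value_and_gradient(m, PenaltySpec("l1", 1.0))
        off, _ = penalty_value_and_gradient(
            m, PenaltySpec("l1", 1.0, penalize_observation=False)
        )
        assert on == pytest.approx(3.0, rel=1e-4)
        assert off == pytest.approx(0.0, abs=1e-8)

    def test_custom_hook_and_shape_check(self):
        m = MutualHazardNetwork.zeros(make_catalog(2))

        def hook(th):
            return float(th.sum()), np.ones_like(th)

        value, grad = penalty_value_and_gradient(
            m, PenaltySpec("custom", 1.0, custom_hook=hook)
        )
        assert value == 0.0 and grad.shape == m.log_theta.shape

        def bad_hook(th):
            return 0.0, np.ones((2, 2))

        with pytest.raises(ValidationError):
            penalty_value_and_gradient(m, PenaltySpec("custom", 1.0, custom_hook=bad_hook))

    @pytest.mark.parametrize("kind", ["l1", "l2", "symmetric"])
    def test_gradient_matches_finite_differences(self, kind):
        m = random_model(4, seed=3, scale=1.2)
        spec = PenaltySpec(kind, 1.0)
        _, G = penalty_value_and_gradient(m, spec)
        step = 1e-6
        for idx in [(0, 1), (1, 0), (2, 3), (4, 2), (3, 3)]:
            tp = m.log_theta.copy()
            tp[idx] += step
            tm = m.log_theta.copy()
            tm[idx] -= step
            fd = (
                penalty_value_and_gradient(MutualHazardNetwork(tp, m.catalog), spec)[0]
                - penalty_value_and_gradient(MutualHazardNetwork(tm, m.catalog), spec)[0]
            ) / (2 * step)
            assert G[idx] == pytest.approx(fd, rel=1e-6, abs=1e-8)


@pytest.fixture(scope="module")
def small_cohort():
    """600 samples from a seeded 3-event model with one strong interaction."""
    cat = make_catalog(3)
    th = np.zeros((4, 3))
    np.fill_diagonal(th[:3], -0.5)
    th[1, 0] = 1.2
    th[3, 2] = 0.8
    truth = MutualHazardNetwork(th, cat)
    return truth, sample_dataset(truth, 600, seed=21)


class TestFit:
    def test_objective_trace_non_decreasing(self, small_cohort):
        _, data = small_cohort
        res = fit(data, PenaltySpec("l1", 0.01))
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) >= -1e-10)
        assert trace[-1] >= trace[0]

    def test_recovers_generative_distribution(self, small_cohort):
        truth, data = small_cohort
        res = fit(data, PenaltySpec("l1", 0.005))
        tv = 0.5 * np.abs(
            marginal_distribution_full(truth) - marginal_distribution_full(res.model)
        ).sum()
        assert tv < 0.06  # 600 samples: sampling noise dominates

    def test_row_order_invariance(self, small_cohort):
        _, data = small_cohort
        shuffled = data.subset(np.random.default_rng(5).permutation(len(data)))
        r1 = fit(data, PenaltySpec("l2", 0.01))
        r2 = fit(shuffled, PenaltySpec("l2", 0.01))
        assert np.array_equal(r1.model.log_theta, r2.model.log_theta)

    def test_large_strength_shrinks_all_penalized_entries(self, small_cohort):
        _, data = small_cohort
        res = fit(data, PenaltySpec("l1", 10.0))
        th = res.model.log_theta
        off = th.copy()
        off[np.arange(3), np.arange(3)] = 0.0
        assert np.abs(off).max() < 1e-2

    def test_classic_equals_frozen_observation_fit(self, small_cohort):
        _, data = small_cohort
        spec = PenaltySpec("l1", 0.01)
        classic = fit(data, spec, kind="classic")
        frozen = fit(data, spec, kind="observation_aware", freeze_observation=True)
        assert np.all(classic.model.log_theta[3] == 0.0)
        assert abs(
            log_likelihood(classic.model, data) - log_likelihood(frozen.model, data)
        ) <= 1e-10

    def test_empty_dataset_rejected(self, cat3):
        with pytest.raises(ValidationError):
            fit(Dataset(np.zeros((0, 3), dtype=int), cat3))


class TestCrossValidate:
    def test_deterministic_given_seed(self, small_cohort):
        _, data = small_cohort
        sub = data.subset(np.arange(120))
        grid = [1e-3, 1e-1]
        r1 = cross_validate(sub, grid, folds=3, seed=9, max_iter=100)
        r2 = cross_validate(sub, grid, folds=3, seed=9, max_iter=100)
        assert np.array_equal(r1.fold_scores, r2.fold_scores)
        assert r1.selected_strength == r2.selected_strength
        assert np.array_equal(
            r1.final_fit.model.log_theta, r2.final_fit.model.log_theta
        )

    def test_tie_breaks_to_smaller_strength(self, cat3):
        # all-healthy cohort: the likelihood depends only on the unpenalized
        # diagonals, so every strength yields a bit-identical fit and an
        # exactly tied held-out score; the tie rule must pick the smallest
        g = np.zeros((40, 3), dtype=int)
        data = Dataset(g, cat3)
        res = cross_validate(data, [5.0, 10.0], folds=4, seed=2, max_iter=200)
        assert res.fold_scores[0] == pytest.approx(res.fold_scores[1], abs=0)
        assert res.selected_strength == 5.0

    def test_penalized_beats_unpenalized_on_sparse_truth(self):
        cat = make_catalog(4)
        th = np.zeros((5, 4))
        np.fill_diagonal(th[:4], -0.3)
        th[2, 0] = 1.0
        truth = MutualHazardNetwork(th, cat)
        data = sample_dataset(truth, 150, seed=33)  # small N: overfitting bites
        res = cross_validate(data, [1e-3, 3e-2, 0.3], folds=3, seed=4, max_iter=200)
        unpen = res.fold_scores[0].mean() if res.grid[0] == 1e-3 else None
        assert res.mean_scores.max() >= unpen - 1e-12

    def test_rejects_bad_folds(self, cat3):
        data = Dataset(np.zeros((6, 3), dtype=int), cat3)
        with pytest.raises(ValidationError):
            cross_validate(data, [0.1], folds=1)
        with pytest.raises(ValidationError):
            cross_validate(data, [], folds=2)
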