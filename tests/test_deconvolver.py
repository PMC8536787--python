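"""Coarse NNLS, platform correction, loss/gradient, and the full solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbdeconv import (
    CompoundSampleSet,
    DegenerateInputError,
    ValidationError,
    coarse_estimate,
    compute_correction_factors,
    deconvolute,
    loss_and_gradient,
    solve_proportions,
)
from tests.conftest import make_panel


def grid_search_simplex_2(y, mu, step=0.001):
    """Exhaustive 2-simplex oracle for the coarse direction (proportional fit)."""
    best, arg = np.inf, None
    for t in np.arange(0.0, 1.0 + step / 2, step):
        tau = np.array([t, 1.0 - t])
        pred = mu @ tau
        scale = (pred @ y) / (pred @ pred) if pred @ pred > 0 else 0.0
        sse = np.sum((y - scale * pred) ** 2)
        if sse < best:
            best, arg = sse, tau
    return arg


class TestCoarseEstimate:
    def test_exact_column_gives_one_hot(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(1, 10, size=(30, 4))
        panel = make_panel(mu)
        tau = coarse_estimate(mu[:, 2].copy(), panel)
        np.testing.assert_allclose(tau, np.eye(4)[2], atol=1e-8)

    def test_orthogonal_design_matches_simplex_grid_oracle(self):
        panel = make_panel(np.array([[1.0, 0.0], [0.0, 1.0]]))
        y = np.array([3.0, 7.0])
        tau = coarse_estimate(y, panel)
        np.testing.assert_allclose(tau, [0.3, 0.7], atol=1e-9)
        oracle = grid_search_simplex_2(y, panel.mu)
        np.testing.assert_allclose(tau, oracle, atol=1e-3)

    def test_zero_input_is_degenerate(self):
        panel = make_panel(np.ones((5, 2)))
        with pytest.raises(DegenerateInputError):
            coarse_estimate(np.zeros(5), panel)


class TestCorrectionFactors:
    def test_fixed_points_and_hand_value(self):
        panel = make_panel(np.array([[10.0], [10.0], [10.0]]))
        tau = np.array([1.0])
        r, valid = compute_correction_factors(np.array([10.0, 0.0, 30.0]), panel, tau)
        assert valid.all()
        np.testing.assert_allclose(r, [1.0, 0.0, 2.0])  # log2(ratio + 1)

    def test_zero_predicted_mean_is_masked(self):
        panel = make_panel(np.array([[10.0], [0.0]]))
        r, valid = compute_correction_factors(np.array([10.0, 5.0]), panel, np.array([1.0]))
        assert valid.tolist() == [True, False]

    def test_off_simplex_tau_rejected(self):
        panel = make_panel(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            compute_correction_factors(np.ones(2), panel, np.array([0.9, 0.9]))


class TestLossAndGradient:
    def test_hand_arithmetic(self):
        y = np.array([4.0, 6.0])
        mu = np.array([[2.0], [3.0]])
        one = np.ones(2)
        loss, grad = loss_and_gradient(np.array([1.0]), y, mu, one, one, 0.0)
        assert loss == pytest.approx(13.0)
        assert grad[0] == pytest.approx(-26.0)

    def test_beta_zero_plugin(self):
        rng = np.random.default_rng(1)
        I, K = 8, 3
        y = rng.uniform(0, 5, I)
        mu = rng.uniform(0, 5, (I, K))
        w = rng.uniform(0.1, 1, I)
        r = rng.uniform(0.1, 2, I)
        loss, grad = loss_and_gradient(np.zeros(K), y, mu, w, r, 3.7)
        assert loss == pytest.approx(float(w @ y**2))
        np.testing.assert_allclose(grad, -2 * mu.T @ (r * w * y))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            loss_and_gradient(np.ones(2), np.ones(3), np.ones((3, 3)), np.ones(3), np.ones(3), 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_gradient_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        I, K = int(rng.integers(3, 20)), int(rng.integers(1, 6))
        y = rng.uniform(0, 10, I)
        mu = rng.uniform(0, 5, (I, K))
        w = rng.uniform(0.05, 2, I)
        r = rng.uniform(0.1, 3, I)
        lam = float(rng.uniform(0, 5))
        beta = rng.uniform(0, 3, K)
        _, grad = loss_and_gradient(beta, y, mu, w, r, lam)
        h = 1e-5
        for k in range(K):
            e = np.zeros(K)
            e[k] = h
            lp, _ = loss_and_gradient(beta + e, y, mu, w, r, lam)
            lm, _ = loss_and_gradient(beta - e, y, mu, w, r, lam)
            fd = (lp - lm) / (2 * h)
            assert abs(grad[k] - fd) <= 1e-5 * max(1.0, abs(fd))


class TestSolveProportions:
    def test_single_type_panel_returns_certainty(self):
        panel = make_panel(np.array([[2.0], [5.0], [1.0]]))
        res = solve_proportions(np.array([4.0, 10.0, 2.0]), panel)
        np.testing.assert_allclose(res.theta[0], [1.0])

    def test_noiseless_mixture_recovered_against_wls_oracle(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(0.5, 10, (40, 2))
        beta_star = np.array([2.0, 8.0])
        y = mu @ beta_star
        panel = make_panel(mu)
        res = solve_proportions(y, panel, lam=0.0, correction="none")
        np.testing.assert_allclose(res.theta[0], [0.2, 0.8], atol=1e-3)
        # closed-form least squares on the two-column design
        beta_ls = np.linalg.lstsq(mu, y, rcond=None)[0]
        np.testing.assert_allclose(res.beta_raw[0], beta_ls, rtol=1e-4)

    def test_matches_nnls_then_normalize_with_unit_weights(self):
        """With unit weights, r = 1 and lambda = 0 the solver reduces to
        plain NNLS followed by simplex normalization."""
        from scipy.optimize import nnls

        rng = np.random.default_rng(4)
        for _ in range(20):
            I, K = int(rng.integers(5, 50)), int(rng.integers(2, 6))
            mu = rng.uniform(0, 5, (I, K))
            y = rng.uniform(0, 20, I)
            if not y.any():
                continue
            panel = make_panel(mu)
            res = solve_proportions(y, panel, lam=0.0, correction="none")
            coef, _ = nnls(mu, y)
            if coef.sum() == 0:
                continue
            np.testing.assert_allclose(res.theta[0], coef / coef.sum(), atol=1e-6)

    def test_scale_equivariance_without_regularization(self):
        rng = np.random.default_rng(5)
        mu = rng.uniform(0, 5, (30, 3))
        y = mu @ np.array([1.0, 2.0, 3.0]) + rng.uniform(0, 1, 30)
        panel = make_panel(mu)
        a = solve_proportions(y, panel, lam=0.0, correction="none")
        b = solve_proportions(123.4 * y, panel, lam=0.0, correction="none")
        np.testing.assert_allclose(a.theta[0], b.theta[0], atol=1e-6)

    def test_regularization_pulls_toward_uniform_on_fixed_instance(self):
        rng = np.random.default_rng(6)
        mu = rng.uniform(0.5, 5, (40, 4))
        y = mu @ np.array([5.0, 1.0, 0.5, 0.1])
        panel = make_panel(mu)
        dist = []
        for lam in [0.0, 1e1, 1e3, 1e5, 1e7]:
            res = solve_proportions(y, panel, lam=lam, correction="none")
            dist.append(np.max(np.abs(res.theta[0] - 0.25)))
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(dist, dist[1:]))


class TestDeconvolute:
    def _samples(self, panel, Y, groups=None):
        return CompoundSampleSet(
            counts=Y,
            gene_ids=list(panel.selected_genes),
            sample_ids=[f"s{j}" for j in range(Y.shape[1])],
            replicate_groups=groups,
        )

    def test_identical_samples_identical_rows(self, small_panel):
        rng = np.random.default_rng(7)
        y = small_panel.mu @ rng.dirichlet(np.ones(small_panel.n_types)) * 50
        res = deconvolute(self._samples(small_panel, np.column_stack([y, y])), small_panel)
        np.testing.assert_array_equal(res.theta[0], res.theta[1])

    def test_sample_order_independence(self, small_panel):
        rng = np.random.default_rng(8)
        Y = np.column_stack(
            [small_panel.mu @ rng.dirichlet(np.ones(small_panel.n_types)) * 30 for _ in range(3)]
        )
        a = deconvolute(self._samples(small_panel, Y), small_panel)
        b = deconvolute(self._samples(small_panel, Y[:, ::-1].copy()), small_panel)
        np.testing.assert_allclose(a.theta, b.theta[::-1], atol=1e-10)

    def test_simplex_closure(self, small_panel):
        rng = np.random.default_rng(9)
        Y = rng.uniform(0, 30, size=(small_panel.n_genes, 4))
        res = deconvolute(self._samples(small_panel, Y), small_panel)
        assert np.all(res.theta >= 0)
        np.testing.assert_allclose(res.theta.sum(axis=1), 1.0, atol=1e-9)
        # theta recomputable from beta_raw
        sums = res.beta_raw.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(res.theta, res.beta_raw / sums, atol=1e-12)

    def test_replicate_group_shares_correction(self, small_panel):
        rng = np.random.default_rng(10)
        y = small_panel.mu @ rng.dirichlet(np.ones(small_panel.n_types)) * 40
        Y = np.column_stack([y * 1.1, y * 0.9])
        groups = {"s0": "grp", "s1": "grp"}
        res = deconvolute(self._samples(small_panel, Y, groups), small_panel)
        assert set(res.correction_factors) == {"grp"}

    def test_insufficient_gene_overlap_is_an_error(self, small_panel):
        Y = np.ones((small_panel.n_genes, 1))
        s = CompoundSampleSet(
            counts=Y,
            gene_ids=[f"other{i}" for i in range(small_panel.n_genes)],
            sample_ids=["s0"],
        )
        with pytest.raises(ValidationError, match="50%"):
            deconvolute(s, small_panel)
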