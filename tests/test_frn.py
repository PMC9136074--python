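"""The reconstruction head: closed-form ridge solution against independent
least-squares oracles, the dual algebraic forms, and the classification
contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frn3d.autograd import Tensor
from frn3d.backbone import FeatureMap
from frn3d.frn import (
    FRNHead,
    ReconHeadParams,
    SupportPool,
    class_probabilities,
    classify,
    effective_lambda,
    effective_rho,
    pool_support,
    reconstruct,
    ridge_weights,
)


def stacked_lstsq_oracle(q, s, lam):
    """Row-wise regularized least squares via the augmented system
    (S^T; sqrt(lam) I) w = (q; 0) — independent of the production path."""
    kr = s.shape[0]
    a = np.vstack([s.T, np.sqrt(lam) * np.eye(kr)])
    b = np.vstack([q.T, np.zeros((kr, q.shape[0]))])
    return np.linalg.lstsq(a, b, rcond=None)[0].T


def make_params(lam=None, rho=1.0, gamma=1.0, k=1, r=1, d=1):
    """Head params whose effective lambda equals ``lam`` for given k, r, d."""
    alpha = 0.0 if lam is None else float(np.log(lam * d / (k * r)))
    return ReconHeadParams(alpha=alpha, beta=float(np.log(rho)), gamma=gamma)


class TestPoolSupport:
    def test_single_map_passthrough(self, rng):
        m = FeatureMap(rng.normal(size=(8, 3)), (2, 2, 2))
        pool = pool_support([m], class_id=1)
        np.testing.assert_array_equal(pool.matrix, m.values)
        assert (pool.k, pool.r, pool.class_id) == (1, 8, 1)

    def test_rows_concatenated_in_input_order(self, rng):
        m1 = FeatureMap(rng.normal(size=(2, 3)), (1, 1, 2))
        m2 = FeatureMap(rng.normal(size=(2, 3)), (1, 1, 2))
        pool = pool_support([m1, m2], class_id=0)
        assert pool.matrix.shape == (4, 3)
        np.testing.assert_array_equal(pool.matrix[:2], m1.values)
        np.testing.assert_array_equal(pool.matrix[2:], m2.values)

    def test_empty_and_mismatched_rejected(self, rng):
        with pytest.raises(ValueError):
            pool_support([], class_id=0)
        m1 = FeatureMap(rng.normal(size=(2, 3)), (1, 1, 2))
        m2 = FeatureMap(rng.normal(size=(2, 4)), (1, 1, 2))
        with pytest.raises(ValueError):
            pool_support([m1, m2], class_id=0)


class TestRidgeWeights:
    def test_scalar_closed_form(self):
        # qs/(s^2 + lam) = 2*1/(1+1) = 1
        np.testing.assert_allclose(ridge_weights([[2.0]], [[1.0]], 1.0), [[1.0]])

    def test_identity_support_vanishing_penalty(self):
        w = ridge_weights(np.eye(2), np.eye(2), 1e-8)
        np.testing.assert_allclose(w, np.eye(2), atol=1e-6)

    def test_matches_stacked_oracle(self, rng):
        q = rng.normal(size=(3, 2))
        s = rng.normal(size=(4, 2))
        w = ridge_weights(q, s, 0.5)
        np.testing.assert_allclose(w, stacked_lstsq_oracle(q, s, 0.5), atol=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        r=st.integers(1, 5), d=st.integers(1, 5), kr=st.integers(1, 8),
        lam=st.floats(1e-3, 1e3), seed=st.integers(0, 2**16),
    )
    def test_oracle_equivalence_property(self, r, d, kr, lam, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(size=(r, d))
        s = rng.normal(size=(kr, d))
        np.testing.assert_allclose(ridge_weights(q, s, lam),
                                   stacked_lstsq_oracle(q, s, lam), atol=1e-8)

    def test_invalid_inputs_rejected(self, rng):
        q, s = rng.normal(size=(2, 2)), rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            ridge_weights(q, s, 0.0)
        with pytest.raises(ValueError):
            ridge_weights(q * np.nan, s, 1.0)


class TestEffectiveParams:
    def test_alpha_zero_gives_kr_over_d(self):
        assert effective_lambda(ReconHeadParams(), k=1, r=8, d=2) == 4.0

    def test_beta_zero_gives_unit_rho(self):
        assert effective_rho(ReconHeadParams()) == 1.0

    def test_log_two_alpha(self):
        lam = effective_lambda(ReconHeadParams(alpha=np.log(2.0)), k=2, r=4, d=8)
        np.testing.assert_allclose(lam, 2.0)


class TestReconstruct:
    def test_scalar_worked_example(self):
        """k=r=d=1, alpha=beta=0: lambda=1, reconstruction 1/(1+1)=0.5,
        distance (1-0.5)^2 = 0.25."""
        pool = SupportPool(np.array([[1.0]]), class_id=0, k=1, r=1)
        res = reconstruct(np.array([[1.0]]), pool, ReconHeadParams())
        np.testing.assert_allclose(res.reconstruction, [[0.5]])
        np.testing.assert_allclose(res.distance, 0.25)

    def test_span_membership_distance_vanishes(self, rng):
        s = rng.normal(size=(4, 3))
        pool = SupportPool(s, class_id=0, k=1, r=4)
        q = s[1:2].copy()
        res = reconstruct(q, pool, make_params(lam=1e-10, k=1, r=4, d=3))
        assert res.distance < 1e-8

    @pytest.mark.parametrize("kr,d", [(3, 6), (6, 6), (12, 4)])
    def test_dual_forms_agree(self, kr, d, rng):
        """kr x kr and d x d solve forms are algebraically identical."""
        q = rng.normal(size=(8, d))
        s = rng.normal(size=(kr, d))
        lam, rho = 0.7, 1.3
        primal = rho * q @ s.T @ np.linalg.solve(s @ s.T + lam * np.eye(kr), s)
        dual = rho * q @ np.linalg.solve(s.T @ s + lam * np.eye(d), s.T @ s)
        assert np.abs(primal - dual).max() < 1e-8
        pool = SupportPool(s, class_id=0, k=1, r=kr)
        res = reconstruct(q, pool, make_params(lam=lam, rho=rho, k=1, r=kr, d=d))
        np.testing.assert_allclose(res.reconstruction, primal, atol=1e-8)

    def test_distance_definition_holds(self, rng):
        q = rng.normal(size=(4, 3))
        pool = SupportPool(rng.normal(size=(6, 3)), class_id=0, k=2, r=3)
        res = reconstruct(q, pool, ReconHeadParams())
        direct = np.sum((q - res.reconstruction) ** 2) / 4
        assert abs(res.distance - direct) < 1e-9

    def test_support_row_permutation_invariance(self, rng):
        q = rng.normal(size=(3, 4))
        s = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        p1 = SupportPool(s, class_id=0, k=2, r=3)
        p2 = SupportPool(s[perm], class_id=0, k=2, r=3)
        params = make_params(lam=0.3, k=2, r=3, d=4)
        r1 = reconstruct(q, p1, params, retain_weights=True)
        r2 = reconstruct(q, p2, params, retain_weights=True)
        assert np.abs(r1.reconstruction - r2.reconstruction).max() < 1e-10
        assert abs(r1.distance - r2.distance) < 1e-10
        np.testing.assert_allclose(r1.weights[:, perm], r2.weights, atol=1e-10)

    def test_lambda_monotonicity_of_distance(self, rng):
        """With rho=1 the reconstruction error is non-decreasing in lambda."""
        q = rng.normal(size=(4, 3))
        s = rng.normal(size=(5, 3))
        pool = SupportPool(s, class_id=0, k=1, r=5)
        dists = [
            reconstruct(q, pool, make_params(lam=lam, k=1, r=5, d=3)).distance
            for lam in np.logspace(-4, 4, 17)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(dists, dists[1:]))


class TestClassProbabilities:
    def test_symmetry(self):
        np.testing.assert_allclose(class_probabilities([0.25, 0.25], 1.0), [0.5, 0.5])

    def test_log_two_gap(self):
        p = class_probabilities([0.0, np.log(2.0)], 1.0)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_large_gamma_no_overflow(self):
        p = class_probabilities([0.0, 1.0], 1000.0)
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p, [1.0, 0.0], atol=1e-12)

    def test_sums_to_one_and_uniform_limit(self, rng):
        d = rng.random(5)
        p = class_probabilities(d, 3.7)
        assert abs(p.sum() - 1.0) < 1e-12
        p0 = class_probabilities(d, 1e-12)
        np.testing.assert_allclose(p0, 0.2, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            class_probabilities([0.5], 1.0)
        with pytest.raises(ValueError):
            class_probabilities([0.5, 0.2], 0.0)


class TestClassify:
    def test_query_in_support_span_wins(self, rng):
        s0 = rng.normal(size=(4, 3))
        q = s0[0:1] + s0[1:2]
        pools = [SupportPool(s0, 0, 1, 4), SupportPool(rng.normal(size=(4, 3)), 1, 1, 4)]
        pred, probs, dists = classify(q, pools, make_params(lam=1e-8, k=1, r=4, d=3))
        assert pred == 0
        assert dists[0] < dists[1]

    def test_tie_breaks_to_lower_class(self, rng):
        s = rng.normal(size=(4, 3))
        pools = [SupportPool(s, 0, 1, 4), SupportPool(s.copy(), 1, 1, 4)]
        q = rng.normal(size=(2, 3))
        pred, probs, dists = classify(q, pools, ReconHeadParams())
        assert dists[0] == dists[1]
        assert pred == 0

    def test_argmin_distance_equals_argmax_probability(self, rng):
        """Composition oracle: classify agrees with per-class reconstruct."""
        params = ReconHeadParams(alpha=0.3, beta=-0.2, gamma=2.0)
        for _ in range(10):
            q = rng.normal(size=(3, 4))
            pools = [SupportPool(rng.normal(size=(6, 4)), c, 2, 3) for c in range(2)]
            pred, probs, dists = classify(q, pools, params)
            brute = np.array([reconstruct(q, p, params).distance for p in pools])
            np.testing.assert_allclose(dists, brute, atol=1e-12)
            assert pred == int(np.argmin(brute)) == int(np.argmax(probs))

    def test_mismatched_channels_rejected(self, rng):
        pools = [SupportPool(rng.normal(size=(4, 3)), 0, 1, 4),
                 SupportPool(rng.normal(size=(4, 2)), 1, 1, 4)]
        with pytest.raises(ValueError):
            classify(rng.normal(size=(2, 3)), pools, ReconHeadParams())


class TestDifferentiableHead:
    def test_distances_match_numpy_path(self, rng):
        head = FRNHead()
        head.alpha.data += 0.2
        head.beta.data -= 0.1
        r, d = 4, 3
        q = rng.normal(size=(2 * r, d))
        s0 = rng.normal(size=(2 * r, d))
        s1 = rng.normal(size=(3 * r, d))
        dist = head.distances(Tensor(q), r, [(Tensor(s0), 2), (Tensor(s1), 3)])
        params = head.params()
        for i, (s, k) in enumerate([(s0, 2), (s1, 3)]):
            pool = SupportPool(s, i, k, r)
            for j in range(2):
                ref = reconstruct(q[j * r:(j + 1) * r], pool, params).distance
                np.testing.assert_allclose(dist.data[j, i], ref, atol=1e-10)

    def test_head_scalar_gradients_match_finite_differences(self, rng):
        head = FRNHead()
        r, d = 3, 4
        q = rng.normal(size=(2 * r, d))
        s0 = rng.normal(size=(2 * r, d))
        s1 = rng.normal(size=(2 * r, d))
        labels = np.array([0, 1])

        def loss():
            dist = head.distances(Tensor(q), r, [(Tensor(s0), 2), (Tensor(s1), 2)])
            log_p = head.log_probabilities(dist)
            n = log_p.shape[0]
            return log_p[np.arange(n), labels].sum() * (-1.0 / n)

        val = loss()
        val.backward()
        h = 1e-6
        for p in (head.alpha, head.beta, head.log_gamma):
            auto = float(p.grad)
            p.zero_grad()
            p.data += h
            lp = loss().item()
            p.data -= 2 * h
            lm = loss().item()
            p.data += h
            fd = (lp - lm) / (2 * h)
            assert abs(fd - auto) / max(abs(fd), 1e-12) < 1e-3
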