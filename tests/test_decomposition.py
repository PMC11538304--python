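import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migtensor import (
    CPModel,
    MaskedNCPD,
    factor_match_score,
    fit_ncpd,
    masked_objective,
    normalize_factors,
    rank_scan,
    reconstruct,
    stability_check,
)
from migtensor.decomposition import RankScan, match_congruences
from migtensor.io import FlowTensor, GeoIndex
from migtensor.synthetic import PlantedSpec, generate

from oracles import loop_masked_objective, loop_reconstruct


def _random_model(rng, I=4, K=3, F=3):
    A = rng.uniform(0, 1, (I, F))
    B = rng.uniform(0, 1, (I, F))
    C = rng.uniform(0, 1, (K, F))
    return normalize_factors(A, B, C)


def _tensor_from(values):
    values = np.asarray(values, dtype=float)
    I = values.shape[0]
    mask = np.ones_like(values)
    idx = np.arange(I)
    mask[idx, idx, :] = 0
    geo = GeoIndex.from_labels([f"g{i}" for i in range(I)])
    return FlowTensor(values, mask, geo, tuple(range(values.shape[2])))


class TestReconstruct:
    def test_single_spike_component(self):
        m = CPModel(
            A=np.array([[1.0], [0.0]]),
            B=np.array([[0.0], [1.0]]),
            C=np.array([[1.0]]),
            weights=np.array([3.0]),
        )
        out = reconstruct(m)
        expected = np.zeros((2, 2, 1))
        expected[0, 1, 0] = 3.0
        np.testing.assert_allclose(out, expected)

    def test_matches_triple_loop_oracle(self, rng):
        m = _random_model(rng)
        np.testing.assert_allclose(
            reconstruct(m), loop_reconstruct(m.weights, m.A, m.B, m.C), atol=1e-12
        )

    def test_block_support_pattern(self):
        """A system with 2 origins and 3 destinations fills exactly that block."""
        labels = ["SF", "SantaClara", "Alameda", "SanMateo", "Marin"]
        A = np.zeros((5, 1))
        B = np.zeros((5, 1))
        A[[0, 1], 0] = [0.8, 0.6]
        B[[2, 3, 4], 0] = [0.7, 0.5, 0.2]
        C = np.ones((4, 1))
        m = normalize_factors(A, B, C, geo=GeoIndex.from_labels(labels))
        out = reconstruct(m)
        support = out > 0
        expected = np.zeros((5, 5, 4), dtype=bool)
        expected[np.ix_([0, 1], [2, 3, 4], range(4))] = True
        assert np.array_equal(support, expected)
        # per-period scaling follows c
        np.testing.assert_allclose(out[0, 2, :] / out[0, 2, 0], C[:, 0] / C[0, 0])


class TestMaskedObjective:
    def test_diagonal_never_contributes(self, rng):
        m = _random_model(rng)
        values = reconstruct(m)
        idx = np.arange(values.shape[0])
        values[idx, idx, :] = rng.uniform(100, 200, size=values[idx, idx, :].shape)
        t = _tensor_from(values)
        assert masked_objective(t, m) == pytest.approx(0.0, abs=1e-20)

    def test_zero_model_gives_masked_sumsq(self, small_tensor):
        m = CPModel(
            A=np.zeros((4, 1)),
            B=np.zeros((4, 1)),
            C=np.zeros((3, 1)),
            weights=np.zeros(1),
        )
        assert masked_objective(small_tensor, m) == pytest.approx(
            small_tensor.masked_sumsq()
        )

    def test_matches_triple_loop_oracle(self, rng, small_tensor):
        m = _random_model(rng)
        expected = loop_masked_objective(
            small_tensor.values, small_tensor.mask, m.weights, m.A, m.B, m.C
        )
        assert masked_objective(small_tensor, m) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, rng, small_tensor):
        m = _random_model(rng, I=5)
        with pytest.raises(ValueError, match="shape"):
            masked_objective(small_tensor, m)


class TestNormalize:
    def test_column_norms_and_scale(self):
        m = normalize_factors(
            np.array([[3.0], [4.0], [0.0]]),
            np.array([[0.0], [0.0], [1.0]]),
            np.array([[2.0], [0.0]]),
        )
        np.testing.assert_allclose(m.A[:, 0], [0.6, 0.8, 0.0])
        assert m.weights[0] == pytest.approx(10.0)  # 5 * 1 * 2

    def test_idempotent_on_normalized_model(self, rng):
        m = _random_model(rng)
        m2 = normalize_factors(m.A * m.weights ** (1 / 3), m.B * m.weights ** (1 / 3),
                               m.C * m.weights ** (1 / 3))
        np.testing.assert_allclose(m2.weights, m.weights, rtol=1e-12)
        np.testing.assert_allclose(m2.A, m.A, atol=1e-12)

    def test_components_sorted_by_scale(self, rng):
        A = rng.uniform(0.1, 1, (4, 2))
        B = rng.uniform(0.1, 1, (4, 2))
        C = rng.uniform(0.1, 1, (3, 2))
        A[:, 0] *= 2.0 / np.linalg.norm(A[:, 0])
        A[:, 1] *= 7.0 / np.linalg.norm(A[:, 1])
        for M in (B, C):
            M /= np.linalg.norm(M, axis=0)
        m = normalize_factors(A, B, C)
        assert m.weights[0] == pytest.approx(7.0) and m.weights[1] == pytest.approx(2.0)

    def test_reconstruction_preserved(self, rng):
        A = rng.uniform(0, 2, (4, 3))
        B = rng.uniform(0, 2, (4, 3))
        C = rng.uniform(0, 2, (3, 3))
        raw = np.einsum("if,jf,kf->ijk", A, B, C)
        m = normalize_factors(A, B, C)
        np.testing.assert_allclose(reconstruct(m), raw, rtol=1e-12, atol=1e-12)

    def test_zero_column_dropped_with_warning(self, rng):
        A = rng.uniform(0.1, 1, (4, 2))
        B = rng.uniform(0.1, 1, (4, 2))
        C = rng.uniform(0.1, 1, (3, 2))
        A[:, 1] = 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            m = normalize_factors(A, B, C)
        assert m.n_components == 1


class TestFit:
    def test_rank1_noiseless_recovery(self):
        spec = PlantedSpec(I=10, K=6, F_true=1, support_size=3, noise="none", seed=5)
        t, truth = generate(spec)
        m = fit_ncpd(t, 1, seed=0, n_restarts=5)
        assert factor_match_score(m, truth) >= 0.999

    def test_invariance_to_masked_cell_values(self):
        """Perturbing diagonal (masked) cells changes nothing, bitwise."""
        spec = PlantedSpec(I=8, K=5, F_true=2, support_size=3, noise="none", seed=9)
        t, _ = generate(spec)
        m1 = fit_ncpd(t, 2, seed=4, n_restarts=3)
        values = t.values.copy()
        idx = np.arange(t.n_geo)
        values[idx, idx, :] *= 1000.0
        values[idx, idx, :] += 123.456
        t2 = FlowTensor(values, t.mask.copy(), t.geo, t.periods)
        m2 = fit_ncpd(t2, 2, seed=4, n_restarts=3)
        assert np.array_equal(m1.A, m2.A)
        assert np.array_equal(m1.B, m2.B)
        assert np.array_equal(m1.C, m2.C)
        assert m1.objective_trace == m2.objective_trace

    def test_objective_trace_monotone(self, small_tensor):
        m = fit_ncpd(small_tensor, 2, seed=1, n_restarts=3)
        tr = np.asarray(m.objective_trace)
        assert np.all(np.diff(tr) <= 1e-10 * np.maximum(tr[:-1], 1e-300))

    def test_deterministic_given_seed(self, small_tensor):
        m1 = fit_ncpd(small_tensor, 2, seed=3, n_restarts=3, max_iter=60)
        m2 = fit_ncpd(small_tensor, 2, seed=3, n_restarts=3, max_iter=60)
        assert np.array_equal(m1.A, m2.A) and m1.objective_trace == m2.objective_trace

    def test_all_zero_observed_data_rejected(self):
        geo = GeoIndex.from_labels(["a", "b"])
        values = np.zeros((2, 2, 2))
        values[[0, 1], [0, 1], :] = 5.0  # only diagonal, all masked
        mask = np.ones_like(values)
        mask[[0, 1], [0, 1], :] = 0
        t = FlowTensor(values, mask, geo, (0, 1))
        with pytest.raises(ValueError, match="nothing to fit"):
            fit_ncpd(t, 1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MaskedNCPD(n_components=1).fit(np.full((2, 2, 1), np.nan))

    def test_estimator_fitted_attributes(self, small_tensor):
        est = MaskedNCPD(n_components=2, n_restarts=2, random_state=0, max_iter=50)
        est.fit(small_tensor)
        assert est.origin_factors_.shape == (4, 2)
        assert est.weights_.shape == (2,)
        assert 0 <= est.reconstruction_err_ <= 1
        np.testing.assert_allclose(np.linalg.norm(est.origin_factors_, axis=0), 1.0)
        params = est.get_params()
        assert params["n_components"] == 2 and params["random_state"] == 0

    def test_warm_start_cannot_worsen_the_fit(self, small_tensor):
        cold = MaskedNCPD(n_components=2, n_restarts=3, random_state=0).fit(small_tensor)
        m = cold.model_
        scale = m.weights ** (1 / 3)
        warm = MaskedNCPD(
            n_components=2,
            n_restarts=3,
            random_state=0,
            init_factors=(m.A * scale, m.B * scale, m.C * scale),
        ).fit(small_tensor)
        assert warm.objective_trace_[-1] <= cold.objective_trace_[-1] * (1 + 1e-9)


class TestModelInvariance:
    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_reconstruction_invariant_to_permutation_and_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        F = 3
        A = rng.uniform(0.1, 1, (4, F))
        B = rng.uniform(0.1, 1, (4, F))
        C = rng.uniform(0.1, 1, (3, F))
        base = reconstruct(normalize_factors(A, B, C))
        perm = rng.permutation(F)
        alpha = rng.uniform(0.5, 2.0, F)
        m2 = normalize_factors(A[:, perm] * alpha, B[:, perm], C[:, perm] / alpha)
        np.testing.assert_allclose(reconstruct(m2), base, rtol=1e-10, atol=1e-12)


class TestRankDiagnostics:
    def test_rank1_exact_tensor_has_negligible_residual(self):
        spec = PlantedSpec(I=8, K=5, F_true=1, support_size=3, noise="none", seed=2)
        t, _ = generate(spec)
        scan = rank_scan(t, [1], seed=0, n_restarts=3)
        assert scan.rel_residual[0] <= 1e-6

    def test_residuals_bounded_and_decreasing(self, small_tensor):
        scan = rank_scan(small_tensor, [1, 2, 3], seed=0, n_restarts=3)
        r = scan.rel_residual
        assert all(0 <= x <= 1 for x in r)
        assert all(b <= a + 1e-6 for a, b in zip(r, r[1:]))

    def test_nondecreasing_rank_list_rejected(self, small_tensor):
        with pytest.raises(ValueError):
            rank_scan(small_tensor, [2, 2])

    def test_pure_noise_tensor_has_no_elbow(self):
        rng = np.random.default_rng(77)
        values = rng.uniform(0, 1, (12, 12, 8))
        idx = np.arange(12)
        values[idx, idx, :] = 0
        geo = GeoIndex.from_labels([f"g{i}" for i in range(12)])
        mask = np.ones_like(values)
        mask[idx, idx, :] = 0
        t = FlowTensor(values, mask, geo, tuple(range(8)))
        scan = rank_scan(t, [1, 2, 3, 4], seed=0, n_restarts=3, max_iter=200)
        assert scan.elbow(min_drop_ratio=2.0) is None

    def test_elbow_on_synthetic_drop_pattern(self):
        scan = RankScan(F_values=[1, 2, 3, 4, 5], rel_residual=[0.7, 0.4, 0.1, 0.095, 0.09])
        assert scan.elbow() == 3


class TestStability:
    def test_model_against_itself_scores_one(self, rng):
        m = _random_model(rng)
        np.testing.assert_allclose(match_congruences(m, m), 1.0, atol=1e-12)

    def test_orthogonal_supports_score_zero(self):
        A1 = np.zeros((6, 1)); A1[[0, 1], 0] = 1.0
        A2 = np.zeros((6, 1)); A2[[4, 5], 0] = 1.0
        B = np.ones((6, 1))
        C = np.ones((4, 1))
        m1 = normalize_factors(A1, B, C)
        m2 = normalize_factors(A2, B, C)
        assert match_congruences(m1, m2)[0] == pytest.approx(0.0, abs=1e-12)

    def test_f_plus_must_exceed_f(self, small_tensor):
        with pytest.raises(ValueError):
            stability_check(small_tensor, 3, 2)
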