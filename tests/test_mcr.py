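import numpy as np
import pytest

from ramanmcr import synth
from ramanmcr.errors import DegenerateInputError, ParameterError
from ramanmcr.mcr import (
    MCRConfig,
    abundance_per_cell,
    estimate_rank,
    fit_mcr_als,
    initialize_from_svd,
    match_components,
    relative_abundance,
    update_H,
    update_W,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw", [dict(k=0), dict(alpha2=-1), dict(tol=0), dict(max_iter=0), dict(nonneg="x")]
    )
    def test_invalid(self, kw):
        with pytest.raises(ParameterError):
            MCRConfig(**kw)


class TestEstimateRank:
    def test_exact_rank_four(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(size=(80, 4)) @ rng.uniform(size=(4, 40))
        assert estimate_rank(A).suggested_k == 4

    def test_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            rep = estimate_rank(np.zeros((5, 5)))
        assert rep.suggested_k == 0

    def test_seven_component_noisy_dataset(self, default_sim):
        from ramanmcr.preprocess import crop_fingerprint, remove_cosmic_rays

        ds = crop_fingerprint(remove_cosmic_rays(default_sim.dataset).dataset)
        rep = estimate_rank(ds)
        assert rep.suggested_k in {6, 7, 8}
        assert "suggested k" in str(rep)


class TestInitialization:
    def test_rank_one_closed_form(self):
        w = np.array([3.0, 4.0])
        h = np.array([1.0, 2.0, 2.0])
        W0, H0 = initialize_from_svd(np.outer(w, h), 1)
        # leading singular vectors of a non-negative rank-1 matrix
        assert np.allclose(W0[:, 0] / np.linalg.norm(W0[:, 0]), w / np.linalg.norm(w))
        assert np.allclose(H0[0] / np.linalg.norm(H0[0]), h / np.linalg.norm(h))

    def test_nonnegative_by_construction(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(20, 10))
        W0, H0 = initialize_from_svd(A, 5)
        assert np.all(W0 >= 0) and np.all(H0 >= 0)
        assert np.all(np.any(W0 > 0, axis=0))  # no dead columns

    def test_k_too_large(self):
        with pytest.raises(ParameterError):
            initialize_from_svd(np.ones((4, 3)), 4)

    def test_seven_components_on_generator(self, small_world):
        W0, H0 = initialize_from_svd(small_world.dataset.A, 7)
        assert W0.shape[1] == 7 and np.all(np.any(W0 > 0, axis=0))


class TestUpdateH:
    def test_orthonormal_exact(self):
        W, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(20, 3)))
        H_true = np.abs(np.random.default_rng(1).normal(size=(3, 6)))
        H = update_H(W @ H_true, W, alpha2=0.0)
        np.testing.assert_allclose(H, H_true, atol=1e-10)

    def test_scalar_closed_form(self):
        w = np.array([[0.6], [0.8]])  # unit vector
        A = 3.0 * w
        for alpha2 in (0.0, 0.005, 0.3):
            H = update_H(A, w, alpha2)
            assert H[0, 0] == pytest.approx(3.0 / (1.0 + alpha2))

    def test_l1_shrinkage_entrywise(self):
        rng = np.random.default_rng(2)
        W = np.abs(rng.normal(size=(30, 3)))
        H_true = np.abs(rng.normal(size=(3, 8)))
        A = W @ H_true
        H0 = update_H(A, W, 0.0)
        H1 = update_H(A, W, 0.05)
        assert np.all(H1 <= H0 + 1e-12)

    def test_nnls_mode_matches_clip_when_interior(self):
        W, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(15, 2)))
        W = np.abs(W)
        H_true = 1.0 + np.abs(np.random.default_rng(4).normal(size=(2, 5)))
        A = W @ H_true
        np.testing.assert_allclose(
            update_H(A, W, 0.01, "nnls"), update_H(A, W, 0.01, "clip"), atol=1e-8
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ParameterError):
            update_H(np.ones((4, 2)), np.ones((5, 2)), 0.0)


class TestUpdateW:
    def test_orthonormal_rows_exact(self):
        Q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(8, 3)))
        H = Q.T  # orthonormal rows
        W_true = np.abs(np.random.default_rng(1).normal(size=(20, 3)))
        W = update_W(W_true @ H, H, beta2=0.0)
        np.testing.assert_allclose(W, W_true, atol=1e-10)

    def test_scalar_closed_form(self):
        h = np.array([[0.6, 0.8]])  # unit-norm row
        w = np.array([2.0, 1.0, 5.0])
        A = 5.0 * np.outer(w, h)
        for beta2 in (0.0, 0.005, 0.2):
            W = update_W(A, h, beta2)
            np.testing.assert_allclose(W[:, 0], 5.0 * w / (1.0 + beta2), atol=1e-10)

    def test_ridge_shrinks_frobenius_norm(self):
        rng = np.random.default_rng(5)
        H = np.abs(rng.normal(size=(3, 12)))
        A = np.abs(rng.normal(size=(10, 12)))
        W0 = update_W(A, H, 0.0)
        W1 = update_W(A, H, 0.005)
        assert np.linalg.norm(W1) < np.linalg.norm(W0)


class TestFit:
    def test_rank_one(self):
        w = np.array([1.0, 2.0, 2.0])
        h = np.array([4.0, 1.0, 3.0, 2.0])
        res = fit_mcr_als(np.outer(w, h), MCRConfig(k=1, alpha2=0, beta2=0))
        assert np.allclose(res.W[:, 0], w / np.linalg.norm(w), atol=1e-8)
        assert np.allclose(res.H[0] / np.linalg.norm(res.H[0]), h / np.linalg.norm(h), atol=1e-8)

    def test_noiseless_component_recovery(self):
        jit = {"AF": 1.2, "N+P": 1.2, "Lipid 1": 1.2, "P": 1.2}
        cfg = synth.GeneratorConfig(
            seed=2,
            n_cells_per_group=15,
            wn_step=2.0,
            components=("AF", "N+P", "Lipid 1", "P"),
            noise_sigma=0.0,
            spike_rate=0.0,
            point_jitter_cv=jit,
            lipid_dropout=0.1,
        )
        sim = synth.simulate_cells(cfg)
        res = fit_mcr_als(
            sim.dataset, MCRConfig(k=4, alpha2=0, beta2=0, tol=1e-13, max_iter=6000)
        )
        A = sim.dataset.A
        assert np.linalg.norm(A - res.W @ res.H) / np.linalg.norm(A) < 1e-6
        _, cos = match_components(res.W, sim.W_true.to_numpy())
        assert np.min(cos) > 0.99

    def test_nonnegativity_scale_and_objective(self, small_world):
        from ramanmcr.preprocess import preprocess_dataset

        pts, _ = preprocess_dataset(small_world.dataset, average=False)
        res = fit_mcr_als(pts, MCRConfig(max_iter=300))
        assert np.all(res.W >= 0) and np.all(res.H >= 0)
        np.testing.assert_allclose(np.linalg.norm(res.W, axis=0), 1.0, atol=1e-10)
        assert res.objective_trace[-1] <= res.objective_trace[0]

    def test_homogeneity(self):
        rng = np.random.default_rng(7)
        A = np.abs(rng.normal(size=(30, 10)))
        c1 = fit_mcr_als(A, MCRConfig(k=3, alpha2=0, beta2=0, max_iter=200, tol=1e-12))
        c2 = fit_mcr_als(2 * A, MCRConfig(k=3, alpha2=0, beta2=0, max_iter=200, tol=1e-12))
        np.testing.assert_allclose(c2.W, c1.W, atol=1e-6)
        np.testing.assert_allclose(c2.H, 2 * c1.H, rtol=1e-5, atol=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_mcr_als(np.zeros((5, 5)), MCRConfig(k=2))

    def test_negative_input_floored_with_warning(self):
        A = np.ones((6, 4))
        A[0, 0] = -1.0
        with pytest.warns(UserWarning, match="negative"):
            fit_mcr_als(A, MCRConfig(k=1, max_iter=10))


class TestRelativeAbundance:
    def _result(self, H):
        from ramanmcr.mcr import MCRResult

        H = np.asarray(H, dtype=float)
        return MCRResult(np.ones((3, H.shape[0])), H, np.array([1.0, 0.5]), 1, True)

    def test_arithmetic(self):
        res = self._result([[2.0, 4.0, 6.0], [1.0, 2.0, 3.0]])
        ra = relative_abundance(res, 0, 1)
        np.testing.assert_array_equal(ra.ratios, [2.0, 2.0, 2.0])
        assert not ra.excluded.any()

    def test_zero_denominator_flagged(self):
        res = self._result([[2.0, 4.0], [1.0, 0.0]])
        ra = relative_abundance(res, 0, 1)
        assert list(ra.excluded) == [False, True]
        assert ra.ratios[0] == 2.0 and np.isnan(ra.ratios[1])
        assert ra.mean == 2.0

    def test_self_ratio_is_one(self):
        res = self._result([[2.0, 4.0, 0.0]])
        ra = relative_abundance(res, 0, 0)
        np.testing.assert_array_equal(ra.ratios[~ra.excluded], [1.0, 1.0])

    def test_index_validation(self):
        res = self._result([[1.0, 2.0]])
        with pytest.raises(ParameterError):
            relative_abundance(res, 0, 3)


class TestAbundancePerCell:
    def test_groups_by_first_appearance(self):
        H = np.array([[1.0, 3.0, 10.0, 20.0]])
        Hc, cells = abundance_per_cell(H, ["a", "a", "b", "b"])
        np.testing.assert_array_equal(Hc, [[2.0, 15.0]])
        assert list(cells) == ["a", "b"]
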