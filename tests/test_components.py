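"""PCA retention rule, varimax rotation, voxelwise GLM, permutation FWE."""

import numpy as np
import pytest

from latmorph import fit_component_model, fit_pca, varimax
from latmorph.components import (
    permutation_significance,
    spatial_maps_glm,
    varimax_criterion,
)


def _data_with_eigenvalues(eigs, n_vox=400, seed=0):
    """Terms x voxels data whose term-covariance eigenvalues equal ``eigs``."""
    eigs = np.asarray(eigs, dtype=float)
    t = len(eigs)
    rng = np.random.default_rng(seed)
    U = np.linalg.qr(rng.normal(size=(t, t)))[0]
    M = rng.normal(size=(n_vox, t))
    M -= M.mean(axis=0)  # columns orthogonal to the ones vector
    Q = np.linalg.qr(M)[0]  # orthonormal, so rows of X are exactly zero-mean
    return U @ np.diag(np.sqrt(eigs * (n_vox - 1))) @ Q.T


class TestFitPCA:
    def test_grand_average_retention_rule(self):
        # eigenvalues {3, 1, 0.5, 0.5}: mean 1.25 -> keep 1, explaining 3/5
        X = _data_with_eigenvalues([3.0, 1.0, 0.5, 0.5])
        model = fit_pca(X)
        assert np.allclose(model.eigenvalues, [3.0, 1.0, 0.5, 0.5], atol=1e-8)
        assert model.n_retained == 1
        assert np.isclose(model.variance_explained, 0.6, atol=1e-8)

    def test_exact_rank_k_data_has_k_nonzero_eigenvalues(self, box_grid):
        rng = np.random.default_rng(1)
        W = rng.dirichlet(np.ones(3), size=20)
        A = rng.normal(size=(3, 500))
        model = fit_pca(W @ A)
        assert np.sum(model.eigenvalues > 1e-10 * model.eigenvalues[0]) == 3

    def test_all_components_reconstruct_centred_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 300))
        Xc = X - X.mean(axis=1, keepdims=True)
        model = fit_pca(X, n_retained=10)
        L = model.loadings_unrotated  # eigvecs * sqrt(eigs)
        scores = np.linalg.lstsq(L, Xc, rcond=None)[0]
        assert np.allclose(L @ scores, Xc, atol=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            fit_pca(np.ones((5, 10)))  # rank 0 after centring


class TestVarimax:
    def test_perfect_simple_structure_is_a_fixed_point(self):
        L = np.zeros((9, 3))
        for i in range(9):
            L[i, i % 3] = [2.0, -1.5, 1.0][i % 3]
        rotated, R, conv = varimax(L)
        assert conv
        # unchanged up to column sign/permutation
        M = np.abs(rotated.T @ L) / (
            np.linalg.norm(rotated, axis=0)[:, None] * np.linalg.norm(L, axis=0)[None, :]
        )
        assert np.allclose(np.sort(M.max(axis=0)), 1.0, atol=1e-6)

    def test_rotation_preserves_loading_gram_matrix(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(25, 4))
        rotated, R, _ = varimax(L)
        assert np.allclose(R @ R.T, np.eye(4), atol=1e-8)
        assert np.allclose(rotated @ rotated.T, L @ L.T, atol=1e-8)
        assert np.allclose(rotated, L @ R, atol=1e-10)

    def test_two_column_rotation_matches_exhaustive_angle_sweep(self):
        rng = np.random.default_rng(4)
        L = rng.normal(size=(30, 2))
        rotated, _, _ = varimax(L)
        # brute-force oracle: scan rotation angles in 0.01-degree steps
        h = np.sqrt((L**2).sum(axis=1))
        A = L / h[:, None]
        best = -np.inf
        for deg in np.arange(0.0, 90.0, 0.01):
            a = np.deg2rad(deg)
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            best = max(best, varimax_criterion(A @ R))
        achieved = varimax_criterion(rotated / h[:, None])
        assert achieved >= best - 1e-6

    def test_criterion_does_not_decrease(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(40, 6))
        rotated, _, _ = varimax(L)
        h = np.sqrt((L**2).sum(axis=1))[:, None]
        assert varimax_criterion(rotated / h) >= varimax_criterion(L / h) - 1e-12

    def test_matches_statsmodels_criterion(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        rng = np.random.default_rng(6)
        L = rng.normal(size=(30, 5))
        h = np.sqrt((L**2).sum(axis=1))[:, None]
        ours, _, _ = varimax(L)
        theirs, _ = rotate_factors(L / h, "varimax")
        assert np.isclose(
            varimax_criterion(ours / h), varimax_criterion(theirs), rtol=1e-5
        )


class TestSpatialMapsGLM:
    def test_exact_linear_model_recovers_patterns(self):
        rng = np.random.default_rng(7)
        loadings = rng.normal(size=(20, 3))
        patterns = rng.normal(size=(3, 200))
        betas, _, _ = spatial_maps_glm(loadings @ patterns, loadings)
        assert np.allclose(betas, patterns, atol=1e-8)

    def test_all_zero_voxel_gives_zero_betas(self):
        rng = np.random.default_rng(8)
        loadings = rng.normal(size=(15, 2))
        Y = rng.normal(size=(15, 50))
        Y[:, 7] = 0.0
        betas, _, _ = spatial_maps_glm(Y, loadings)
        assert np.allclose(betas[:, 7], 0.0)

    def test_orthonormal_loadings_give_projection_betas(self):
        rng = np.random.default_rng(9)
        Q = np.linalg.qr(rng.normal(size=(20, 4)))[0]
        Y = rng.normal(size=(20, 100))
        betas, _, _ = spatial_maps_glm(Y, Q)
        assert np.allclose(betas, Q.T @ Y, atol=1e-10)

    def test_rank_deficiency_names_offending_columns(self):
        rng = np.random.default_rng(10)
        L = rng.normal(size=(10, 3))
        L[:, 2] = 2 * L[:, 0] - L[:, 1]
        with pytest.raises(ValueError, match="component"):
            spatial_maps_glm(rng.normal(size=(10, 20)), L)


class TestPermutationSignificance:
    def test_undersized_cluster_is_removed(self, box_grid):
        from latmorph.components import _cluster_filter, _connectivity_structure

        structure = _connectivity_structure(26)
        mask = np.zeros(box_grid.n_half_voxels, dtype=bool)
        mask[:19] = True  # 19 voxels, contiguous in the flattened box grid
        assert not _cluster_filter(mask, box_grid, 20, structure).any()
        mask[:20] = True
        assert _cluster_filter(mask, box_grid, 20, structure).sum() == 20

    def test_strong_single_component_recovered_with_high_sensitivity(self, box_grid):
        rng = np.random.default_rng(11)
        n_vox = box_grid.n_half_voxels
        pattern = box_grid.half_to_vector(
            __import__("scipy.ndimage", fromlist=["gaussian_filter"]).gaussian_filter(
                rng.normal(size=box_grid.half_shape), sigma=1.5
            )
        )
        pattern /= pattern.std()
        w = rng.normal(size=40)
        li = np.outer(w, pattern) * 3.0 + rng.normal(0, 0.1, size=(40, n_vox))
        model = fit_component_model(li)
        sig = permutation_significance(
            li, model, box_grid, n_perm=300, cluster_min=1, seed=12, statistic="z"
        )
        truly = np.abs(pattern) > 1.0  # clearly non-null voxels
        sens = (sig.any_mask & truly).sum() / truly.sum()
        assert sens >= 0.9

    def test_reordering_terms_leaves_masks_unchanged(self, box_grid):
        """Term order only permutes loading rows; with the same seed the
        significance masks are identical."""
        from latmorph.synthetic import generate_term_maps
        from latmorph.li import hemisphere_matrices

        ts, _ = generate_term_maps(box_grid, 24, 3, noise_sd=0.1, seed=51)
        left, right = hemisphere_matrices(ts.volumes, box_grid, 0.0)
        li = right - left
        order = np.random.default_rng(52).permutation(24)

        masks = []
        for Y in (li, li[order]):
            model = fit_component_model(Y)
            sig = permutation_significance(Y, model, box_grid, n_perm=150,
                                           cluster_min=5, seed=53, statistic="z")
            masks.append(sig.any_mask)
        assert np.array_equal(masks[0], masks[1])

    def test_parameter_preconditions(self, planted):
        with pytest.raises(ValueError):
            permutation_significance(planted["li"], planted["model"], planted["grid"],
                                     n_perm=50)
        with pytest.raises(ValueError):
            permutation_significance(planted["li"], planted["model"], planted["grid"],
                                     n_perm=200, alpha=0.6)

    def test_lean_and_reference_paths_agree(self, planted):
        """The vectorised permutation loop must reproduce the plain per-
        permutation GLM on identical permutations."""
        from latmorph.components import varimax_batch

        li, model = planted["li"], planted["model"]
        L0 = model.loadings_unrotated
        rng = np.random.default_rng(13)
        perms = np.stack([rng.permutation(60) for _ in range(5)])
        rotated, R = varimax_batch(L0[perms])
        G0_inv = np.linalg.inv(L0.T @ L0)
        for i in range(5):
            betas_ref, _, z_ref = spatial_maps_glm(li, rotated[i])
            XtX_inv = R[i].T @ G0_inv @ R[i]
            coef = XtX_inv @ (rotated[i].T @ li)
            assert np.allclose(coef, betas_ref, atol=1e-8)
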