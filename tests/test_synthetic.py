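"""Synthetic-data generator: planted structure, nulls, determinism."""

import numpy as np
import pytest
from scipy.optimize import nnls

from latmorph import make_symmetric_grid
from latmorph.li import hemisphere_matrices
from latmorph.synthetic import (
    demo_dominance_field,
    generate_connectivity,
    generate_null_maps,
    generate_term_maps,
)


class TestTermMaps:
    def test_noise_free_li_equals_planted_convex_mixture(self, box_grid):
        ts, truth = generate_term_maps(box_grid, 30, 3, noise_sd=0.0, seed=7)
        left, right = hemisphere_matrices(ts.volumes, box_grid, 0.0)
        planted = truth.term_weights @ truth.archetype_patterns
        assert np.allclose(right - left, planted, atol=1e-12)

    def test_noise_free_maps_lie_in_archetype_simplex(self, box_grid):
        # nonnegative-least-squares reconstruction residual is zero
        ts, truth = generate_term_maps(box_grid, 30, 3, noise_sd=0.0, seed=7)
        left, right = hemisphere_matrices(ts.volumes, box_grid, 0.0)
        li = right - left
        A = truth.archetype_patterns.T
        for t in range(0, 30, 7):
            _, resid = nnls(A, li[t])
            assert resid < 1e-8

    def test_term_weights_are_convex(self, box_grid):
        _, truth = generate_term_maps(box_grid, 30, 4, noise_sd=0.1, seed=3)
        assert np.all(truth.term_weights >= 0)
        assert np.allclose(truth.term_weights.sum(axis=1), 1.0)

    def test_same_seed_is_bit_identical(self, box_grid):
        a, _ = generate_term_maps(box_grid, 20, 3, noise_sd=0.2, seed=11)
        b, _ = generate_term_maps(box_grid, 20, 3, noise_sd=0.2, seed=11)
        assert np.array_equal(a.volumes, b.volumes)
        c, _ = generate_term_maps(box_grid, 20, 3, noise_sd=0.2, seed=12)
        assert not np.array_equal(a.volumes, c.volumes)

    def test_dominance_field_within_bounds(self, box_grid):
        _, truth = generate_term_maps(box_grid, 20, 3, noise_sd=0.1, seed=2)
        d = truth.dominance_field
        assert np.nanmax(np.abs(d)) <= np.pi / 4 + 1e-12

    @pytest.mark.parametrize(
        "kwargs", [dict(n_archetypes=5), dict(n_terms=5), dict(noise_sd=-0.1)]
    )
    def test_invalid_parameters_rejected(self, box_grid, kwargs):
        args = dict(n_terms=30, n_archetypes=3, noise_sd=0.1)
        args.update(kwargs)
        with pytest.raises(ValueError):
            generate_term_maps(box_grid, args["n_terms"], args["n_archetypes"],
                               args["noise_sd"], seed=0)


class TestNullMaps:
    def test_expected_li_is_zero_across_seeds(self, box_grid):
        acc = np.zeros(box_grid.n_half_voxels)
        n_seeds = 20
        for s in range(n_seeds):
            ts = generate_null_maps(box_grid, 6, noise_sd=0.5, seed=100 + s)
            left, right = hemisphere_matrices(ts.volumes, box_grid, 0.0)
            acc += (right - left).mean(axis=0)
        mean_li = acc / n_seeds
        # SE of the mean LI per voxel: sqrt(2)*0.5 / sqrt(6*20)
        se = np.sqrt(2) * 0.5 / np.sqrt(6 * n_seeds)
        assert np.abs(mean_li).mean() < 2 * se

    def test_hemisphere_mirror_negates_li(self, box_grid):
        ts = generate_null_maps(box_grid, 5, noise_sd=0.3, seed=4)
        left, right = hemisphere_matrices(ts.volumes, box_grid, 0.0)
        mirrored = np.stack([box_grid.mirror(v) for v in ts.volumes])
        lm, rm = hemisphere_matrices(mirrored, box_grid, 0.0)
        assert np.allclose(rm - lm, -(right - left), atol=1e-12)

    def test_seed_determinism(self, box_grid):
        a = generate_null_maps(box_grid, 5, noise_sd=0.3, seed=9)
        b = generate_null_maps(box_grid, 5, noise_sd=0.3, seed=9)
        assert np.array_equal(a.volumes, b.volumes)


class TestConnectivity:
    def test_probabilities_are_multiples_of_one_over_n_subjects(self):
        dom = demo_dominance_field(200, seed=0)
        conn = generate_connectivity(None, dom, n_subjects=163, seed=1)
        p = conn.indicator.mean(axis=0)
        assert np.allclose(p * 163, np.round(p * 163), atol=1e-9)
        assert conn.indicator.shape == (163, 200)
        assert np.isin(conn.indicator, (0, 1)).all()
        assert np.all((conn.awf >= 0) & (conn.awf <= 1))

    def test_negative_slope_gives_negative_dominance_probability_correlation(self):
        dom = demo_dominance_field(3000, seed=2)
        conn = generate_connectivity(None, dom, conn_slope=-1.0, n_subjects=163,
                                     seed=3, p_jitter_sd=0.0)
        p = conn.indicator.mean(axis=0)
        r = np.corrcoef(np.abs(dom), p)[0, 1]
        assert r < -0.5

    def test_null_slope_and_offset_centre_pool_differences_on_zero(self):
        dom = np.concatenate([demo_dominance_field(1500, seed=4), np.full(1500, np.nan)])
        conn = generate_connectivity(None, dom, conn_slope=0.0, awf_offset=0.0,
                                     n_subjects=163, seed=5, p_jitter_sd=0.0)
        p = conn.indicator.mean(axis=0)
        lat, non = p[:1500], p[1500:]
        se = np.sqrt(p.var() * 2 / 1500)
        assert abs(lat.mean() - non.mean()) < 4 * se
        awf = conn.awf.mean(axis=0)
        se_awf = np.sqrt(awf.var() * 2 / 1500)
        assert abs(awf[:1500].mean() - awf[1500:].mean()) < 4 * se_awf

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            generate_connectivity(None, demo_dominance_field(10, seed=0), n_subjects=1)
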