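"""Dominance, pools, binning, and dominance-connectivity correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latmorph import (
    assign_voxel_dominance,
    bin_by_probability,
    dominance,
    dominance_connectivity_correlation,
    nonlateralised_mask,
    probability_of_connection,
    sample_difference_distribution,
)
from latmorph.connectivity import bin_edges_by_probability, distance_control
from latmorph.synthetic import SubjectConnectivity, demo_dominance_field, generate_connectivity


class TestDominance:
    def test_closed_forms(self):
        assert np.isclose(dominance(1.0, 1.0), 0.0)
        assert np.isclose(dominance(0.0, 1.0), np.pi / 4)
        assert np.isclose(dominance(1.0, 0.0), -np.pi / 4)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_hemisphere_swap(self, left, right):
        if left == 0 and right == 0:
            return
        assert np.isclose(dominance(left, right), -dominance(right, left), atol=1e-12)

    def test_both_zero_is_nan(self):
        d = dominance(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isnan(d[0]) and np.isclose(d[1], 0.0)

    def test_negative_activation_rejected(self):
        with pytest.raises(ValueError):
            dominance(-0.1, 1.0)


class TestAssignDominance:
    def test_argmax_z_component_selected_with_tie_to_lowest(self):
        z = np.array([[3.1, 2.0, 2.0], [2.2, 2.0, 4.0]])
        left = np.array([[1.0, 1.0, 1.0], [9.0, 9.0, 0.0]])
        right = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 1.0]])
        mask = np.array([True, True, True])
        dm = assign_voxel_dominance(z, left, right, mask)
        assert list(dm.component_id) == [0, 0, 1]  # tie at voxel 1 -> lowest index
        assert np.isclose(dm.dominance[0], 0.0)
        assert np.isclose(dm.dominance[2], np.pi / 4)

    def test_recovered_dominance_tracks_planted_field(self, planted):
        from latmorph.components import permutation_significance
        from latmorph.connectivity import (
            component_hemisphere_strengths,
            raw_hemisphere_strengths,
        )

        li, model, grid = planted["li"], planted["model"], planted["grid"]
        sig = permutation_significance(li, model, grid, n_perm=200, cluster_min=5,
                                       seed=31, statistic="z")
        assert sig.any_mask.sum() > 50
        truth_dom = planted["truth"].dominance_field

        # raw-value mode: mean hemisphere activations are exactly what the
        # generator's dominance field encodes
        bl, br = raw_hemisphere_strengths(planted["left"], planted["right"],
                                          model.n_retained)
        dm = assign_voxel_dominance(model.z_maps, bl, br, sig.any_mask)
        idx = sig.any_mask & ~np.isnan(dm.dominance)
        r = np.corrcoef(dm.dominance[idx], truth_dom[idx])[0, 1]
        assert r >= 0.95

        # component-level mode carries a per-component baseline, so recovery
        # is looser (threshold frozen from the recovery simulation)
        bl_c, br_c = component_hemisphere_strengths(planted["left"], planted["right"],
                                                    model.loadings_rotated)
        dm_c = assign_voxel_dominance(model.z_maps, bl_c, br_c, sig.any_mask)
        idx_c = sig.any_mask & ~np.isnan(dm_c.dominance)
        r_c = np.corrcoef(dm_c.dominance[idx_c], truth_dom[idx_c])[0, 1]
        assert r_c >= 0.7


class TestProbabilityAndPools:
    def test_probability_edge_cases(self):
        ind = np.array([[1, 0, 1], [1, 0, 0]])
        conn = SubjectConnectivity(n_subjects=2, indicator=ind, awf=np.full((2, 3), 0.5))
        assert np.allclose(probability_of_connection(conn), [1.0, 0.0, 0.5])

    def test_proportion_arithmetic(self):
        ind = np.zeros((163, 1), dtype=np.uint8)
        ind[:81, 0] = 1
        conn = SubjectConnectivity(163, ind, np.full((163, 1), 0.5))
        assert np.isclose(probability_of_connection(conn)[0], 81 / 163)

    def test_non_binary_indicator_rejected(self):
        conn = SubjectConnectivity(2, np.array([[2, 0]]), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            probability_of_connection(conn)

    def test_identical_pools_centre_differences_on_zero(self):
        rng = np.random.default_rng(0)
        n = 400
        p = rng.uniform(0.2, 0.9, size=n)
        awf = rng.normal(0.6, 0.05, size=(8, n))
        ind = (rng.random((8, n)) < p).astype(np.uint8)
        pools = {"lateralised": np.arange(n), "nonlateralised": np.arange(n)}
        dp, da = sample_difference_distribution(pools, p, awf, ind, frac=0.05,
                                                n_rep=400, seed=1)
        assert abs(dp.mean()) < 3 * dp.std(ddof=1) / np.sqrt(400)
        assert abs(da.mean()) < 3 * da.std(ddof=1) / np.sqrt(400)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_difference_distribution(
                {"lateralised": np.array([]), "nonlateralised": np.arange(3)},
                np.zeros(3), np.zeros((2, 3)), np.zeros((2, 3)),
            )


class TestBinning:
    def test_smallest_bin_width_is_exactly_one_over_n_subjects(self):
        edges = bin_edges_by_probability(163)
        assert np.isclose(edges[1] - edges[0], 1 / 163, atol=1e-12)
        assert np.isclose(edges[-1], 1.0)
        widths = np.diff(edges)
        assert np.all(np.diff(widths) > 0)  # strictly increasing widths

    def test_every_value_is_assigned(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, size=500)
        bins, edges = bin_by_probability(p, 163)
        assert bins.min() >= 0 and bins.max() < len(edges) - 1

    def test_all_values_in_one_bin(self):
        bins, _ = bin_by_probability(np.full(10, 0.5), 163)
        assert len(np.unique(bins)) == 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bin_edges_by_probability(1)
        with pytest.raises(ValueError):
            bin_by_probability(np.array([1.5]), 163)


class TestCorrelation:
    def test_perfect_linear_relation_gives_minus_one(self):
        p = np.linspace(0.1, 0.9, 200)
        dom = 0.7 - 0.6 * p
        bins, _ = bin_by_probability(p, 163)
        r, _, n = dominance_connectivity_correlation(dom, p, bins)
        assert n >= 3
        assert np.isclose(r, -1.0, atol=1e-6)

    def test_partial_correlation_matches_pingouin_on_bin_means(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        n = 2000
        cov = rng.uniform(0, 1, size=n)
        p = np.clip(0.2 + 0.6 * cov + rng.normal(0, 0.1, n), 0.01, 1.0)
        dom = np.clip(0.1 + 0.3 * cov + rng.normal(0, 0.1, n), 0, np.pi / 4)
        bins, _ = bin_by_probability(p, 163)
        r_part, _, _ = dominance_connectivity_correlation(dom, p, bins, covariate=cov)
        labels = np.unique(bins)
        df = pd.DataFrame({
            "x": [p[bins == b].mean() for b in labels],
            "y": [np.abs(dom)[bins == b].mean() for b in labels],
            "c": [cov[bins == b].mean() for b in labels],
        })
        expected = float(pg.partial_corr(data=df, x="x", y="y", covar="c")["r"].iloc[0])
        assert np.isclose(r_part, expected, atol=1e-10)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            dominance_connectivity_correlation(
                np.array([0.1, 0.2]), np.array([0.5, 0.5]), np.array([0, 0])
            )


class TestDistanceControl:
    def test_distance_independent_effect_has_small_correlation(self):
        rng = np.random.default_rng(4)
        n = 1000
        dist = np.concatenate([rng.uniform(1, 30, n), rng.uniform(1, 30, n)])
        p = np.concatenate([rng.normal(0.5, 0.05, n), rng.normal(0.6, 0.05, n)])
        pools = {"lateralised": np.arange(n), "nonlateralised": np.arange(n, 2 * n)}
        out = distance_control(pools, p, None, dist)
        assert abs(out["p_conn"]["r"]) < 0.15

    def test_distance_proportional_effect_is_detected(self):
        rng = np.random.default_rng(5)
        n = 1000
        d_lat = rng.uniform(1, 30, n)
        dist = np.concatenate([d_lat, rng.uniform(1, 30, n)])
        p = np.concatenate(
            [0.5 + 0.01 * d_lat + rng.normal(0, 0.02, n), rng.normal(0.5, 0.02, n)]
        )
        pools = {"lateralised": np.arange(n), "nonlateralised": np.arange(n, 2 * n)}
        out = distance_control(pools, p, None, dist)
        assert out["p_conn"]["r"] > 0.5

    def test_equidistant_voxels_rejected(self):
        pools = {"lateralised": np.arange(5), "nonlateralised": np.arange(5, 10)}
        with pytest.raises(ValueError):
            distance_control(pools, np.random.default_rng(0).random(10), None,
                             np.full(10, 3.0))


class TestNonLateralisedMask:
    def test_three_criteria_hold_on_planted_data(self, planted):
        from latmorph.components import permutation_significance

        li, model, grid = planted["li"], planted["model"], planted["grid"]
        sig = permutation_significance(li, model, grid, n_perm=200, cluster_min=5,
                                       seed=41, statistic="z")
        lat = sig.any_mask
        nonlat, per_hemi = nonlateralised_mask(
            planted["term_set"].volumes, lat, grid,
            n_perm=200, cluster_min=5, seed=42,
        )
        assert nonlat.sum() > 0
        assert not np.any(nonlat & lat)  # criterion 2: disjoint from lateralised
        # criteria 1+3: significant in both hemispheres (homologue included)
        assert np.all(nonlat <= per_hemi["left"].any_mask)
        assert np.all(nonlat <= per_hemi["right"].any_mask)

    def test_lateralised_voxels_are_excluded(self, planted):
        li, model, grid = planted["li"], planted["model"], planted["grid"]
        # claim every voxel is lateralised: nothing can satisfy criterion 2
        with pytest.raises(ValueError, match="no non-lateralised"):
            nonlateralised_mask(
                planted["term_set"].volumes,
                np.ones(grid.n_half_voxels, dtype=bool), grid,
                n_perm=200, seed=43,
            )

    def test_generated_connectivity_recovers_planted_offset(self):
        dom = demo_dominance_field(1500, n_nonlateralised=1500, seed=6)
        conn = generate_connectivity(None, dom, awf_offset=-0.05, n_subjects=163,
                                     seed=7)
        lat = ~np.isnan(dom)
        pools = {"lateralised": np.flatnonzero(lat),
                 "nonlateralised": np.flatnonzero(~lat)}
        p = probability_of_connection(conn)
        _, da = sample_difference_distribution(pools, p, conn.awf, conn.indicator,
                                               frac=0.05, n_rep=500, seed=8)
        assert abs(da.mean() - (-0.05)) < 0.01
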