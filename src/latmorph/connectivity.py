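"""Hemispheric dominance and callosal connectivity analyses.

This module relates graded functional lateralisation to interhemispheric
(corpus callosum) connectivity: it defines the non-lateralised comparison
pool, builds pooled difference distributions for connection probability
and callosal axonal water fraction, assigns a per-voxel hemispheric
dominance (``arctan(right/left) - pi/4`` radians, 0 = bilateral, +-pi/4 =
unilateral), and correlates binned dominance magnitude with connection
probability, optionally controlling for mean bilateral activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .components import fit_component_model, permutation_significance, SignificanceMask
from .grid import GridSpec
from .synthetic import SubjectConnectivity

logger = logging.getLogger(__name__)


@dataclass
class DominanceMap:
    """Per-voxel hemispheric dominance on significantly lateralised voxels."""

    dominance: np.ndarray = field(repr=False, default=None)  # radians, NaN off-mask
    component_id: np.ndarray = field(repr=False, default=None)  # int, -1 off-mask
    mean_activity: np.ndarray = field(repr=False, default=None)  # (left+right)/2


@dataclass
class ConnectivityProfile:
    """Connectivity summaries over lateralised / non-lateralised pools."""

    p_conn: np.ndarray = field(repr=False, default=None)
    pools: dict = None  # {"lateralised": idx, "nonlateralised": idx}
    diff_p_conn: np.ndarray | None = field(repr=False, default=None)
    diff_awf: np.ndarray | None = field(repr=False, default=None)


# --------------------------------------------------------------------------
# Pools
# --------------------------------------------------------------------------


def nonlateralised_mask(
    original_maps: np.ndarray,
    lateralised_mask: np.ndarray,
    grid: GridSpec,
    fwhm_mm: float = 0.0,
    n_perm: int = 500,
    alpha: float = 0.05,
    cluster_min: int = 20,
    connectivity: int = 26,
    seed: int = 0,
    statistic: str = "z",
) -> tuple[np.ndarray, dict]:
    """Voxels significantly active bilaterally but not lateralised.

    Reruns the component-significance machinery on the *original*
    (un-differenced) hemisphere maps, separately per hemisphere, and keeps
    half-grid voxels that (1) pass the significance threshold for at least
    one component in a hemisphere, (2) do not overlap the lateralised
    mask, and (3) whose homologue in the opposite hemisphere also meets
    (1) and (2).  Returns the half-grid boolean vector and the two
    per-hemisphere significance masks.
    """
    from .li import hemisphere_matrices

    left_m, right_m = hemisphere_matrices(original_maps, grid, fwhm_mm)
    lat = np.asarray(lateralised_mask, dtype=bool)
    sig = {}
    for name, mat, sub_seed in (("left", left_m, 0), ("right", right_m, 1)):
        model = fit_component_model(mat)
        sig[name] = permutation_significance(
            mat, model, grid, n_perm=n_perm, alpha=alpha, cluster_min=cluster_min,
            connectivity=connectivity, seed=np.random.default_rng((seed, sub_seed)),
            statistic=statistic,
        )
    meets_left = sig["left"].any_mask & ~lat
    meets_right = sig["right"].any_mask & ~lat
    # homologous voxels share half-grid indices, so criterion (3) is an AND
    mask = meets_left & meets_right
    if not mask.any():
        raise ValueError("no non-lateralised voxels found; pipeline cannot proceed")
    return mask, sig


# --------------------------------------------------------------------------
# Connection probability and pooled differences
# --------------------------------------------------------------------------


def probability_of_connection(conn: SubjectConnectivity) -> np.ndarray:
    """Per-voxel fraction of subjects with a callosal connection."""
    ind = np.asarray(conn.indicator)
    if not np.isin(ind, (0, 1)).all():
        raise ValueError("indicator must be binary")
    return ind.mean(axis=0)


def sample_difference_distribution(
    pools: dict,
    p_conn: np.ndarray,
    awf: np.ndarray,
    weights_source: np.ndarray,
    frac: float = 0.05,
    n_rep: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lateralised-minus-non-lateralised difference distributions.

    Per repetition, ``ceil(frac * pool size)`` voxels are sampled without
    replacement from each pool; the differences in mean connection
    probability and in replicability-weighted mean axonal water fraction
    are recorded.  A callosal voxel's weight is the fraction of subjects
    in which it connects to at least one sampled cortical voxel (with the
    one-to-one cortical-callosal mapping this is its connection
    probability restricted to the sample).

    Negative values mean weaker connectivity of the lateralised pool.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    lat = np.asarray(pools["lateralised"], dtype=int)
    non = np.asarray(pools["nonlateralised"], dtype=int)
    if lat.size == 0 or non.size == 0:
        raise ValueError("both pools must be non-empty")
    n_lat = int(np.ceil(frac * lat.size))
    n_non = int(np.ceil(frac * non.size))
    if n_lat == 0 or n_non == 0:
        raise ValueError("sample size is zero; increase frac")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    awf_voxel_mean = np.asarray(awf, dtype=float).mean(axis=0)
    weight = np.asarray(weights_source, dtype=float).mean(axis=0)  # replicability

    diff_p = np.empty(n_rep)
    diff_awf = np.empty(n_rep)
    for r in range(n_rep):
        s_lat = rng.choice(lat, size=n_lat, replace=False)
        s_non = rng.choice(non, size=n_non, replace=False)
        diff_p[r] = p_conn[s_lat].mean() - p_conn[s_non].mean()
        w_lat, w_non = weight[s_lat], weight[s_non]
        diff_awf[r] = (
            np.average(awf_voxel_mean[s_lat], weights=w_lat)
            - np.average(awf_voxel_mean[s_non], weights=w_non)
        )
    return diff_p, diff_awf


# --------------------------------------------------------------------------
# Dominance
# --------------------------------------------------------------------------


def dominance(left_act: np.ndarray, right_act: np.ndarray) -> np.ndarray:
    """Hemispheric dominance in radians: ``arctan(right/left) - pi/4``.

    Inputs must be nonnegative activation strengths; voxels where both are
    zero are undefined and returned as NaN (logged).  0 means bilateral,
    +pi/4 unilateral right, -pi/4 unilateral left.
    """
    left = np.asarray(left_act, dtype=float)
    right = np.asarray(right_act, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("activation strengths must be nonnegative")
    both_zero = (left == 0) & (right == 0)
    if np.any(both_zero):
        logger.info("dominance undefined at %d voxels (both activations zero)",
                    int(np.sum(both_zero)))
    with np.errstate(invalid="ignore"):
        d = np.arctan2(right, left) - np.pi / 4.0
    return np.where(both_zero, np.nan, d)


def assign_voxel_dominance(
    z_maps: np.ndarray,
    left_strength: np.ndarray,
    right_strength: np.ndarray,
    significant_mask: np.ndarray,
) -> DominanceMap:
    """Per-voxel dominance from the component with the largest |z|.

    ``z_maps`` and the strength maps are components x voxels;
    ``significant_mask`` flags voxels covered by at least one significant
    component.  Ties in |z| resolve to the lowest component index
    (np.argmax).  Negative strengths are clamped to zero before the
    arctangent.
    """
    z = np.asarray(z_maps, dtype=float)
    mask = np.asarray(significant_mask, dtype=bool)
    comp = np.argmax(np.abs(z), axis=0)
    cols = np.arange(z.shape[1])
    left = np.clip(np.asarray(left_strength, dtype=float)[comp, cols], 0.0, None)
    right = np.clip(np.asarray(right_strength, dtype=float)[comp, cols], 0.0, None)
    dom = dominance(left, right)
    dom = np.where(mask, dom, np.nan)
    return DominanceMap(
        dominance=dom,
        component_id=np.where(mask, comp, -1),
        mean_activity=(left + right) / 2.0,
    )


# --------------------------------------------------------------------------
# Binning and correlation
# --------------------------------------------------------------------------


def bin_edges_by_probability(n_subjects: int, n_bins: int = 8) -> np.ndarray:
    """Log-spaced bin edges over (0, 1] whose first width is 1/n_subjects.

    Edges are geometric with the lowest edge solved so that the smallest
    (first) bin width equals exactly ``1/n_subjects``; widths then
    increase strictly with the probability of connection.  The edge count
    is the free variable of the construction: if ``n_bins`` bins cannot be
    made that narrow (small samples), the bin count is reduced to the
    largest feasible value.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    target = 1.0 / n_subjects

    def first_width(log_e0: float, b: int) -> float:
        e0 = 10.0**log_e0
        return e0 * (e0 ** (-1.0 / b) - 1.0) - target

    # the first width e0^((b-1)/b) - e0 peaks at e0* = ((b-1)/b)^b; take the
    # small-edge root so the edges span (0, 1] rather than a sliver near 1
    while n_bins >= 2:
        e0_star = ((n_bins - 1) / n_bins) ** n_bins
        if first_width(np.log10(e0_star), n_bins) >= 0:
            break
        n_bins -= 1
    else:
        raise ValueError(f"no log-spaced binning has a first width of 1/{n_subjects}")
    log_e0 = optimize.brentq(first_width, -12.0, np.log10(e0_star), args=(n_bins,))
    e0 = 10.0**log_e0
    return np.geomspace(e0, 1.0, n_bins + 1)


def bin_by_probability(p_values: np.ndarray, n_subjects: int, n_bins: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Assign connection probabilities to log-spaced bins.

    Returns ``(assignments, edges)``; values at or below the lowest edge
    fall into the first bin, so every voxel is assigned.  Empty bins are
    simply unused downstream.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = bin_edges_by_probability(n_subjects, n_bins=n_bins)
    idx = np.clip(np.searchsorted(edges, p, side="left") - 1, 0, len(edges) - 2)
    return idx, edges


def dominance_connectivity_correlation(
    dominance_values: np.ndarray,
    p_conn: np.ndarray,
    bins: np.ndarray,
    covariate: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation of bin-mean |dominance| with bin-mean p_conn.

    With a covariate, both binned variables are residualised on the
    bin-mean covariate and the residuals correlated (partial correlation).
    Returns ``(r, p_value, n_bins_used)``; requires at least 3 populated
    bins.
    """
    mag = np.abs(np.asarray(dominance_values, dtype=float))
    ok = ~np.isnan(mag)
    mag, p, b = mag[ok], np.asarray(p_conn, float)[ok], np.asarray(bins)[ok]
    if covariate is not None:
        cov = np.asarray(covariate, float)[ok]
    labels = np.unique(b)
    x = np.array([p[b == lab].mean() for lab in labels])
    y = np.array([mag[b == lab].mean() for lab in labels])
    if labels.size < 3:
        raise ValueError(f"need at least 3 populated bins, got {labels.size}")
    if covariate is not None:
        c = np.array([cov[b == lab].mean() for lab in labels])
        X = np.column_stack([np.ones_like(c), c])
        x = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    r, pval = stats.pearsonr(y, x)
    return float(r), float(pval), int(labels.size)


def distance_control(
    pools: dict,
    p_conn: np.ndarray,
    awf: np.ndarray | None,
    midline_distance: np.ndarray,
) -> dict:
    """Does the lateralised-vs-non-lateralised difference track midline distance?

    Each lateralised voxel is paired with the non-lateralised voxel of
    matching rank in distance to the interhemispheric plane; the per-pair
    connectivity difference is correlated with the lateralised voxel's
    distance.  Returns Pearson r and p for the connection-probability
    difference (and the AWF difference when ``awf`` is given).
    """
    lat = np.asarray(pools["lateralised"], dtype=int)
    non = np.asarray(pools["nonlateralised"], dtype=int)
    if lat.size < 3 or non.size < 3:
        raise ValueError("pools too small for the distance control")
    dist = np.asarray(midline_distance, dtype=float)
    if np.ptp(dist[lat]) == 0:
        raise ValueError("all lateralised voxels are equidistant from the midline")
    lat_order = lat[np.argsort(dist[lat], kind="stable")]
    non_order = non[np.argsort(dist[non], kind="stable")]
    # rank-match: i-th closest lateralised voxel vs quantile-matched non-lateralised
    match = non_order[
        np.round(np.linspace(0, non.size - 1, lat.size)).astype(int)
    ]
    d_lat = dist[lat_order]
    diff_p = p_conn[lat_order] - p_conn[match]
    r_p, p_p = stats.pearsonr(d_lat, diff_p)
    out = {"p_conn": {"r": float(r_p), "p": float(p_p)}, "n_pairs": int(lat.size)}
    if awf is not None:
        awf_mean = np.asarray(awf, float).mean(axis=0)
        diff_a = awf_mean[lat_order] - awf_mean[match]
        r_a, p_a = stats.pearsonr(d_lat, diff_a)
        out["awf"] = {"r": float(r_a), "p": float(p_a)}
    return out


# --------------------------------------------------------------------------
# Component hemisphere strengths (inputs to dominance assignment)
# --------------------------------------------------------------------------


def raw_hemisphere_strengths(
    left_matrix: np.ndarray, right_matrix: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Raw-value activation strengths: across-term mean per hemisphere.

    The alternative to component-level strengths for the dominance
    arctangent; the same mean map is shared by all components (tiled to
    components x voxels so it plugs into :func:`assign_voxel_dominance`).
    Negative means are clamped to zero.
    """
    lm = np.clip(np.asarray(left_matrix, float).mean(axis=0), 0.0, None)
    rm = np.clip(np.asarray(right_matrix, float).mean(axis=0), 0.0, None)
    return np.tile(lm, (n_components, 1)), np.tile(rm, (n_components, 1))


def component_hemisphere_strengths(
    left_matrix: np.ndarray, right_matrix: np.ndarray, rotated_loadings: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component left/right activation strength maps.

    Fits the voxelwise GLM of each hemisphere's (smoothed, homologously
    indexed) activation matrix on the rotated component loadings; the
    component betas are the hemisphere activation strengths entering the
    dominance arctangent.
    """
    from .components import spatial_maps_glm

    bl, _, _ = spatial_maps_glm(left_matrix, rotated_loadings, with_z=False)
    br, _, _ = spatial_maps_glm(right_matrix, rotated_loadings, with_z=False)
    return bl, br
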