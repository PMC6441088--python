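"""End-to-end synthetic pipeline orchestration and reporting.

``run_pipeline`` executes simulate -> LI maps -> components + significance
-> embedding -> triangularity/archetypes -> connectivity on a synthetic
dataset and writes a JSON (+ HTML) report carrying every statistic, the
parameters, and the child seeds.  The report's ``statistics`` block is
serialised deterministically, so identical ``(config, seed)`` runs are
byte-identical there.
"""

from __future__ import annotations

import json
import logging
import time
from fractions import Fraction
from pathlib import Path

import numpy as np

from . import connectivity as conn_mod
from ._seeds import child_int_seed
from .components import fit_component_model, permutation_significance
from .config import PipelineConfig
from .embedding import embed_li_matrix
from .grid import make_symmetric_grid
from .li import hemisphere_matrices
from .pareto import archetype_maps, t_ratio_null_test
from .synthetic import generate_connectivity, generate_term_maps

logger = logging.getLogger(__name__)


def agreement_rate(n_total: int, n_agree_include: int, n_agree_exclude: int) -> tuple[int, float]:
    """Inter-judge agreement: percentage of items with concordant decisions.

    Returns ``(percent, fraction)`` where ``percent`` is rounded to the
    nearest integer and ``fraction`` is the exact ratio
    ``(n_agree_include + n_agree_exclude) / n_total``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    agree = n_agree_include + n_agree_exclude
    if agree > n_total:
        raise ValueError("agreement counts exceed the total")
    frac = Fraction(agree, n_total)
    return int(round(100 * float(frac))), float(frac)


REPORT_SCHEMA = {
    "config": dict,
    "seeds": dict,
    "statistics": dict,
    "runtime_s": dict,
}

_STAT_KEYS = {
    "n_retained": int,
    "variance_explained": float,
    "n_significant_components": int,
    "n_lateralised_voxels": int,
    "n_nonlateralised_voxels": int,
    "pareto": list,
    "connectivity": dict,
}


def validate_report(report: dict) -> None:
    """Raise if the report does not match the expected schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report or not isinstance(report[key], typ):
            raise ValueError(f"report missing or mistyped field {key!r}")
    for key, typ in _STAT_KEYS.items():
        if key not in report["statistics"] or not isinstance(report["statistics"][key], typ):
            raise ValueError(f"report statistics missing or mistyped field {key!r}")


def statistics_bytes(report: dict) -> bytes:
    """Deterministic serialisation of the statistics block."""
    return json.dumps(report["statistics"], sort_keys=True).encode()


def _html_report(report: dict) -> str:
    rows = json.dumps(report["statistics"], sort_keys=True, indent=2)
    return (
        "<html><head><title>latmorph pipeline report</title></head><body>"
        "<h1>Lateralisation pipeline report</h1>"
        f"<pre>{rows}</pre></body></html>"
    )


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run the full synthetic pipeline and return the report dict."""
    t0 = time.perf_counter()
    runtime: dict[str, float] = {}
    seed = config.seed
    seeds = {
        "master": seed,
        "permutation": child_int_seed(seed, "permutation"),
        "pareto_null": child_int_seed(seed, "pareto_null"),
        "pool_sampling": child_int_seed(seed, "pool_sampling"),
    }

    # -- simulate ----------------------------------------------------------
    grid = make_symmetric_grid(
        config.grid_shape, config.mask_kind, voxel_size_mm=config.voxel_size_mm
    )
    term_set, truth = generate_term_maps(
        grid, config.n_terms, config.n_archetypes, config.noise_sd, seed=seed
    )
    runtime["simulate"] = time.perf_counter() - t0

    # -- LI maps -----------------------------------------------------------
    t = time.perf_counter()
    left_m, right_m = hemisphere_matrices(term_set.volumes, grid, config.fwhm_mm)
    li = right_m - left_m
    runtime["li"] = time.perf_counter() - t

    # -- components + significance -----------------------------------------
    t = time.perf_counter()
    model = fit_component_model(li, terms=term_set.terms)
    sig = permutation_significance(
        li, model, grid,
        n_perm=config.n_perm, alpha=config.alpha, cluster_min=config.cluster_min,
        connectivity=config.cluster_connectivity, seed=seeds["permutation"],
        statistic=config.statistic,
    )
    lateralised = sig.any_mask
    n_sig_comp = int(np.sum([(sig.pos[k] | sig.neg[k]).any() for k in range(sig.pos.shape[0])]))
    runtime["components"] = time.perf_counter() - t

    # -- embedding + triangularity + archetypes -----------------------------
    t = time.perf_counter()
    pareto_results = t_ratio_null_test(
        left_m, right_m, n_retained=model.n_retained,
        n_sets=config.n_null_sets, alpha=config.pareto_alpha,
        seed=seeds["pareto_null"], n_dims=config.n_dims,
    )
    _, space = embed_li_matrix(li, model, n_dims=config.n_dims)
    first = pareto_results[0]
    from .embedding import denoise_maps

    den = denoise_maps(li, model)
    archetypes = archetype_maps(
        den, space.coords, first.triangle_vertices,
        n_regress_dims=config.n_dims, subspace=first.subspace,
    )
    runtime["pareto"] = time.perf_counter() - t

    # -- connectivity -------------------------------------------------------
    t = time.perf_counter()
    stats_conn: dict = {}
    try:
        nonlat, _ = conn_mod.nonlateralised_mask(
            term_set.volumes, lateralised, grid,
            fwhm_mm=config.fwhm_mm, n_perm=config.n_perm, alpha=config.alpha,
            cluster_min=config.cluster_min, connectivity=config.cluster_connectivity,
            seed=seeds["permutation"], statistic=config.statistic,
        )
    except ValueError as exc:
        raise RuntimeError(f"pipeline stage 'connectivity' failed: {exc}") from exc

    dom_field = np.where(lateralised, truth.dominance_field, np.nan)
    subj = generate_connectivity(
        grid, dom_field, awf_offset=config.awf_offset,
        n_subjects=config.n_subjects, seed=seed,
    )
    p_conn = conn_mod.probability_of_connection(subj)
    pools = {
        "lateralised": np.flatnonzero(lateralised),
        "nonlateralised": np.flatnonzero(nonlat),
    }
    diff_p, diff_awf = conn_mod.sample_difference_distribution(
        pools, p_conn, subj.awf, subj.indicator,
        frac=config.frac, n_rep=config.n_rep, seed=seeds["pool_sampling"],
    )
    bins, _ = conn_mod.bin_by_probability(p_conn, config.n_subjects, n_bins=config.n_bins)

    strengths = conn_mod.component_hemisphere_strengths(left_m, right_m, model.loadings_rotated)
    dom_map = conn_mod.assign_voxel_dominance(model.z_maps, *strengths, lateralised)
    lat_idx = pools["lateralised"]
    r_bin, p_bin, n_bins_used = conn_mod.dominance_connectivity_correlation(
        dom_map.dominance[lat_idx], p_conn[lat_idx], bins[lat_idx]
    )
    r_part, p_part, _ = conn_mod.dominance_connectivity_correlation(
        dom_map.dominance[lat_idx], p_conn[lat_idx], bins[lat_idx],
        covariate=dom_map.mean_activity[lat_idx],
    )
    dist = conn_mod.distance_control(pools, p_conn, subj.awf, grid.midline_distance_mm())
    stats_conn = {
        "diff_p_conn_mean": float(diff_p.mean()),
        "diff_p_conn_sd": float(diff_p.std(ddof=1)),
        "diff_awf_mean": float(diff_awf.mean()),
        "diff_awf_sd": float(diff_awf.std(ddof=1)),
        "binned_dominance_r": r_bin,
        "binned_dominance_r_partial": r_part,
        "n_bins_used": n_bins_used,
        "distance_control_r": dist["p_conn"]["r"],
    }
    runtime["connectivity"] = time.perf_counter() - t

    report = {
        "config": config.as_dict(),
        "seeds": seeds,
        "statistics": {
            "n_retained": int(model.n_retained),
            "variance_explained": float(model.variance_explained),
            "n_significant_components": n_sig_comp,
            "n_lateralised_voxels": int(lateralised.sum()),
            "n_nonlateralised_voxels": int(nonlat.sum()),
            "pareto": [
                {
                    "subspace": list(r.subspace),
                    "t_ratio": float(r.t_ratio),
                    "p_value": float(r.p_value),
                    "significant": bool(r.significant),
                }
                for r in pareto_results
            ],
            "n_archetypes": len(archetypes),
            "connectivity": stats_conn,
        },
        "runtime_s": {k: round(v, 3) for k, v in runtime.items()},
    }
    validate_report(report)

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
        (out / "report.html").write_text(_html_report(report))
        config.to_yaml(out / "config.yaml")
    return report
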