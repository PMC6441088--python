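#!/usr/bin/env python
"""Spectral morphospace of the LI maps and its triangularity (Pareto) test.

Denoises maps through the component model, embeds them by the normalised
graph Laplacian of their similarity matrix, tests the t-ratio of every 2-D
subspace against voxel-permutation nulls (Bonferroni-corrected), and
reconstructs archetype maps at the minimal enclosing triangle's vertices.
Writes the t-ratio table, embedding coordinates, archetype maps, and a
scatter plot under results/.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from latmorph import archetype_maps, fit_component_model, t_ratio_null_test
from latmorph import io as lio
from latmorph.embedding import denoise_maps, embed_li_matrix
from latmorph.li import hemisphere_matrices

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-null-sets", type=int, default=200)
    ap.add_argument("--n-dims", type=int, default=5)
    args = ap.parse_args()

    term_set = lio.read_volumes(ROOT / "results" / "data" / "volumes")
    grid = term_set.grid
    left, right = hemisphere_matrices(term_set.volumes, grid, 0.0)
    li = right - left
    model = fit_component_model(li, terms=term_set.terms)

    results = t_ratio_null_test(
        left, right, n_retained=model.n_retained, n_sets=args.n_null_sets,
        alpha=0.05, seed=args.seed, n_dims=args.n_dims,
    )
    den = denoise_maps(li, model)
    _, space = embed_li_matrix(li, model, n_dims=args.n_dims)

    out = ROOT / "results"
    table = pd.DataFrame([
        {"dim_a": r.subspace[0], "dim_b": r.subspace[1], "t_ratio": r.t_ratio,
         "p_value": r.p_value, "significant": r.significant}
        for r in results
    ])
    table.to_csv(out / "t_ratio_table.csv", index=False)
    pd.DataFrame(space.coords, index=term_set.terms).to_csv(out / "embedding_coords.csv")

    first = results[0]
    arch = archetype_maps(den, space.coords, first.triangle_vertices,
                          n_regress_dims=args.n_dims, subspace=first.subspace)
    arch_mat = np.stack([a.predicted_li for a in arch])
    lio.write_li_maps(arch_mat, [a.label for a in arch], grid, out / "archetype_maps")

    fig, ax = plt.subplots(figsize=(5, 5))
    pts = space.coords[:, first.subspace]
    ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.7)
    tri = np.vstack([first.triangle_vertices, first.triangle_vertices[:1]])
    ax.plot(tri[:, 0], tri[:, 1], "r-", lw=1)
    ax.set_xlabel(f"dimension {first.subspace[0] + 1}")
    ax.set_ylabel(f"dimension {first.subspace[1] + 1}")
    ax.set_title(f"morphospace, t-ratio {first.t_ratio:.3f} (p = {first.p_value:.4f})")
    fig.tight_layout()
    fig.savefig(out / "morphospace.svg")

    n_sig = int(table["significant"].sum())
    print(f"first subspace t-ratio {first.t_ratio:.3f}, p = {first.p_value:.4f} "
          f"vs {args.n_null_sets} voxel-permutation null sets")
    print(f"{n_sig}/{len(results)} subspaces significant after Bonferroni")
    print(f"wrote {len(arch)} archetype maps and {out / 'morphospace.svg'}")


if __name__ == "__main__":
    main()
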