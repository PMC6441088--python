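"""NIfTI / CSV / JSON input-output for the pipeline's data objects.

Volumes are written one NIfTI file per term with a JSON manifest mapping
term labels to filenames and recording the grid; LI maps are stored as
half-volumes embedded in a full-grid NIfTI with the unused hemisphere
zero-filled, plus a JSON sidecar recording the sign convention.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridSpec, make_symmetric_grid
from .synthetic import PlantedTruth, SubjectConnectivity, TermMapSet

MANIFEST_NAME = "manifest.json"


def _slug(term: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", term).strip("_") or "term"


def _grid_meta(grid: GridSpec) -> dict:
    return {
        "shape": list(grid.shape),
        "mirror_axis": grid.mirror_axis,
        "voxel_size_mm": grid.voxel_size_mm,
        "mask_voxels": int(grid.mask.sum()),
    }


def _grid_from_meta(meta: dict, mask: np.ndarray) -> GridSpec:
    return GridSpec(
        shape=tuple(meta["shape"]),
        mirror_axis=int(meta["mirror_axis"]),
        mask=mask,
        voxel_size_mm=float(meta["voxel_size_mm"]),
    )


def write_volumes(term_set: TermMapSet, out_dir: str | Path) -> Path:
    """Write one NIfTI per term plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = term_set.grid
    affine = grid.affine()
    entries = {}
    for term, vol in zip(term_set.terms, term_set.volumes):
        fname = f"{_slug(term)}.nii"
        if fname in entries.values():
            raise ValueError(f"manifest label collision for term {term!r} -> {fname}")
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), out / fname)
        entries[term] = fname
    nib.save(nib.Nifti1Image(grid.mask.astype(np.uint8), affine), out / "mask.nii")
    manifest = {"grid": _grid_meta(grid), "terms": entries, "mask_file": "mask.nii"}
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out / MANIFEST_NAME


def read_volumes(in_dir: str | Path) -> TermMapSet:
    """Read a term-map directory written by :func:`write_volumes`."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    mask_img = nib.load(in_dir / manifest["mask_file"])
    mask = np.asarray(mask_img.dataobj).astype(bool)
    grid = _grid_from_meta(manifest["grid"], mask)
    ref_affine = None
    terms, vols = [], []
    for term, fname in sorted(manifest["terms"].items()):
        img = nib.load(in_dir / fname)
        data = np.asarray(img.dataobj, dtype=float)
        if data.shape != grid.shape:
            raise ValueError(f"volume {fname} has shape {data.shape}, expected {grid.shape}")
        if ref_affine is None:
            ref_affine = img.affine
        elif not np.allclose(img.affine, ref_affine):
            raise ValueError(f"volume {fname} has a mismatched affine")
        terms.append(term)
        vols.append(data)
    return TermMapSet(volumes=np.stack(vols), terms=terms, grid=grid)


def write_li_maps(li_mat: np.ndarray, terms: list[str], grid: GridSpec, out_dir: str | Path) -> Path:
    """Write LI half-maps embedded in full-grid NIfTIs (left hemisphere zeroed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = grid.affine()
    entries = {}
    for term, vec in zip(terms, li_mat):
        half = grid.vector_to_half(vec)
        full = grid.assemble(np.zeros(grid.half_shape), half)
        fname = f"li_{_slug(term)}.nii"
        nib.save(nib.Nifti1Image(full.astype(np.float32), affine), out / fname)
        entries[term] = fname
    nib.save(nib.Nifti1Image(grid.mask.astype(np.uint8), affine), out / "mask.nii")
    sidecar = {
        "grid": _grid_meta(grid),
        "terms": entries,
        "mask_file": "mask.nii",
        "convention": "half-grid LI stored in the right hemisphere; positive = right-lateralised",
    }
    (out / "li_manifest.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out / "li_manifest.json"


def read_li_maps(in_dir: str | Path) -> tuple[np.ndarray, list[str], GridSpec]:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "li_manifest.json").read_text())
    mask = np.asarray(nib.load(in_dir / sidecar["mask_file"]).dataobj).astype(bool)
    grid = _grid_from_meta(sidecar["grid"], mask)
    terms, rows = [], []
    for term, fname in sorted(sidecar["terms"].items()):
        full = np.asarray(nib.load(in_dir / fname).dataobj, dtype=float)
        rows.append(grid.half_to_vector(grid.right_half(full)))
        terms.append(term)
    return np.stack(rows), terms, grid


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """PlantedTruth as a compressed npz with a JSON sidecar."""
    path = Path(path)
    arrays = {
        "archetype_patterns": truth.archetype_patterns,
        "archetype_coords": truth.archetype_coords,
        "term_weights": truth.term_weights,
        "dominance_field": truth.dominance_field,
    }
    np.savez_compressed(path, **{k: v for k, v in arrays.items() if v is not None})
    sidecar = {
        "conn_slope": truth.conn_slope,
        "awf_offset": truth.awf_offset,
        "arrays": sorted(k for k, v in arrays.items() if v is not None),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> PlantedTruth:
    path = Path(path)
    data = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return PlantedTruth(
        archetype_patterns=data.get("archetype_patterns"),
        archetype_coords=data.get("archetype_coords"),
        term_weights=data.get("term_weights"),
        dominance_field=data.get("dominance_field"),
        conn_slope=sidecar.get("conn_slope"),
        awf_offset=sidecar.get("awf_offset"),
    )


def write_connectivity(conn: SubjectConnectivity, out_dir: str | Path) -> None:
    """Indicator stack as CSV-backed table plus AWF table (voxels as columns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(conn.indicator).to_csv(out / "indicator.csv", index_label="subject")
    pd.DataFrame(conn.awf).to_csv(out / "awf.csv", index_label="subject")
    (out / "connectivity.json").write_text(
        json.dumps({"n_subjects": conn.n_subjects}, indent=2)
    )


def read_connectivity(in_dir: str | Path) -> SubjectConnectivity:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "connectivity.json").read_text())
    ind = pd.read_csv(in_dir / "indicator.csv", index_col="subject").to_numpy(dtype=np.uint8)
    awf = pd.read_csv(in_dir / "awf.csv", index_col="subject").to_numpy(dtype=float)
    return SubjectConnectivity(n_subjects=int(meta["n_subjects"]), indicator=ind, awf=awf)
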