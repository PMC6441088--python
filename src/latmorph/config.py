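"""Pipeline configuration: a flat, YAML-round-trippable parameter record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable parameters of the synthetic end-to-end pipeline.

    Defaults are the desk-scale study conditions; every stage echoes its
    parameters into the report for provenance.
    """

    # grid
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    mask_kind: str = "ellipsoid"
    voxel_size_mm: float = 2.0
    # synthetic data
    n_terms: int = 60
    n_archetypes: int = 3
    noise_sd: float = 0.1
    # LI maps
    fwhm_mm: float = 0.0
    # components / significance
    n_perm: int = 500
    alpha: float = 0.05
    cluster_min: int = 20
    cluster_connectivity: int = 26
    statistic: str = "z"  # map statistic entering the maximal-statistic test
    # embedding / pareto
    n_dims: int = 5
    n_null_sets: int = 200
    pareto_alpha: float = 0.05
    # connectivity
    n_subjects: int = 163
    awf_offset: float = -0.05
    frac: float = 0.05
    n_rep: int = 1000
    n_bins: int = 8
    # bookkeeping
    seed: int = 0
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.n_terms < 3 * self.n_archetypes:
            raise ValueError("n_terms must be at least 3 * n_archetypes")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d
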