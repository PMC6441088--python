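"""Shared fixtures: small symmetric grids and a planted-archetype dataset.

Expensive objects are session-scoped so the suite computes them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from latmorph import fit_component_model, make_symmetric_grid
from latmorph.li import hemisphere_matrices
from latmorph.synthetic import generate_term_maps


@pytest.fixture(scope="session")
def box_grid():
    return make_symmetric_grid((12, 12, 12), "box")


@pytest.fixture(scope="session")
def ellipsoid_grid():
    return make_symmetric_grid((14, 12, 12), "ellipsoid")


@pytest.fixture(scope="session")
def planted(box_grid):
    """60-term, 3-archetype dataset at the study noise level, plus its
    hemisphere matrices, LI matrix and fitted component model."""
    term_set, truth = generate_term_maps(box_grid, 60, 3, noise_sd=0.1, seed=1)
    left, right = hemisphere_matrices(term_set.volumes, box_grid, 0.0)
    li = right - left
    model = fit_component_model(li, terms=term_set.terms)
    return {
        "grid": box_grid,
        "term_set": term_set,
        "truth": truth,
        "left": left,
        "right": right,
        "li": li,
        "model": model,
    }
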