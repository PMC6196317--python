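"""Shared fixtures: compact stimulus designs and a default HRF.

Unit tests run on scaled-down movies (coarse grids, few cycles) so the whole
suite stays fast; full-scale designs are exercised in test_acceptance.py.
"""

import numpy as np
import pytest

from prfmap import (
    DEFAULT_HRF,
    SearchGrid,
    make_ring_movie,
    make_wedge_movie,
)


@pytest.fixture(scope="session")
def hrf():
    return DEFAULT_HRF


@pytest.fixture(scope="session")
def small_movie():
    """Compact wedge+ring mapping movie on a 9-degree field (36 frames)."""
    wedge = make_wedge_movie(width_deg=36, step_deg=18, n_cycles=1,
                             fov_radius_deg=9.0, grid_n=25)
    ring = make_ring_movie(n_steps=8, n_reps=2, fov_radius_deg=9.0,
                           inner_radius_deg=0.28, grid_n=25)
    return wedge.concat(ring)


@pytest.fixture(scope="session")
def small_grid():
    return SearchGrid.default(9.0, n_angles=8, n_ecc=6, n_sigma=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
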