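"""Shared fixtures: small phantoms and their pipeline intermediates.

Unit tests run on 320-px phantoms (fast); the acceptance suite uses the
full 640-px default where cohort statistics matter.
"""

import numpy as np
import pytest

import ropscreen as rs


@pytest.fixture(scope="session")
def straight_phantom():
    """Default-parameter phantom with four straight radial trunks."""
    params = rs.PhantomParams(image_size=320, seed=5, n_trunks=4,
                              tortuosity_amp=0.0)
    image, truth = rs.generate_phantom(params)
    return params, image, truth


@pytest.fixture(scope="session")
def tortuous_phantom():
    """Small phantom with curved, branching vessels."""
    params = rs.PhantomParams(image_size=320, seed=3, tortuosity_amp=4.0,
                              branch_prob=0.02, vascular_extent=4.0)
    image, truth = rs.generate_phantom(params, label="aprop")
    return params, image, truth


@pytest.fixture(scope="session")
def tortuous_result(tortuous_phantom):
    """Full morphology-pipeline intermediates for the tortuous phantom."""
    _, image, truth = tortuous_phantom
    return rs.process_image(image, truth.od_geometry, rs.RunConfig()), truth


def centerline_raster(truth, shape):
    """Rasterize analytic centerlines onto a boolean canvas."""
    canvas = np.zeros(shape, dtype=bool)
    for pl in truth.centerlines:
        ij = np.round(pl).astype(int)
        ok = ((ij[:, 0] >= 0) & (ij[:, 0] < shape[0])
              & (ij[:, 1] >= 0) & (ij[:, 1] < shape[1]))
        canvas[ij[ok, 0], ij[ok, 1]] = True
    return canvas
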