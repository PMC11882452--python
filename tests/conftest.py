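import math

import numpy as np
import pytest

from patchnet import (Configuration, ModelParams, Particle,
                      make_compact_island)


@pytest.fixture(scope="session")
def kf_params():
    """Classical Kern-Frenkel parameters (no angular-entropy compensation),
    the textbook convention the pair-potential contracts are written in."""
    return ModelParams(epsilon=8.0, normalize_patch_entropy=False,
                       box_side=20.0, n_particles=2)


@pytest.fixture(scope="session")
def flower():
    """24-particle honeycomb flower (7 hexagons), in nm."""
    return make_compact_island(n_rings=2, seed=0)


def ideal_ring(params: ModelParams, r_bond: float = None) -> Configuration:
    """Ideal 6-ring of bonded particles with all arms closed and aligned."""
    if r_bond is None:
        r_bond = params.sigma + params.delta / 2.0
    centre = params.box_side / 2.0
    ring_r = r_bond  # hexagon side equals circumradius
    parts = []
    for k in range(6):
        a = k * math.pi / 3.0
        x = centre + ring_r * math.cos(a)
        y = centre + ring_r * math.sin(a)
        # patch 0 points toward the next ring member (tangentially)
        orientation = a + 2.0 * math.pi / 3.0
        parts.append(Particle(x, y, orientation, (1, 1, 1)))
    return Configuration.from_particles(parts, params.box_side)


@pytest.fixture(scope="session")
def six_ring_config():
    params = ModelParams(epsilon=6.0, normalize_patch_entropy=False,
                         box_side=12.0, n_particles=6)
    return params, ideal_ring(params)
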