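import numpy as np
import pytest

import fgmem as fg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def icosahedron():
    return fg.build_icosphere(1)


@pytest.fixture
def tetrahedron():
    return fg.build_tetrahedron()


@pytest.fixture
def icosphere4(rng):
    surf = fg.build_icosphere(4)
    fg.assign_sigma_random(surf, 0.7, rng)
    return surf


@pytest.fixture
def params_model2():
    return fg.ModelParams(lambda_=0.5, kappa=10.0, c=8.37, phi0=0.8,
                          variant=fg.MODEL2)


@pytest.fixture
def params_model1():
    return fg.ModelParams(lambda_=0.2, kappa=7.0, c=5.0, phi0=0.7,
                          variant=fg.MODEL1)


def jiggled(surface, rng, scale=0.05):
    """Randomly perturb vertex positions (keeps topology, breaks symmetry)."""
    surf = surface.copy()
    surf.pos += scale * rng.standard_normal(surf.pos.shape)
    return surf
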