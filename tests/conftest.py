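import logging

import numpy as np
import pytest

import gbmsim
from gbmsim.tensor_fields import (
    preferential_directions,
    sample_to_mesh,
    synthetic_isotropic,
)

# Invariant-violation warnings are expected in a few stress tests; keep the
# test log quiet but allow caplog-based assertions.
logging.getLogger("gbmsim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def params():
    """Reference parameter set (the full-run values)."""
    return gbmsim.ModelParameters()


@pytest.fixture(scope="session")
def sensitivity_params():
    """Parameter values of the sensitivity studies (nu = 1, delta_n = 8640)."""
    return gbmsim.ModelParameters(nu_c=1.0, delta_c=0.3, n_s=0.07,
                                  D_n=86.4, E=694.0, phi_e=0.389,
                                  S_n=1.0e4, delta_n=8640.0, chi=900.0)


@pytest.fixture(scope="session")
def small_mesh():
    """Centered 10 mm cube at 4^3 hex resolution (384 tets)."""
    return gbmsim.box_mesh((10.0, 10.0, 10.0), (4, 4, 4), origin=(-5.0, -5.0, -5.0))


def centered_box(extent: float, res: int) -> "gbmsim.Mesh":
    return gbmsim.box_mesh((extent,) * 3, (res,) * 3, origin=(-extent / 2.0,) * 3)


def isotropic_cell_field(mesh, res: int, D_n: float):
    """Uniform isotropic (D, T) sampled onto the mesh cells."""
    lo, hi = mesh.bounding_box()
    spacing = (hi - lo) / res
    field = synthetic_isotropic((res,) * 3, D_n, spacing=spacing,
                                origin=lo + spacing / 2.0)
    D = sample_to_mesh(field, mesh)
    return D, preferential_directions(D)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
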