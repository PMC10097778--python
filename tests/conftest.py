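"""Shared fixtures: small meshes and cached solver runs.

Expensive objects are session-scoped; the `small` family uses a shortened
cell (30 um body, 12 um diameter) that keeps every property of the full
geometry — stub, shoulder, thin sheet pad, thick normal pad — at a
fraction of the dof count.
"""

import warnings

import numpy as np
import pytest

from emimech.fem import TaylorHoodSpace
from emimech.geometry import (CellGeometrySpec, build_single_cell_mesh,
                              build_tiled_mesh)
from emimech.materials import MaterialParams

warnings.filterwarnings("ignore", message="overflow")


@pytest.fixture(scope="session")
def default_spec():
    return CellGeometrySpec()


@pytest.fixture(scope="session")
def small_spec():
    return CellGeometrySpec(body_length=30.0, diameter=12.0,
                            fillet_radius=6.0)


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return build_single_cell_mesh(small_spec, 20.0)


@pytest.fixture(scope="session")
def small_space(small_mesh):
    return TaylorHoodSpace(small_mesh)


@pytest.fixture(scope="session")
def small_pair_mesh(small_spec):
    return build_tiled_mesh(small_spec, 2, 1, 1, 20.0)


@pytest.fixture(scope="session")
def table3_params():
    """Averaged fitted material parameters (defaults of MaterialParams)."""
    return MaterialParams()


#: calibration-fixture protocol magnitudes: reduced from the package
#: defaults (10 % / 40 %) to keep the nine-mode virtual experiments in
#: robust, fast territory on the coarse test meshes
CAL_MAGNITUDES = {m: (0.06 if m in ("FF", "SS", "NN") else 0.20)
                  for m in ("FF", "SS", "NN", "FS", "FN", "SF", "SN",
                            "NF", "NS")}
CAL_KAPPA = 25.0


@pytest.fixture(scope="session")
def cal_setup(small_spec):
    """Shared simulator configuration for all calibration tests; the
    cache holds a deliberately coarse mesh and warm-starts repeated
    evaluations."""
    from emimech.geometry import build_single_cell_mesh as build
    mesh = build(small_spec, 20.0, min_side_segments=2)
    return {"spec": small_spec, "resolution": 20.0, "n_steps": 2,
            "space_cache": {"mesh": mesh}, "magnitudes": CAL_MAGNITUDES,
            "stabilization": CAL_KAPPA}


@pytest.fixture(scope="session")
def cal_sample(cal_setup, table3_params):
    """Noiseless nine-mode synthetic experiment from the default
    parameters on the calibration fixture."""
    from emimech.calibrate import generate_synthetic_experiment
    return generate_synthetic_experiment(
        table3_params, noise_sd=0.0, seed=3, **cal_setup)


@pytest.fixture(scope="session")
def affine_isochoric():
    """A volume-preserving uniaxial stretch F = diag(l, 1/sqrt(l), ...)."""
    lam = 1.1
    return np.diag([lam, lam ** -0.5, lam ** -0.5])


def make_affine_state(space, F):
    """A hand-built SolutionState with u(X) = (F - I) X and zero pressure."""
    from emimech.solver import SolutionState
    X = space.p2_coords
    u = X @ F.T - X
    st = SolutionState(u=u, p=np.zeros(space.nv), multipliers=None,
                       step_value=0.0, step_index=0)
    st.space = space
    return st
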