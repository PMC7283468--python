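import numpy as np
import pytest

from mechamigr.geometry import build_cell_mesh, build_substrate_grid
from mechamigr.params import load_params, Condition, Setup


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def stiff_condition():
    return Condition(k_ECM=0.5, r_off_FA0=5e-4)


@pytest.fixture()
def ico1():
    """Small icosphere fixture (42 nodes, 80 triangles)."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_cell_mesh(radius=8e-6, subdivision=1)


@pytest.fixture()
def ico2():
    """Standard test cortex (162 nodes, 320 triangles)."""
    return build_cell_mesh(radius=8e-6, subdivision=2)


@pytest.fixture()
def perturbed_ico1(ico1):
    """ico1 with a reproducible random perturbation of node positions."""
    rng = np.random.default_rng(42)
    ico1.positions = ico1.positions + rng.normal(scale=2e-7,
                                                 size=ico1.positions.shape)
    return ico1


@pytest.fixture(scope="session")
def substrate():
    return build_substrate_grid(40e-6, 20e-6)


@pytest.fixture(scope="session")
def _spread_state_base(params, stiff_condition):
    from mechamigr.engine import initialize_cell
    return initialize_cell(params, stiff_condition, subdivision=2)


@pytest.fixture()
def spread_state(_spread_state_base):
    """Deterministic initialized (attached and spread) cell.

    The expensive initialization runs once per session; each test receives
    an independent copy so in-place mutations cannot leak between tests.
    """
    import copy

    from mechamigr.adhesion import RefractoryState
    from mechamigr.engine import SimState

    base = _spread_state_base
    state = SimState(
        clock=base.clock,
        mesh=base.mesh.copy(),
        substrate=base.substrate,
        field=base.field.copy(),
        labels=copy.deepcopy(base.labels),
        fas=[], refractory=RefractoryState(base.mesh.n_nodes), sfs=[],
        rng=np.random.default_rng(0),
    )
    state._radii = None
    return state
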