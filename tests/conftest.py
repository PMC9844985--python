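import numpy as np
import pytest

from activeshell import ActivityPattern, Parameters
from activeshell.geometry import AxisymShape


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def unit_sphere():
    return AxisymShape.sphere(n=801)


@pytest.fixture(scope="session")
def sphere_nematic(unit_sphere, params):
    from activeshell import solve_nematic

    return solve_nematic(unit_sphere, params.lc)


@pytest.fixture(scope="session")
def zero_pattern():
    return ActivityPattern(mode="step")


# ---------------------------------------------------------------------------
# expensive shared computations, reused by several acceptance checks
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def homogeneous_tube_branch(params):
    """Free-volume branch of homogeneous nematic bending down to zcn=-20."""
    from activeshell import continue_branch

    pattern = ActivityPattern(mode="step", la=np.pi)
    return continue_branch(pattern, params, control="dzeta_cn", target=-20.0,
                           volume_mode="free", max_nodes=20000)


@pytest.fixture(scope="session")
def budding_branch(params):
    """Free-volume isotropic-bending branch at small la/L0, followed to
    neck constriction."""
    from activeshell import continue_branch

    frac = 0.04
    pattern = ActivityPattern(mode="step", la=frac * np.pi)
    branch = continue_branch(pattern, params, control="dzeta_c", target=120.0,
                             volume_mode="free", neck_threshold=1e-3,
                             max_nodes=24000, max_steps=300)
    return frac, branch


@pytest.fixture(scope="session")
def isobend_dynamics(params):
    """Dynamic relaxation at la/L0=0.1, dzeta_c=40, free volume."""
    from activeshell import ActivityPattern, SimConfig, run_simulation

    # dzeta_c = 25 sits below the budding transition of this patch size
    # (two-sphere constriction value ~29.6), where a dynamically stable
    # deformed equilibrium exists
    pattern = ActivityPattern(dzeta_c=25.0, la=0.1 * np.pi, mode="smooth")
    cfg = SimConfig(t_max=2.5, steady_vtol=1e-3, n_grid=400, output_every=500)
    return run_simulation(cfg, pattern, params, volume_mode="free")
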