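import pytest

from smootheffort import (GravityCondition, OcpSpec, PlantParams, solve,
                          trajectory_rtpv)


def frictionless_params(**kw):
    """Plant with no damping and no inertial shift (symmetric test plant)."""
    return PlantParams(damping=0.0, inertial_shift=0.0, **kw)


@pytest.fixture(scope="session")
def default_params():
    return PlantParams()


@pytest.fixture(scope="session")
def traj_1g_up():
    """Reference solve: 1g upward, paper defaults, moderate grid."""
    spec = OcpSpec(cond=GravityCondition(alpha=0.0, direction="upward"),
                   nodes=61)
    return solve(spec)


@pytest.fixture(scope="session")
def traj_0g():
    spec = OcpSpec(cond=GravityCondition(alpha=1.0, direction="upward"),
                   nodes=61)
    return solve(spec)


def rtpv_of(traj):
    return trajectory_rtpv(traj)
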