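"""Shared fixtures: mechanism presets and a few expensive simulations reused
across test modules (session-scoped to keep the suite fast)."""

import numpy as np
import pytest

import uvrkin as uk


@pytest.fixture(scope="session")
def wt():
    """Wild-type apo variant + published parameter set."""
    return uk.variant_preset("wild_type_apo")


@pytest.fixture(scope="session")
def wt_network(wt):
    variant, params = wt
    return uk.build_mechanism(variant, params)


@pytest.fixture(scope="session")
def wt_trace_1mM(wt_network):
    """Noise-free Pi trace, 2 µM dimer + 1 mM ATP, 0-10 s log grid."""
    t = np.concatenate([[0.0], np.geomspace(1e-3, 10.0, 500)])
    cond = uk.ExperimentCondition(enzyme_total=2.0, atp_total=1000.0)
    traj = uk.simulate(wt_network, cond, t)
    return uk.KineticTrace(times=t, signal=traj.cumulative_pi, condition=cond)


@pytest.fixture(scope="session")
def wt_trajectory_30s(wt_network):
    """Noise-free trajectory to 30 s at 2 µM dimer + 1 mM ATP."""
    t = np.concatenate([[0.0], np.geomspace(1e-3, 30.0, 600)])
    cond = uk.ExperimentCondition(enzyme_total=2.0, atp_total=1000.0)
    return uk.simulate(wt_network, cond, t)
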