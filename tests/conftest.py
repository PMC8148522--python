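"""Shared fixtures: synthetic surfaces and cached trajectory ensembles."""

import numpy as np
import pytest

from edchannel import (
    AppliedVoltage,
    SimulationConfig,
    calibrate_detailed_balance,
    make_synthetic_pmf,
    run_ensemble,
)


@pytest.fixture(scope="session")
def flat_surface():
    """Identically-zero PMF (pure free diffusion when ΔV = 0)."""
    z = np.linspace(-15.0, 15.0, 61)
    return make_synthetic_pmf("tabulated", z=z, A=np.zeros_like(z))


@pytest.fixture(scope="session")
def flat_well():
    return make_synthetic_pmf("flat_well")


@pytest.fixture(scope="session")
def central_barrier():
    return make_synthetic_pmf("central_barrier", height=2.0)


@pytest.fixture(scope="session")
def mouth_barriers():
    return make_synthetic_pmf("mouth_barriers")


@pytest.fixture(scope="session")
def tall_barrier():
    return make_synthetic_pmf("tall_barrier", height=7.0)


@pytest.fixture(scope="session")
def barrier_pair_50mv(central_barrier):
    """10^5-trajectory forward/backward pair on the 2 kcal/mol barrier, +50 mV."""
    v = AppliedVoltage.full_window(central_barrier, 50.0)
    sf = run_ensemble(central_barrier, v,
                      SimulationConfig(n_traj=100_000, direction="forward",
                                       seed=101))
    sb = run_ensemble(central_barrier, v,
                      SimulationConfig(n_traj=100_000, direction="backward",
                                       seed=202))
    return central_barrier, v, sf, sb


@pytest.fixture(scope="session")
def barrier_weight(central_barrier):
    """Detailed-balance weight for the 2 kcal/mol barrier surface."""
    return calibrate_detailed_balance(
        central_barrier,
        SimulationConfig(n_traj=100_000, direction="forward", seed=11),
        SimulationConfig(n_traj=100_000, direction="backward", seed=12),
    )


@pytest.fixture(scope="session")
def rare_event_pair():
    """Rare-event regime: zero forward crossings, plentiful backward ones.

    A 5.5 kcal/mol barrier tilted by 300 mV suppresses forward crossings
    to ~10^-7 per injection while backward trajectories ride the field
    over an effective ~2 kcal/mol barrier.
    """
    s = make_synthetic_pmf("tall_barrier", height=5.5)
    v = AppliedVoltage.full_window(s, 300.0)
    sf = run_ensemble(s, v, SimulationConfig(n_traj=100_000,
                                             direction="forward", seed=303))
    sb = run_ensemble(s, v, SimulationConfig(n_traj=100_000,
                                             direction="backward", seed=404))
    return s, v, sf, sb
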