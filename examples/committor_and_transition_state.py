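"""Estimate the committor from trajectories and compare to the closed form.

We inject 10^5 overdamped trajectories from each side of a 2 kcal/mol
central barrier at +50 mV, calibrate the detailed-balance weight w at zero
voltage, and combine both ensembles into the two-sided committor
estimate.  The closed-form splitting probability is the exact answer.
"""

import numpy as np

from edchannel import (
    AppliedVoltage,
    SimulationConfig,
    calibrate_detailed_balance,
    committor_two_sided,
    exact_committor,
    make_synthetic_pmf,
    run_ensemble,
    transition_state,
)

surface = make_synthetic_pmf("central_barrier", height=2.0)
voltage = AppliedVoltage.full_window(surface, 50.0)

forward = run_ensemble(surface, voltage, SimulationConfig(
    n_traj=100_000, direction="forward", seed=1))
backward = run_ensemble(surface, voltage, SimulationConfig(
    n_traj=100_000, direction="backward", seed=2))
weight = calibrate_detailed_balance(
    surface,
    SimulationConfig(n_traj=100_000, direction="forward", seed=3),
    SimulationConfig(n_traj=100_000, direction="backward", seed=4))
print(f"detailed-balance weight w = {weight.w:.4f} ± {weight.sigma:.4f}")

profile = committor_two_sided(forward, backward, weight.w)
exact = np.interp(profile.z, surface.z, exact_committor(surface, voltage))

print("\n    z      P(sim)   P(exact)")
for i in range(0, profile.z.size, 4):
    if profile.valid[i]:
        print(f"{profile.z[i]:6.1f}   {profile.P[i]:.4f}   {exact[i]:.4f}")

sup = np.max(np.abs(profile.P[profile.valid] - exact[profile.valid]))
print(f"\nsup-norm error: {sup:.4f}")
print(f"transition state: simulated {profile.transition_state_z:.2f} Å, "
      f"exact {transition_state(surface, voltage):.2f} Å")
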