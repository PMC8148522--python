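"""A full I-V curve — and a reversal potential — from one simulated voltage.

Statistics collected at a single reference voltage determine the currents
at every other voltage through an exact ratio formula, using the
committor as the weighting profile.  We reconstruct the curve for a
cation on a flat-well channel, compare it to the direct closed-form
solution, then scale the cis-side concentration 5:1 and locate the
reversal potential of a two-ion (cation + anion) channel, converting it
to a GHK selectivity.
"""

import numpy as np

from edchannel import (
    AppliedVoltage,
    IonCurrentModel,
    SimulationConfig,
    calibrate_detailed_balance,
    committor_two_sided,
    crossing_currents,
    exact_iv_curve,
    f_profile,
    ghk_selectivity,
    make_synthetic_pmf,
    reconstruct_iv,
    reversal_potential,
    run_ensemble,
)

surface = make_synthetic_pmf("flat_well", ion_label="cation")
window = AppliedVoltage.full_window(surface, 0.0)
reference = window.at(50.0)

forward = run_ensemble(surface, reference, SimulationConfig(
    n_traj=100_000, direction="forward", seed=21))
backward = run_ensemble(surface, reference, SimulationConfig(
    n_traj=100_000, direction="backward", seed=22))
w = calibrate_detailed_balance(
    surface,
    SimulationConfig(n_traj=100_000, direction="forward", seed=23),
    SimulationConfig(n_traj=100_000, direction="backward", seed=24)).w

current = crossing_currents(forward, backward, w, t_S=1.0, q=surface.q)
P = committor_two_sided(forward, backward, w)
f = f_profile(surface, reference, mode="committor", committor=P)

voltages = np.linspace(-50.0, 150.0, 9)
curve = reconstruct_iv(current, f, surface, reference, voltages)
exact = exact_iv_curve(surface, window, voltages, 1.0, 1.0)
scale = current.J / exact["J"][np.argmin(np.abs(voltages - 50.0))]

print("  ΔV (mV)   J recon     J direct (scaled)    ± SE")
for i, dv in enumerate(voltages):
    print(f"{dv:8.1f}   {curve.J[i]:9.4g}   {exact['J'][i] * scale:9.4g}"
          f"        {curve.SE_pA[i] / 160.2176634:7.2g}")

# two-ion reversal potential at a 5:1 cis:trans salt gradient; both ion
# models must share one normalization, so use the closed-form currents
# for equal reservoir densities on both surfaces
anion = make_synthetic_pmf("central_barrier", height=2.0, q=-1.0,
                           ion_label="anion")
models = [
    IonCurrentModel.from_oracle(surface, window),
    IonCurrentModel.from_oracle(anion, window),
]
v_rev = reversal_potential(models, r=5.0)
print(f"\nreversal potential (5:1): {v_rev:.2f} mV")
print(f"GHK selectivity: {ghk_selectivity(v_rev, 5.0):.2f}")
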