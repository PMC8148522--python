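"""I-V reconstruction from one voltage, reversal potentials, GHK inversion."""

import numpy as np
import pytest

from edchannel import (
    AppliedVoltage,
    IonCurrentModel,
    NumericalBreakdownError,
    current_at_voltage,
    current_ratio,
    exact_committor,
    exact_iv_curve,
    exact_one_sided_density,
    exact_one_sided_fluxes,
    f_profile,
    ghk_reversal_potential,
    ghk_selectivity,
    make_synthetic_pmf,
    nernst_potential,
    reconstruct_iv,
    reversal_potential,
)
from edchannel.iv import exact_f_profile


def test_ratio_is_exactly_one_at_reference(flat_well):
    ref = AppliedVoltage.full_window(flat_well, 40.0)
    f = exact_f_profile(flat_well, ref)
    assert current_ratio(f, flat_well, ref, ref) == 1.0


def test_reconstructed_currents_match_direct_solution(mouth_barriers):
    s = mouth_barriers
    win = AppliedVoltage.full_window(s, 0.0)
    ref = win.at(50.0)
    jf0, jb0 = exact_one_sided_fluxes(s, ref, 1.0, 1.0)
    f = exact_f_profile(s, ref)
    Vs = np.linspace(-100.0, 150.0, 11)
    direct = exact_iv_curve(s, win, Vs, 1.0, 1.0)
    for i, dv in enumerate(Vs):
        jf, jb = current_at_voltage(jf0, jb0, f, s, ref, win.at(dv))
        assert jf == pytest.approx(direct["Jf"][i], rel=0.02)
        assert jb == pytest.approx(direct["Jb"][i], rel=0.02)


def test_f_profile_unity_in_homogeneous_limit(flat_surface):
    """Flat energy and uniform density give f ≡ 1 across the channel."""
    ref = AppliedVoltage.full_window(flat_surface, 0.0)
    f = exact_f_profile(flat_surface, ref)
    # 1 - P is the straight line from 1 to 0 for free diffusion, which is
    # the committor-mode profile; density mode must then agree with it
    np.testing.assert_allclose(
        f.f, 1.0 - (f.z - f.z[0]) / (f.z[-1] - f.z[0]), atol=1e-10)


def test_committor_and_density_modes_agree_on_oracle_inputs(central_barrier):
    from edchannel.estimators import CommittorProfile
    from edchannel.reconstruct import PMFEstimate

    s = central_barrier
    ref = AppliedVoltage.full_window(s, 60.0)
    P = exact_committor(s, ref)
    rho_f = exact_one_sided_density(s, ref, "forward")
    ones = np.ones(s.z.size, bool)
    prof = CommittorProfile(s.z, P, np.zeros_like(P), ones, "two_sided")
    fc = f_profile(s, ref, mode="committor", committor=prof)

    pmf = PMFEstimate(z=s.z, delta_A=s.A - s.A[0], valid=ones,
                      method="cpm_wham", delta_v=ref.delta_v,
                      reference_z=s.z[0])

    class FakeStats:
        direction = "forward"
        rho = rho_f
    fd = f_profile(s, ref, mode="density", pmf=pmf, stats=FakeStats())
    zi = s.z[1:-1]
    np.testing.assert_allclose(np.interp(zi, fd.z, fd.f),
                               np.interp(zi, fc.z, fc.f), atol=1e-9)


def test_ratio_breakdown_is_reported(central_barrier):
    s = central_barrier
    win = AppliedVoltage.full_window(s, 0.0)
    ref = win.at(300.0)
    f = exact_f_profile(s, ref)
    with pytest.raises(NumericalBreakdownError):
        current_ratio(f, s, ref, win.at(-3000.0))


def test_reconstruct_iv_passes_through_reference_and_propagates_errors(
        barrier_pair_50mv, barrier_weight):
    from edchannel import crossing_currents, committor_two_sided
    s, v, sf, sb = barrier_pair_50mv
    w = barrier_weight.w
    cur = crossing_currents(sf, sb, w, t_S=100.0, q=s.q)
    P = committor_two_sided(sf, sb, w)
    f = f_profile(s, v, mode="committor", committor=P)
    curve = reconstruct_iv(cur, f, s, v, [0.0, 50.0, 100.0])
    i_ref = 1  # 50 mV entry
    assert curve.Jf[i_ref] == pytest.approx(cur.J_f, rel=1e-12)
    assert curve.Jb[i_ref] == pytest.approx(cur.J_b, rel=1e-12)
    assert np.all(curve.SE_pA > 0)
    assert curve.ref_delta_v == 50.0


def test_reconstruct_iv_requires_calibration(barrier_pair_50mv,
                                             barrier_weight):
    from edchannel import CurrentEstimate
    s, v, sf, sb = barrier_pair_50mv
    cur = CurrentEstimate(delta_v=50.0, n_f=10, n_b=10, w=1.0,
                          t_S=float("nan"), J_f=1.0, J_b=1.0, J=0.0,
                          I_pA=0.0, rel_err_f=0.3, rel_err_b=0.3, se_J=0.1)
    f = exact_f_profile(s, v)
    with pytest.raises(ValueError, match="calibration"):
        reconstruct_iv(cur, f, s, v, [0.0])


def test_iv_tsv_output(tmp_path, flat_well):
    ref = AppliedVoltage.full_window(flat_well, 20.0)
    jf0, jb0 = exact_one_sided_fluxes(flat_well, ref, 1.0, 1.0)
    from edchannel import CurrentEstimate
    cur = CurrentEstimate(delta_v=20.0, n_f=100, n_b=100, w=1.0, t_S=1.0,
                          J_f=jf0, J_b=jb0, J=jf0 - jb0,
                          I_pA=(jf0 - jb0) * 160.2176634,
                          rel_err_f=0.1, rel_err_b=0.1, se_J=0.1)
    curve = reconstruct_iv(cur, exact_f_profile(flat_well, ref), flat_well,
                           ref, np.linspace(-50, 50, 5))
    out = tmp_path / "iv.tsv"
    curve.to_tsv(out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("#")
    assert len(lines) == 6


def test_reversal_zero_for_equal_concentrations(flat_well):
    m = IonCurrentModel.from_oracle(
        flat_well, AppliedVoltage.full_window(flat_well, 0.0))
    assert reversal_potential([m], 1.0) == pytest.approx(0.0, abs=0.05)


def test_single_ion_reversal_is_nernst(central_barrier):
    win = AppliedVoltage.full_window(central_barrier, 0.0)
    m = IonCurrentModel.from_oracle(central_barrier, win)
    v = reversal_potential([m], 5.0)
    assert v == pytest.approx(nernst_potential(5.0), abs=0.05)
    assert abs(v) == pytest.approx(41.35, abs=0.1)


def test_two_ion_reversal_matches_ghk_in_constant_field_regime():
    """Flat PMFs + boxcar field is exactly the GHK model: the reversal
    potential must invert to the diffusivity ratio."""
    z = np.linspace(-15.0, 15.0, 201)
    zero = np.zeros_like(z)
    cat = make_synthetic_pmf("tabulated", z=z, A=zero, D=50.0, q=1.0,
                             ion_label="cation")
    an = make_synthetic_pmf("tabulated", z=z, A=zero, D=10.0, q=-1.0,
                            ion_label="anion")
    win = AppliedVoltage.full_window(cat, 0.0)
    models = [IonCurrentModel.from_oracle(cat, win),
              IonCurrentModel.from_oracle(an, win)]
    v_rev = reversal_potential(models, 5.0)
    assert abs(v_rev) == pytest.approx(ghk_reversal_potential(5.0, 5.0),
                                       abs=1.0)
    assert ghk_selectivity(v_rev, 5.0) == pytest.approx(5.0, rel=0.05)


def test_ghk_round_trip_machine_precision():
    for x in (1.0, 1.7, 6.0, 80.0):
        v = ghk_reversal_potential(x, 5.0)
        assert ghk_selectivity(v, 5.0) == pytest.approx(x, rel=1e-9)


def test_ghk_selectivity_nernst_limit_error():
    v_nernst = nernst_potential(5.0)
    with pytest.raises(ValueError, match="Nernst"):
        ghk_selectivity(v_nernst + 1.0, 5.0)


def test_ghk_requires_gradient():
    with pytest.raises(ValueError):
        ghk_selectivity(5.0, 1.0)
    with pytest.raises(ValueError):
        ghk_reversal_potential(0.5, 5.0)


def test_nernst_sign_conventions():
    assert nernst_potential(5.0, q=-1.0) == pytest.approx(
        -nernst_potential(5.0, q=1.0))
    with pytest.raises(ValueError):
        nernst_potential(-1.0)
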