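"""Committor estimators and crossing-count statistics on constructed data."""

import numpy as np
import pytest

from edchannel import (
    AppliedVoltage,
    EnsembleStats,
    MethodUnavailableError,
    committor_alpha_patched,
    committor_one_sided,
    committor_two_sided,
    crossing_currents,
    exact_committor,
    poisson_relative_error,
    stochastic_time,
    time_for_matched_error,
)

Z = np.arange(-14.5, 15.0, 1.0)  # 30 bins on [-15, 15]


def make_stats(direction, n_injected, n_cross, N_reach, rho=None, dv=0.0):
    N_reach = np.asarray(N_reach, dtype=np.int64)
    if rho is None:
        rho = N_reach.astype(float)
    return EnsembleStats(
        direction=direction, n_injected=n_injected, n_cross=n_cross,
        n_return=n_injected - n_cross, n_truncated=0, bin_centers=Z,
        N_reach=N_reach, rho=np.asarray(rho, float), seed=0, delta_v=dv,
        dt=1e-3, epsilon=1.0, bin_width=1.0)


def test_one_sided_forward_committor_arithmetic():
    N = np.maximum(1000 // (1 + np.arange(30)), 10)
    s = make_stats("forward", 1000, int(N[-1]), N)
    prof = committor_one_sided(s)
    i = 10
    assert prof.P[i] == pytest.approx(N[-1] / N[i])
    assert prof.method == "forward"
    assert not prof.flagged


def test_one_sided_backward_committor_arithmetic():
    N = np.maximum((1 + np.arange(30)) * 30, 10)
    s = make_stats("backward", 1000, 90, N)
    prof = committor_one_sided(s)
    i = 20
    assert prof.P[i] == pytest.approx(1.0 - 90 / N[i])


def test_one_sided_flags_zero_crossings():
    N = np.maximum(1000 // (1 + np.arange(30)) ** 2, 0)
    s = make_stats("forward", 1000, 0, N)
    prof = committor_one_sided(s)
    assert prof.flagged
    assert np.all(prof.P[prof.valid] == 0.0)


def test_two_sided_exact_for_consistent_counts():
    """Counts built from a known P(z) return that P for any weight w."""
    P_true = np.linspace(0.05, 0.95, 30)
    base = 10_000
    Nf = np.round(base * P_true[0] / P_true).astype(np.int64)
    Nb = np.round(base * (1 - P_true[-1]) / (1 - P_true)).astype(np.int64)
    nf_cross = int(round(base * P_true[0]))      # = Nf * P exactly-ish
    nb_cross = int(round(base * (1 - P_true[-1])))
    sf = make_stats("forward", 20_000, nf_cross, Nf)
    sb = make_stats("backward", 20_000, nb_cross, Nb)
    for w in (0.5, 1.0, 2.0):
        prof = committor_two_sided(sf, sb, w)
        assert np.max(np.abs(prof.P[prof.valid]
                             - P_true[prof.valid])) < 5e-3


def test_two_sided_reduces_to_one_sided_when_backward_empty():
    N = np.maximum(1000 // (1 + np.arange(30)), 10)
    sf = make_stats("forward", 1000, int(N[-1]), N)
    sb = make_stats("backward", 0, 0, np.zeros(30))
    two = committor_two_sided(sf, sb, 1.0)
    one = committor_one_sided(sf)
    m = two.valid & one.valid
    np.testing.assert_allclose(two.P[m], one.P[m])


def test_two_sided_rejects_nonpositive_weight():
    s = make_stats("forward", 10, 1, np.full(30, 5))
    with pytest.raises(ValueError):
        committor_two_sided(s, make_stats("backward", 10, 1, np.full(30, 5)),
                            0.0)


def test_alpha_patched_continuity_and_range(rare_event_pair):
    surface, v, sf, sb = rare_event_pair
    assert sf.n_cross == 0          # rare-event regime by construction
    assert sb.n_cross > 100
    prof = committor_alpha_patched(sf, sb, 1.0)
    assert prof.alpha is not None and 0.0 <= prof.alpha < 1.0
    P = prof.P[prof.valid]
    assert np.all((P >= 0) & (P <= 1))
    # the patched profile should track the closed-form committor
    P_exact = np.interp(prof.z[prof.valid], surface.z, exact_committor(surface, v))
    assert np.max(np.abs(P - P_exact)) < 0.05


def test_alpha_patched_unavailable_without_overlap():
    Nf = np.zeros(30, dtype=np.int64)
    Nf[:5] = 100
    Nb = np.zeros(30, dtype=np.int64)
    Nb[-5:] = 100
    sf = make_stats("forward", 100, 0, Nf)
    sb = make_stats("backward", 100, 50, Nb)
    with pytest.raises(MethodUnavailableError):
        committor_alpha_patched(sf, sb, 1.0)


def test_transition_state_interpolation(barrier_pair_50mv, barrier_weight):
    surface, v, sf, sb = barrier_pair_50mv
    from edchannel import transition_state
    prof = committor_two_sided(sf, sb, barrier_weight.w)
    z_star = prof.transition_state_z
    assert abs(z_star - transition_state(surface, v)) < 1.0


def test_monotonicity_violation_counter():
    from edchannel.estimators import CommittorProfile
    z = np.arange(5.0)
    P = np.array([0.1, 0.3, 0.2, 0.6, 0.5])
    prof = CommittorProfile(z, P, np.zeros(5), np.ones(5, bool), "forward")
    assert prof.monotonicity_violations() == 2


def test_poisson_relative_error_headline_values():
    assert poisson_relative_error(200) == pytest.approx(0.0707, abs=5e-4)
    assert poisson_relative_error(23) == pytest.approx(0.2085, abs=5e-4)
    with pytest.raises(ValueError):
        poisson_relative_error(0)


def test_time_for_matched_error_extrapolation():
    """23 events in 7.7 μs: a 7% error takes at least 60 μs more sampling."""
    t = time_for_matched_error(7.7, 23, 1.0 / np.sqrt(200))
    assert t >= 60.0
    assert t == pytest.approx(7.7 * 200 / 23, rel=1e-12)


def test_stochastic_time_matching():
    assert stochastic_time(100.0, 20, 60) == pytest.approx(300.0)
    with pytest.raises(ValueError):
        stochastic_time(100.0, 0, 60)


def test_crossing_currents_arithmetic():
    N = np.full(30, 10, dtype=np.int64)
    sf = make_stats("forward", 1000, 80, N, dv=50.0)
    sb = make_stats("backward", 1000, 50, N, dv=50.0)
    cur = crossing_currents(sf, sb, w=1.2, t_S=10.0, q=1.0)
    assert cur.J == pytest.approx((80 - 1.2 * 50) / 10.0)
    assert cur.I_pA == pytest.approx(cur.J * 160.2176634)
    assert cur.rel_err_f == pytest.approx(1 / np.sqrt(80))
    assert cur.se_J == pytest.approx(np.sqrt(80 + 1.2**2 * 50) / 10.0)


def test_crossing_currents_balance_at_zero_voltage(barrier_weight):
    """At ΔV = 0 the calibrated net crossing count is statistically zero."""
    nf = barrier_weight.n_cross_forward
    nb = barrier_weight.n_cross_backward
    net = nf - barrier_weight.w * nb
    assert abs(net) <= 3.0 * np.sqrt(nf + barrier_weight.w**2 * nb) + 1e-9
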