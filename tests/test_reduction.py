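"""Reduction-engine tests: equivalent potentials, optimal grouping
weights, and the three-variable dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trnkit import (
    F_total,
    ModelParams,
    ReducedState,
    compute_weights,
    constant,
    equivalent_potentials,
    ionic_currents,
    kinetics_for,
    partials_of_F,
    recover_channel_currents,
    reduced_rhs,
    simulate_reduced,
    steady_state,
    step,
    zero,
)
from trnkit.dynamics import classify_regime, find_iv_roots
from trnkit.spikes import detect_spikes


def test_equivalent_potentials_roundtrip(params):
    full = steady_state(-60.0, params)
    ep = equivalent_potentials(full, params)
    kin = kinetics_for(params)
    assert float(kin["m"].inf(ep.v_m)) == pytest.approx(full.m, abs=1e-8)
    assert float(kin["q"].inf(ep.v_q)) == pytest.approx(full.q, abs=1e-8)
    # at steady state every equivalent potential equals the voltage
    for v in (ep.v_m, ep.v_h, ep.v_n, ep.v_p, ep.v_q):
        assert v == pytest.approx(-60.0, abs=1e-7)


def test_F_total_consistent_with_channel_currents(params):
    """With all equivalent potentials at V, F equals the summed channel
    currents of the steady state at V."""
    V = -65.0
    full = steady_state(V, params)
    expected = sum(ionic_currents(full, params).values())
    assert F_total(V, V, V, V, V, params) == pytest.approx(expected, rel=1e-10)


def test_F_reduces_to_leaks_without_active_channels():
    p = ModelParams(gNa=0.0, gK=0.0, gT=0.0)
    val = F_total(-60.0, -10.0, -90.0, 0.0, -55.0, p)
    leaks = p.gL * (-60.0 - p.EL) + p.gKL * (-60.0 - p.EKL)
    assert val == pytest.approx(leaks, rel=1e-12)


@pytest.mark.parametrize(
    "state",
    [(-65.0, -65.0, -65.0, -65.0, -65.0, -65.0), (-50.0, -45.0, -60.0, -62.0, -58.0, -70.0)],
)
def test_partials_match_finite_differences(params, state):
    V, v_m, v_h, v_n, v_p, v_q = state
    got = partials_of_F(V, v_m, v_h, v_n, v_p, v_q, params)
    eps = 1e-5

    def F(V, v_m, v_h, v_n, v_p, v_q):
        return F_total(V, v_h, v_n, v_p, v_q, params, v_m=v_m)

    args = [V, v_m, v_h, v_n, v_p, v_q]
    for i, key in enumerate(["dF_dV", "dF_dvm", "dF_dvh", "dF_dvn", "dF_dvp"]):
        up = list(args)
        dn = list(args)
        up[i] += eps
        dn[i] -= eps
        fd = (F(*up) - F(*dn)) / (2 * eps)
        assert got[key] == pytest.approx(fd, rel=1e-4, abs=1e-10), key


def test_partial_wrt_vp_vanishes_without_T_channel():
    p = ModelParams(gT=0.0)
    got = partials_of_F(-60.0, -60.0, -60.0, -60.0, -60.0, -60.0, p)
    assert got["dF_dvp"] == 0.0


def test_h_and_p_sensitivities_are_anti_synergistic(params):
    """Raising v_h opposes the effect of raising v_p on the membrane
    current at interior states between E_K and E_T."""
    for V in (-70.0, -60.0, -50.0):
        got = partials_of_F(V, V, V, V, V, V, params)
        assert got["dF_dvh"] * got["dF_dvp"] < 0


def test_weights_pin_rho_p_to_k(params):
    w = compute_weights(ReducedState(-65.0, -65.0, -65.0), params)
    assert w.rho_p == pytest.approx(params.k)
    assert w.rho_h + w.rho_n == pytest.approx(1.0 - params.k, abs=1e-12)


def test_weights_proportional_to_sensitivities(params):
    """rho_h : rho_n reproduces dF/dv_h : dF/dv_n with the (1-k)
    normalization at a state where both are positive."""
    s = ReducedState(-55.0, -60.0, -68.0)
    w = compute_weights(s, params)
    parts = partials_of_F(s.x, s.x, s.y, s.y, s.y, s.z, params)
    denom = parts["dF_dvh"] + parts["dF_dvn"]
    assert w.rho_h == pytest.approx((1 - params.k) * parts["dF_dvh"] / denom, rel=1e-8)
    assert w.rho_n == pytest.approx((1 - params.k) * parts["dF_dvn"] / denom, rel=1e-8)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    x=st.floats(min_value=-100.0, max_value=40.0),
    y=st.floats(min_value=-100.0, max_value=-40.0),
    z=st.floats(min_value=-100.0, max_value=-40.0),
)
def test_weight_normalization_everywhere(x, y, z):
    p = ModelParams()
    w = compute_weights(ReducedState(x, y, z), p)
    assert w.rho_V + w.rho_m == pytest.approx(1.0, abs=1e-12)
    assert w.rho_h + w.rho_n + w.rho_p == pytest.approx(1.0, abs=1e-12)
    for val in (w.rho_V, w.rho_m, w.rho_h, w.rho_n, w.rho_p):
        assert val >= 0.0


@pytest.mark.parametrize("x", [-80.0, -65.0, -50.0, -20.0])
def test_y_nullcline_is_the_diagonal(params, x):
    for z in (-75.0, -65.0, -55.0):
        d = reduced_rhs(0.0, ReducedState(x, x, z), params)
        assert d[1] == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("x", [-80.0, -65.0, -50.0, -20.0])
def test_z_nullcline_is_the_diagonal(params, x):
    for y in (-75.0, -60.0):
        d = reduced_rhs(0.0, ReducedState(x, y, x), params)
        assert d[2] == pytest.approx(0.0, abs=1e-9)


def test_diagonal_iv_roots_are_reduced_equilibria(params):
    """Any root of the current-voltage relation along the diagonal is a
    rest point of the full three-variable flow."""
    roots = find_iv_roots(-65.0, 0.0, params)
    # the diagonal equilibrium: x=y=z=V* where I(V*, z=V*)=0
    diag = [V for V in np.linspace(-90, -40, 200)]
    from trnkit.dynamics import global_equilibria

    for fp in global_equilibria(0.0, params):
        d = reduced_rhs(0.0, ReducedState(fp.V, fp.V, fp.V), params)
        assert np.max(np.abs(d)) < 1e-8


def test_recovered_currents_sum_to_F(params):
    s = ReducedState(-58.0, -62.0, -67.0)
    cur = recover_channel_currents(s, params)
    assert sum(cur.values()) == pytest.approx(
        F_total(s.x, s.y, s.y, s.y, s.z, params), rel=1e-10
    )


def test_recovered_sodium_current_zero_at_reversal(params):
    cur = recover_channel_currents(ReducedState(params.ENa, -60.0, -65.0), params)
    assert cur["I_Na"] == 0.0


def test_T_current_is_depolarizing_at_rebound_onset(params):
    """During a rebound burst the recovered T current is inward
    (negative, i.e. depolarizing) at burst onset."""
    tr = simulate_reduced(params, step(-0.03, 50.0, 250.0, 400.0))
    # at release the T channel is de-inactivated; check the first 30 ms after
    w = tr.window(250.0, 280.0)
    assert w["I_T"].min() < -0.5


def test_quiet_at_rest(params):
    tr = simulate_reduced(params, zero(400.0))
    assert len(detect_spikes(tr)) == 0


def test_rebound_protocol_burst_then_subthreshold(comparison_params):
    """An inhibitory 200 ms step yields a rebound burst after release and
    subthreshold oscillation afterwards."""
    tr = simulate_reduced(comparison_params, step(-0.05, 0.0, 200.0, 1000.0))
    burst_window = tr.window(200.0, 400.0)
    assert len(detect_spikes(burst_window)) >= 2
    late = tr.window(600.0, 1000.0)
    assert classify_regime(late.t, late.V, window=400.0) in (
        "subthreshold-oscillation",
        "stationary",
    )


def test_reduced_matches_full_tonic_rate(comparison_params):
    """Under sustained depolarization the reduced model settles into the
    same tonic spiking as the full model (final 200 ms count within 1)."""
    from trnkit import simulate_full

    proto = constant(0.2, 1000.0)
    n_full = len(
        detect_spikes(simulate_full(comparison_params, proto, record_stride=5).window(800, 1000))
    )
    n_red = len(
        detect_spikes(simulate_reduced(comparison_params, proto).window(800, 1000))
    )
    assert abs(n_full - n_red) <= 1
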