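"""Full conductance-model tests: current bookkeeping against a hand
evaluation, equilibrium consistency, rebound bursting, and integrator
behaviour."""

import math

import numpy as np
import pytest

from trnkit import (
    FullState,
    ModelParams,
    full_rhs,
    ionic_currents,
    simulate_full,
    steady_state,
    step,
    zero,
)
from trnkit.spikes import detect_spikes


def test_all_currents_vanish_at_leak_reversal():
    p = ModelParams(gNa=0.0, gK=0.0, gT=0.0, gKL=0.0)
    cur = ionic_currents(steady_state(p.EL, p), p)
    assert all(abs(v) < 1e-12 for v in cur.values())


def test_potassium_current_zero_at_reversal(params):
    st = FullState(params.EK, 0.5, 0.5, 1.0, 0.5, 0.5)
    assert ionic_currents(st, params)["I_K"] == 0.0


def test_currents_match_hand_evaluation(params):
    """Independent spreadsheet-style evaluation of the channel currents
    at V = -70 mV with every gate at steady state."""
    V = -70.0
    # rates written out from first principles (not via the package)
    u = 13.0 - V - 55.0
    am = 0.32 * u / (math.exp(u / 4.0) - 1.0)
    u = V - 40.0 + 55.0
    bm = 0.28 * u / (math.exp(u / 5.0) - 1.0)
    ah = 0.128 * math.exp((17.0 - V - 55.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp((40.0 - V - 55.0) / 5.0))
    u = 15.0 - V - 55.0
    an = 0.032 * u / (math.exp(u / 5.0) - 1.0)
    bn = 0.5 * math.exp((10.0 - V - 55.0) / 40.0)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)
    pinf = 1.0 / (1.0 + math.exp((-52.0 - V - 3.0) / 7.4))
    qinf = 1.0 / (1.0 + math.exp((80.0 + V + 3.0) / 5.0))
    expected = {
        "I_Na": 100.0 * m**3 * h * (V - 50.0),
        "I_K": 10.0 * n**4 * (V + 100.0),
        "I_T": 2.25 * pinf**2 * qinf * (V - 120.0),
        "I_L": 0.06 * (V + 70.0),
        "I_KL": 0.0065 * (V + 100.0),
    }
    got = ionic_currents(steady_state(V, params), params)
    for key, val in expected.items():
        assert got[key] == pytest.approx(val, rel=1e-12), key


def test_rhs_zero_at_exact_equilibrium(params):
    """At a voltage where the gates are at steady state and the net
    current is balanced by the stimulus, all derivatives vanish."""
    V = -68.0
    st = steady_state(V, params)
    net = sum(ionic_currents(st, params).values())
    # choose the stimulus that balances the ionic current exactly
    amp_nA = net * params.A / 1e-3
    proto = step(amp_nA, 0.0, 10.0, 10.0)
    d = full_rhs(5.0, st, params, proto)
    assert np.max(np.abs(d)) < 1e-9


def test_rest_drift_sign_matches_leak(params):
    """With zero stimulus and gates at rest below threshold, dV/dt has
    the sign of the net inward leak."""
    st = steady_state(-80.0, params)
    leak = ionic_currents(st, params)
    d = full_rhs(0.0, st, params, None)
    expected_sign = -np.sign(sum(leak.values()))
    assert np.sign(d[0]) == expected_sign


def test_zero_stimulus_settles_without_nan(params):
    tr = simulate_full(params, zero(500.0), record_stride=10)
    V = tr["V_mV"]
    assert np.all(np.isfinite(V))
    dV = np.diff(V[-50:]) / np.diff(tr.t[-50:])
    # settled or at worst slowly oscillating
    assert np.max(np.abs(dV)) < 1.0


def test_gating_variables_stay_in_unit_interval(params):
    tr = simulate_full(params, step(0.2, 0.0, 100.0, 200.0), record_stride=5)
    for g in ("m", "h", "n", "p", "q"):
        assert np.all(tr[g] >= 0.0) and np.all(tr[g] <= 1.0), g


def test_long_run_voltage_within_reversal_bounds(params):
    tr = simulate_full(params, zero(800.0), record_stride=10)
    lo = min(params.EK, params.EKL, params.EL)
    hi = max(params.ENa, params.ET)
    assert np.all(tr["V_mV"] >= lo) and np.all(tr["V_mV"] <= hi)


def test_rebound_burst_after_hyperpolarizing_step():
    """Releasing a 200 ms inhibitory step fires a rebound burst (the
    de-inactivated T current drives spikes within 150 ms)."""
    p = ModelParams(EL=-77.0, gKL=0.00793, gT=2.0)
    tr = simulate_full(p, step(-0.03, 0.0, 200.0, 600.0), record_stride=5)
    w = tr.window(200.0, 350.0)
    assert len(detect_spikes(w)) >= 2


def test_tonic_protocol_produces_burst_then_regular_spiking(comparison_params):
    tr = simulate_full(comparison_params, step(0.2, 0.0, 1000.0, 1000.0),
                       record_stride=5)
    train = detect_spikes(tr.window(900.0, 1000.0))
    isis = train.isis
    assert len(train) >= 3
    assert np.std(isis) / np.mean(isis) < 0.05


def test_fixed_step_convergence(params):
    """Halving the RK4 step changes the endpoint voltage of a 50 ms
    segment by far less than 0.1 mV (and consistently with 4th order)."""
    init = steady_state(-68.0, params)
    proto = step(0.05, 0.0, 50.0, 50.0)
    ends = {}
    for dt in (0.04, 0.02, 0.01):
        tr = simulate_full(params, proto, init=init, dt=dt)
        ends[dt] = tr["V_mV"][-1]
    assert abs(ends[0.02] - ends[0.01]) < 0.1
    err_coarse = abs(ends[0.04] - ends[0.01])
    err_fine = abs(ends[0.02] - ends[0.01])
    if err_coarse > 1e-10:
        assert err_fine < err_coarse


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        ModelParams(gNa=-1.0)
    with pytest.raises(ValueError, match="outside"):
        FullState(-70.0, 1.2, 0.5, 0.5, 0.5, 0.5)
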