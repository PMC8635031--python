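"""Gating-kinetics unit tests: Table-style rate functions, removable
singularities, monotone steady states, analytic derivatives, and the
scalar/vectorized implementation pair staying in lockstep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trnkit import kinetics_for, rate_value, standard_kinetics
from trnkit import _fastmath as fm

KIN = standard_kinetics()


def test_alpha_m_removable_singularity_analytic_limit():
    # 13 - V + VthNa = 0 at V = -42 with VthNa = -55; limit is 0.32 * 4
    assert rate_value(KIN["m"], "alpha", -42.0) == pytest.approx(1.28, abs=1e-9)
    # continuity: values straddling the singular voltage agree closely
    left = rate_value(KIN["m"], "alpha", -42.0 - 1e-6)
    right = rate_value(KIN["m"], "alpha", -42.0 + 1e-6)
    assert left == pytest.approx(right, rel=1e-5)


def test_q_inf_logistic_midpoint():
    # 80 + V - VthT = 0 at V = -83 for VthT = -3
    assert float(KIN["q"].inf(-83.0)) == pytest.approx(0.5, abs=1e-12)


def test_steady_states_bounded_and_monotone(v_grid):
    for name, kin in KIN.items():
        inf = np.asarray(kin.inf(v_grid))
        assert np.all((inf > 0.0) & (inf < 1.0)), name
        diffs = np.diff(inf)
        if kin.increasing:
            assert np.all(diffs > 0), f"{name} should increase with V"
        else:
            assert np.all(diffs < 0), f"{name} should decrease with V"


def test_time_constants_positive(v_grid):
    for name, kin in KIN.items():
        assert np.all(np.asarray(kin.tau(v_grid)) > 0), name


def test_n_inf_increases_on_example_grid():
    vals = [float(KIN["n"].inf(v)) for v in (-60.0, -50.0, -40.0)]
    assert vals[0] < vals[1] < vals[2]


@pytest.mark.parametrize("name", list(KIN))
def test_dinf_matches_finite_difference(name):
    kin = KIN[name]
    for V in (-90.0, -63.0, -42.0, -20.0, 5.0):
        fd = (float(kin.inf(V + 1e-5)) - float(kin.inf(V - 1e-5))) / 2e-5
        assert float(kin.dinf(V)) == pytest.approx(fd, rel=1e-4, abs=1e-12)


def test_scalar_kernels_match_vectorized_reference(v_grid):
    """The compiled scalar kinetics and the numpy reference are the same
    functions to near machine precision."""
    pairs = [
        (KIN["m"].inf, lambda v: fm.m_inf(v, -55.0)),
        (KIN["m"].tau, lambda v: fm.tau_m(v, -55.0)),
        (KIN["h"].inf, lambda v: fm.h_inf(v, -55.0)),
        (KIN["n"].inf, lambda v: fm.n_inf(v, -55.0)),
        (KIN["n"].tau, lambda v: fm.tau_n(v, -55.0)),
        (KIN["p"].inf, lambda v: fm.p_inf(v, -3.0)),
        (KIN["p"].tau, lambda v: fm.tau_p(v, -3.0)),
        (KIN["q"].inf, lambda v: fm.q_inf(v, -3.0)),
        (KIN["q"].tau, lambda v: fm.tau_q(v, -3.0)),
        (KIN["m"].dinf, lambda v: fm.dm_inf(v, -55.0)),
        (KIN["h"].dinf, lambda v: fm.dh_inf(v, -55.0)),
        (KIN["n"].dinf, lambda v: fm.dn_inf(v, -55.0)),
    ]
    for vec, scal in pairs:
        for v in v_grid[::20]:
            assert float(vec(v)) == pytest.approx(scal(float(v)), rel=1e-12, abs=1e-15)


def test_rate_value_rejects_unknown_function():
    with pytest.raises(ValueError, match="unknown kinetic"):
        rate_value(KIN["m"], "gamma", -60.0)


def test_inf_tau_gates_have_no_alpha_beta():
    with pytest.raises(ValueError, match="no alpha/beta"):
        KIN["p"].alpha(-60.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    name=st.sampled_from(["m", "h", "n", "p", "q"]),
    frac=st.floats(min_value=1e-6, max_value=1 - 1e-6),
)
def test_inverse_steady_state_roundtrip(name, frac):
    kin = KIN[name]
    v = kin.inv_inf(frac)
    assert float(kin.inf(v)) == pytest.approx(frac, abs=1e-10)


def test_inverse_steady_state_against_bisection_oracle():
    # independent bisection on [-120, 60] for n_inf = 0.3
    kin = KIN["n"]
    lo, hi = -120.0, 60.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float(kin.inf(mid)) < 0.3:
            lo = mid
        else:
            hi = mid
    assert kin.inv_inf(0.3) == pytest.approx(0.5 * (lo + hi), abs=1e-8)


def test_inverse_steady_state_domain_error():
    with pytest.raises(ValueError, match="outside"):
        KIN["m"].inv_inf(1.5)


def test_kinetics_follow_parameter_thresholds(params):
    shifted = kinetics_for(params.with_(VthT=0.0))
    # q_inf midpoint moves with the Ca threshold: 80 + V - VthT = 0
    assert float(shifted["q"].inf(-80.0)) == pytest.approx(0.5, abs=1e-12)
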