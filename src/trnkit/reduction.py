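"""Reduction of the six-variable TRN model to three variables.

The reduction follows the equivalent-potential method: every gating
fraction theta is mapped to the voltage v_theta at which its steady-state
curve takes that value (theta = theta_inf(v_theta)), making all state
variables commensurate in mV.  Variables evolving on a similar time
scale are then grouped into weighted averages:

    x = rho_V V + rho_m v_m          (fast: spike upstroke)
    y = rho_h v_h + rho_n v_n + rho_p v_p   (intermediate: recovery)
    z = v_q                          (slow: T-channel de-inactivation)

The weights are chosen at each state to minimize the first-order
discrepancy between the reduced and full voltage dynamics: rho_p is
pinned to a small constant k (default 0.01), rho_h and rho_n split the
remaining 1 - k in proportion to the current sensitivities dF/dv_h and
dF/dv_n, and rho_V solves a quadratic balancing the membrane and Na+
activation time scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fastmath as fm
from .channels import kinetics_for
from .full_model import FullState
from .params import ModelParams
from .protocol import StimulusProtocol, zero
from .trace import Trace


@dataclass(frozen=True)
class ReducedState:
    """The three reduced variables, all in mV.

    ``x`` plays the role of the membrane potential, ``y`` the shared
    recovery potential of (h, n, p), ``z`` the slow potential of q.
    """

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @classmethod
    def from_array(cls, arr) -> "ReducedState":
        a = np.asarray(arr, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class ReductionWeights:
    """The grouping coefficients; rho_V + rho_m = 1, rho_h + rho_n + rho_p = 1."""

    rho_V: float
    rho_m: float
    rho_h: float
    rho_n: float
    rho_p: float
    k: float


@dataclass(frozen=True)
class EquivalentPotentials:
    """Per-gate equivalent potentials (mV) of a full-model state."""

    v_m: float
    v_h: float
    v_n: float
    v_p: float
    v_q: float


def inverse_steady_state(kin, fraction: float) -> float:
    """Voltage at which a gate's steady-state curve equals ``fraction``."""
    return kin.inv_inf(fraction)


def equivalent_potentials(
    state: FullState, params: ModelParams | None = None
) -> EquivalentPotentials:
    """Map the gating fractions of a full state to equivalent potentials."""
    params = params or ModelParams()
    kin = kinetics_for(params)
    return EquivalentPotentials(
        kin["m"].inv_inf(state.m),
        kin["h"].inv_inf(state.h),
        kin["n"].inv_inf(state.n),
        kin["p"].inv_inf(state.p),
        kin["q"].inv_inf(state.q),
    )


def F_total(
    V: float,
    v_h: float,
    v_n: float,
    v_p: float,
    v_q: float,
    params: ModelParams,
    v_m: float | None = None,
) -> float:
    """Total ionic current density through equivalent potentials.

    The Na+ activation potential v_m defaults to V itself (the reduced
    voltage equation evaluates m_inf at x).
    """
    kin = kinetics_for(params)
    v_m = V if v_m is None else v_m
    mi = float(kin["m"].inf(v_m))
    hi = float(kin["h"].inf(v_h))
    ni = float(kin["n"].inf(v_n))
    pi_ = float(kin["p"].inf(v_p))
    qi = float(kin["q"].inf(v_q))
    return (
        params.gNa * mi**3 * hi * (V - params.ENa)
        + params.gK * ni**4 * (V - params.EK)
        + params.gT * pi_**2 * qi * (V - params.ET)
        + params.gL * (V - params.EL)
        + params.gKL * (V - params.EKL)
    )


def partials_of_F(
    V: float,
    v_m: float,
    v_h: float,
    v_n: float,
    v_p: float,
    v_q: float,
    params: ModelParams,
) -> dict[str, float]:
    """Analytic partial derivatives of F with respect to V and the
    equivalent potentials of m, h, n, p."""
    kin = kinetics_for(params)
    mi = float(kin["m"].inf(v_m))
    hi = float(kin["h"].inf(v_h))
    ni = float(kin["n"].inf(v_n))
    pi_ = float(kin["p"].inf(v_p))
    qi = float(kin["q"].inf(v_q))
    return {
        "dF_dV": (
            params.gNa * mi**3 * hi
            + params.gK * ni**4
            + params.gT * pi_**2 * qi
            + params.gL
            + params.gKL
        ),
        "dF_dvm": 3.0
        * params.gNa
        * mi**2
        * float(kin["m"].dinf(v_m))
        * hi
        * (V - params.ENa),
        "dF_dvh": params.gNa * mi**3 * float(kin["h"].dinf(v_h)) * (V - params.ENa),
        "dF_dvn": 4.0
        * params.gK
        * ni**3
        * float(kin["n"].dinf(v_n))
        * (V - params.EK),
        "dF_dvp": 2.0
        * params.gT
        * pi_
        * float(kin["p"].dinf(v_p))
        * qi
        * (V - params.ET),
    }


def compute_weights(
    state: ReducedState, params: ModelParams | None = None
) -> ReductionWeights:
    """Grouping weights evaluated at a reduced state (v_m -> x,
    v_h = v_n = v_p -> y, v_q -> z)."""
    params = params or ModelParams()
    rv, rm, rh, rn, rp = fm.reduction_weights(
        state.x, state.y, state.z, params.as_array()
    )
    return ReductionWeights(rv, rm, rh, rn, rp, params.k)


def reduced_rhs(
    t: float,
    state: ReducedState | np.ndarray,
    params: ModelParams,
    protocol: StimulusProtocol | None = None,
) -> np.ndarray:
    """Time derivatives (dx, dy, dz) of the reduced model at time t."""
    s = state.as_array() if isinstance(state, ReducedState) else np.asarray(state, float)
    amp = protocol.amplitude(t) if protocol is not None else 0.0
    i_stim = 1e-3 * amp / params.A
    return np.array(fm.reduced_rhs(s[0], s[1], s[2], i_stim, params.as_array()))


def reduce_state(state: FullState, params: ModelParams | None = None) -> ReducedState:
    """Project a full-model state onto the reduced variables, using
    weights computed at that state."""
    params = params or ModelParams()
    ep = equivalent_potentials(state, params)
    # weights evaluated with the grouped coordinates as the reference
    w = fm.reduction_weights(
        state.V, (ep.v_h + ep.v_n) / 2.0, ep.v_q, params.as_array()
    )
    rho_v, rho_m, rho_h, rho_n, rho_p = w
    return ReducedState(
        rho_v * state.V + rho_m * ep.v_m,
        rho_h * ep.v_h + rho_n * ep.v_n + rho_p * ep.v_p,
        ep.v_q,
    )


def recover_channel_currents(
    state: ReducedState, params: ModelParams | None = None
) -> dict[str, float]:
    """Per-channel current densities reconstructed from (x, y, z)."""
    params = params or ModelParams()
    kin = kinetics_for(params)
    x, y, z = state.x, state.y, state.z
    return {
        "I_Na": params.gNa
        * float(kin["m"].inf(x)) ** 3
        * float(kin["h"].inf(y))
        * (x - params.ENa),
        "I_K": params.gK * float(kin["n"].inf(y)) ** 4 * (x - params.EK),
        "I_T": params.gT
        * float(kin["p"].inf(y)) ** 2
        * float(kin["q"].inf(z))
        * (x - params.ET),
        "I_L": params.gL * (x - params.EL),
        "I_KL": params.gKL * (x - params.EKL),
    }


def _run_segment(y0, amp, t0, t1, rtol, atol, max_step, P):
    t, Y, status, t_fail = fm.integrate_reduced_dp45(
        y0, amp, t0, t1, rtol, atol, max_step, P
    )
    if status != fm.STATUS_OK:
        reason = "step-size underflow" if status == fm.STATUS_UNDERFLOW else "step cap"
        raise RuntimeError(f"reduced-model integration failed ({reason}) at t={t_fail:.4f} ms")
    return t, Y


def _settle_reduced(
    params: ModelParams, settle_ms: float, rtol: float, atol: float, max_step: float
) -> np.ndarray:
    y0 = np.array([-70.0, -70.0, -70.0])
    _, Y = _run_segment(y0, 0.0, 0.0, settle_ms, rtol, atol, max_step, params.as_array())
    return Y[-1]


def simulate_reduced(
    params: ModelParams | None = None,
    protocol: StimulusProtocol | None = None,
    init: ReducedState | str = "steady",
    method: str = "adaptive",
    dt: float = 0.005,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = 0.1,
    settle_ms: float = 2000.0,
    record_stride: int = 1,
) -> Trace:
    """Integrate the reduced model over a stimulation protocol.

    Mirrors :func:`trnkit.full_model.simulate_full`; trace columns are
    x_mV, y_mV, z_mV plus the reconstructed channel currents.  The
    default solver is an adaptive explicit Runge-Kutta 5(4): the
    equivalent-potential equations are mildly stiff whenever a spike
    pushes y toward a gate's saturated range, so fixed-step integration
    needs a conservative ``dt``.
    """
    params = params or ModelParams()
    protocol = protocol or zero(500.0)
    P = params.as_array()
    if isinstance(init, str):
        if init != "steady":
            raise ValueError(f"unknown init policy {init!r}")
        y0 = _settle_reduced(params, settle_ms, rtol, atol, max_step)
    else:
        y0 = init.as_array()

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for t0, t1, amp in protocol.piecewise():
        dens = 1e-3 * amp / params.A
        if method == "rk4":
            t, Y = fm.integrate_reduced_rk4(y0, dens, t0, t1, dt, P)
            if not np.all(np.isfinite(Y)):
                raise RuntimeError(
                    "fixed-step integration of the reduced model diverged; "
                    "use method='adaptive' or a smaller dt"
                )
        elif method == "adaptive":
            t, Y = _run_segment(y0, dens, t0, t1, rtol, atol, max_step, P)
        else:
            raise ValueError(f"unknown method {method!r}")
        y0 = Y[-1].copy()
        if ts:
            t, Y = t[1:], Y[1:]
        ts.append(t)
        ys.append(Y)
    t = np.concatenate(ts)[::record_stride]
    Y = np.concatenate(ys)[::record_stride]

    kin = kinetics_for(params)
    x, y, z = Y[:, 0], Y[:, 1], Y[:, 2]
    mi, hi = kin["m"].inf(x), kin["h"].inf(y)
    ni, pi_, qi = kin["n"].inf(y), kin["p"].inf(y), kin["q"].inf(z)
    cols = {
        "x_mV": x,
        "y_mV": y,
        "z_mV": z,
        "I_Na": params.gNa * mi**3 * hi * (x - params.ENa),
        "I_K": params.gK * ni**4 * (x - params.EK),
        "I_T": params.gT * pi_**2 * qi * (x - params.ET),
        "I_L": params.gL * (x - params.EL),
        "I_KL": params.gKL * (x - params.EKL),
        "I_stim": np.array([protocol.amplitude(tt) for tt in t]),
    }
    meta = {
        "model": "reduced",
        "params": params.to_dict(),
        "protocol": protocol.to_dict(),
        "solver": {"method": method, "dt": dt, "rtol": rtol, "atol": atol},
    }
    return Trace(t, cols, meta)
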