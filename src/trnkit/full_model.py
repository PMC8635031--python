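"""The six-variable conductance-based TRN neuron model.

Membrane equation (current densities in uA/cm2, V in mV, t in ms):

    C dV/dt = 1e-3 I_syn(t) / A - (I_Na + I_K + I_T + I_L + I_KL)

with I_Na = gNa m^3 h (V - ENa), I_K = gK n^4 (V - EK),
I_T = gT p^2 q (V - ET) and ohmic leaks.  Gating variables follow the
kinetics of :mod:`trnkit.channels`.

Stimulus convention: protocol amplitudes are the synaptic current I_syn
in the model's native units (nA); the membrane equation normalizes by
the cell area with the 1e-3/A factor above, so an amplitude of 1 nA adds
1e-3/A ~ 6.99 uA/cm2 of depolarizing current density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _fastmath as fm
from .channels import kinetics_for
from .params import ModelParams
from .protocol import StimulusProtocol, zero
from .trace import Trace

_GATES = ("m", "h", "n", "p", "q")


@dataclass(frozen=True)
class FullState:
    """Membrane potential (mV) and the five gating fractions."""

    V: float
    m: float
    h: float
    n: float
    p: float
    q: float

    def __post_init__(self) -> None:
        for g in _GATES:
            v = getattr(self, g)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gating fraction {g}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n, self.p, self.q])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FullState":
        y = np.asarray(y, dtype=float)
        return cls(y[0], *np.clip(y[1:6], 0.0, 1.0))


def steady_state(V: float, params: ModelParams | None = None) -> FullState:
    """The state with every gate at its steady-state value for voltage V."""
    params = params or ModelParams()
    kin = kinetics_for(params)
    return FullState(V, *(float(kin[g].inf(V)) for g in _GATES))


def ionic_currents(state: FullState, params: ModelParams) -> dict[str, float]:
    """Per-channel current densities (uA/cm2), outward positive."""
    V = state.V
    return {
        "I_Na": params.gNa * state.m**3 * state.h * (V - params.ENa),
        "I_K": params.gK * state.n**4 * (V - params.EK),
        "I_T": params.gT * state.p**2 * state.q * (V - params.ET),
        "I_L": params.gL * (V - params.EL),
        "I_KL": params.gKL * (V - params.EKL),
    }


def full_rhs(
    t: float,
    state: FullState | np.ndarray,
    params: ModelParams,
    protocol: StimulusProtocol | None = None,
) -> np.ndarray:
    """Time derivatives of (V, m, h, n, p, q) at time t."""
    y = state.as_array() if isinstance(state, FullState) else np.asarray(state, float)
    amp = protocol.amplitude(t) if protocol is not None else 0.0
    i_stim = 1e-3 * amp / params.A
    return np.array(fm.full_rhs(*y, i_stim, params.as_array()))


def _settle(params: ModelParams, settle_ms: float, dt: float, V0: float) -> np.ndarray:
    y0 = steady_state(V0, params).as_array()
    _, Y = fm.integrate_full_rk4(y0, 0.0, 0.0, settle_ms, dt, params.as_array())
    return Y[-1]


def simulate_full(
    params: ModelParams | None = None,
    protocol: StimulusProtocol | None = None,
    init: FullState | str = "steady",
    method: str = "rk4",
    dt: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = 0.1,
    settle_ms: float = 2000.0,
    record_stride: int = 1,
) -> Trace:
    """Integrate the full model over a stimulation protocol.

    ``init="steady"`` relaxes the model for ``settle_ms`` at zero
    stimulus before t = 0.  ``method`` is ``"rk4"`` (fixed step ``dt``,
    bit-reproducible) or ``"adaptive"`` (RK45 with the given tolerances).
    """
    params = params or ModelParams()
    protocol = protocol or zero(500.0)
    P = params.as_array()
    if isinstance(init, str):
        if init != "steady":
            raise ValueError(f"unknown init policy {init!r}")
        y0 = _settle(params, settle_ms, max(dt, 0.01), -70.0)
    else:
        y0 = init.as_array()

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for t0, t1, amp in protocol.piecewise():
        dens = 1e-3 * amp / params.A
        if method == "rk4":
            t, Y = fm.integrate_full_rk4(y0, dens, t0, t1, dt, P)
        elif method == "adaptive":
            sol = solve_ivp(
                lambda t, y: fm.full_rhs(*y, dens, P),
                (t0, t1),
                y0,
                method="RK45",
                rtol=rtol,
                atol=atol,
                max_step=max_step,
                dense_output=False,
            )
            if not sol.success:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"integration failed near t={sol.t[-1]:.3f} ms: {sol.message}"
                )
            t, Y = sol.t, np.clip(sol.y.T, None, None)
            Y[:, 1:] = np.clip(Y[:, 1:], 0.0, 1.0)
        else:
            raise ValueError(f"unknown method {method!r}")
        y0 = Y[-1].copy()
        if ts:
            t, Y = t[1:], Y[1:]
        ts.append(t)
        ys.append(Y)
    t = np.concatenate(ts)[::record_stride]
    Y = np.concatenate(ys)[::record_stride]

    V, m, h, n, p, q = (Y[:, i] for i in range(6))
    i_stim = np.array([protocol.amplitude(tt) for tt in t])
    cols = {
        "V_mV": V,
        "m": m,
        "h": h,
        "n": n,
        "p": p,
        "q": q,
        "I_Na": params.gNa * m**3 * h * (V - params.ENa),
        "I_K": params.gK * n**4 * (V - params.EK),
        "I_T": params.gT * p**2 * q * (V - params.ET),
        "I_L": params.gL * (V - params.EL),
        "I_KL": params.gKL * (V - params.EKL),
        "I_stim": i_stim,
    }
    meta = {
        "model": "full",
        "params": params.to_dict(),
        "protocol": protocol.to_dict(),
        "solver": {"method": method, "dt": dt, "rtol": rtol, "atol": atol},
    }
    return Trace(t, cols, meta)
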