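"""Scalar kinetics and fixed-step integrators for the TRN model.

This module mirrors the vectorized voltage-dependent rate functions of
:mod:`trnkit.channels` as plain-float scalar code so that the inner
simulation loops can be compiled with numba when it is installed.  The
formulas here and in ``channels`` are cross-checked against each other in
the test suite; ``channels`` is the readable reference, this file is the
hot path.

Parameter vectors are plain ``float64`` arrays laid out according to the
``P_*`` index constants below (see :meth:`trnkit.params.ModelParams.as_array`).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# Parameter-vector layout (indices into the float64 array built by
# ModelParams.as_array()).
P_C = 0
P_GL = 1
P_EL = 2
P_GKL = 3
P_EKL = 4
P_GNA = 5
P_ENA = 6
P_GK = 7
P_EK = 8
P_GT = 9
P_ET = 10
P_VTHNA = 11
P_VTHK = 12
P_VTHT = 13
P_PHIM = 14
P_PHIH = 15
P_PHIN = 16
P_PHIP = 17
P_PHIQ = 18
P_K = 19
P_LEN = 20

# Below this magnitude of the exponential argument the removable
# singularity u/(exp(u/c)-1) is replaced by its series expansion.
_SING_EPS = 1e-7


@njit(cache=False)
def _rexp(u: float, c: float) -> float:
    """u / (exp(u/c) - 1) with the analytic limit c at u -> 0."""
    if abs(u) < _SING_EPS:
        return c - 0.5 * u + u * u / (12.0 * c)
    return u / math.expm1(u / c)


@njit(cache=False)
def _drexp(u: float, c: float) -> float:
    """d/du of u / (exp(u/c) - 1)."""
    if abs(u) < _SING_EPS:
        return -0.5 + u / (6.0 * c)
    e = math.expm1(u / c)
    return (e - u * (e + 1.0) / c) / (e * e)


# ----------------------------------------------------------------- rates

@njit(cache=False)
def alpha_m(V: float, vth: float) -> float:
    return 0.32 * _rexp(13.0 - V + vth, 4.0)


@njit(cache=False)
def beta_m(V: float, vth: float) -> float:
    return 0.28 * _rexp(V - 40.0 - vth, 5.0)


@njit(cache=False)
def alpha_h(V: float, vth: float) -> float:
    return 0.128 * math.exp((17.0 - V + vth) / 18.0)


@njit(cache=False)
def beta_h(V: float, vth: float) -> float:
    return 4.0 / (1.0 + math.exp((40.0 - V + vth) / 5.0))


@njit(cache=False)
def alpha_n(V: float, vth: float) -> float:
    return 0.032 * _rexp(15.0 - V + vth, 5.0)


@njit(cache=False)
def beta_n(V: float, vth: float) -> float:
    return 0.5 * math.exp((10.0 - V + vth) / 40.0)


@njit(cache=False)
def m_inf(V: float, vth: float) -> float:
    a = alpha_m(V, vth)
    return a / (a + beta_m(V, vth))


@njit(cache=False)
def tau_m(V: float, vth: float) -> float:
    return 1.0 / (alpha_m(V, vth) + beta_m(V, vth))


@njit(cache=False)
def h_inf(V: float, vth: float) -> float:
    a = alpha_h(V, vth)
    return a / (a + beta_h(V, vth))


@njit(cache=False)
def tau_h(V: float, vth: float) -> float:
    return 1.0 / (alpha_h(V, vth) + beta_h(V, vth))


@njit(cache=False)
def n_inf(V: float, vth: float) -> float:
    a = alpha_n(V, vth)
    return a / (a + beta_n(V, vth))


@njit(cache=False)
def tau_n(V: float, vth: float) -> float:
    return 1.0 / (alpha_n(V, vth) + beta_n(V, vth))


@njit(cache=False)
def p_inf(V: float, vth: float) -> float:
    return 1.0 / (1.0 + math.exp((-52.0 - V + vth) / 7.4))


@njit(cache=False)
def tau_p(V: float, vth: float) -> float:
    return 3.0 + 1.0 / (
        math.exp((V + 27.0 - vth) / 10.0) + math.exp((-V - 102.0 + vth) / 15.0)
    )


@njit(cache=False)
def q_inf(V: float, vth: float) -> float:
    return 1.0 / (1.0 + math.exp((80.0 + V - vth) / 5.0))


@njit(cache=False)
def tau_q(V: float, vth: float) -> float:
    return 85.0 + 1.0 / (
        math.exp((V + 48.0 - vth) / 4.0) + math.exp((-V - 407.0 + vth) / 50.0)
    )


# --------------------------------------------- steady-state derivatives

@njit(cache=False)
def dm_inf(V: float, vth: float) -> float:
    a = alpha_m(V, vth)
    b = beta_m(V, vth)
    da = -0.32 * _drexp(13.0 - V + vth, 4.0)
    db = 0.28 * _drexp(V - 40.0 - vth, 5.0)
    s = a + b
    return (da * b - a * db) / (s * s)


@njit(cache=False)
def dh_inf(V: float, vth: float) -> float:
    a = alpha_h(V, vth)
    b = beta_h(V, vth)
    da = -a / 18.0
    sig = b / 4.0
    db = 0.8 * sig * (1.0 - sig)
    s = a + b
    return (da * b - a * db) / (s * s)


@njit(cache=False)
def dn_inf(V: float, vth: float) -> float:
    a = alpha_n(V, vth)
    b = beta_n(V, vth)
    da = -0.032 * _drexp(15.0 - V + vth, 5.0)
    db = -b / 40.0
    s = a + b
    return (da * b - a * db) / (s * s)


@njit(cache=False)
def dp_inf(V: float, vth: float) -> float:
    p = p_inf(V, vth)
    return p * (1.0 - p) / 7.4


@njit(cache=False)
def dq_inf(V: float, vth: float) -> float:
    q = q_inf(V, vth)
    return -q * (1.0 - q) / 5.0


# ------------------------------------------------------------ full model

@njit(cache=False)
def full_rhs(V, m, h, n, p, q, i_stim, P):
    """Time derivatives of the six-variable conductance model.

    ``i_stim`` is a current density in uA/cm2 (depolarizing positive).
    """
    i_na = P[P_GNA] * m * m * m * h * (V - P[P_ENA])
    i_k = P[P_GK] * n * n * n * n * (V - P[P_EK])
    i_t = P[P_GT] * p * p * q * (V - P[P_ET])
    i_l = P[P_GL] * (V - P[P_EL])
    i_kl = P[P_GKL] * (V - P[P_EKL])
    dV = (i_stim - (i_na + i_k + i_t + i_l + i_kl)) / P[P_C]
    vna = P[P_VTHNA]
    vk = P[P_VTHK]
    vt = P[P_VTHT]
    dm = P[P_PHIM] * (alpha_m(V, vna) * (1.0 - m) - beta_m(V, vna) * m)
    dh = P[P_PHIH] * (alpha_h(V, vna) * (1.0 - h) - beta_h(V, vna) * h)
    dn = P[P_PHIN] * (alpha_n(V, vk) * (1.0 - n) - beta_n(V, vk) * n)
    dp = P[P_PHIP] * (p_inf(V, vt) - p) / tau_p(V, vt)
    dq = P[P_PHIQ] * (q_inf(V, vt) - q) / tau_q(V, vt)
    return dV, dm, dh, dn, dp, dq


@njit(cache=False)
def integrate_full_rk4(state0, i_stim, t0, t1, dt, P):
    """Fixed-step RK4 on the full model over [t0, t1] at constant stimulus.

    Returns (t, Y) with Y of shape (n_steps+1, 6); gating variables are
    clamped to [0, 1] after each step.
    """
    n = max(1, int(round((t1 - t0) / dt)))
    dt = (t1 - t0) / n
    t = np.empty(n + 1)
    Y = np.empty((n + 1, 6))
    y = state0.copy()
    t[0] = t0
    Y[0] = y
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    tmp = np.empty(6)
    for i in range(n):
        r = full_rhs(y[0], y[1], y[2], y[3], y[4], y[5], i_stim, P)
        for j in range(6):
            k1[j] = r[j]
            tmp[j] = y[j] + 0.5 * dt * k1[j]
        r = full_rhs(tmp[0], tmp[1], tmp[2], tmp[3], tmp[4], tmp[5], i_stim, P)
        for j in range(6):
            k2[j] = r[j]
            tmp[j] = y[j] + 0.5 * dt * k2[j]
        r = full_rhs(tmp[0], tmp[1], tmp[2], tmp[3], tmp[4], tmp[5], i_stim, P)
        for j in range(6):
            k3[j] = r[j]
            tmp[j] = y[j] + dt * k3[j]
        r = full_rhs(tmp[0], tmp[1], tmp[2], tmp[3], tmp[4], tmp[5], i_stim, P)
        for j in range(6):
            k4[j] = r[j]
            y[j] = y[j] + dt * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) / 6.0
        for j in range(1, 6):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        t[i + 1] = t0 + (i + 1) * dt
        Y[i + 1] = y
    return t, Y


# --------------------------------------------------------- reduced model

@njit(cache=False)
def reduction_weights(x, y, z, P):
    """Grouping weights (rho_V, rho_m, rho_h, rho_n, rho_p) at a state.

    rho_p is pinned to k; rho_h and rho_n split (1-k) in proportion to the
    sensitivities dF/dv_h and dF/dv_n; rho_V solves the quadratic
    (F_V + F_m) r^2 - (a + F_V) r + a = 0 with a = C phi_m / tau_m(x),
    taking the branch continuous with the a/(a+F_V) limit and projecting
    onto [0, 1] if no root lands there.
    """
    vna = P[P_VTHNA]
    vk = P[P_VTHK]
    vt = P[P_VTHT]
    k = P[P_K]
    mi = m_inf(x, vna)
    hi = h_inf(y, vna)
    ni = n_inf(y, vk)
    pi_ = p_inf(y, vt)
    qi = q_inf(z, vt)

    FV = (
        P[P_GNA] * mi * mi * mi * hi
        + P[P_GK] * ni * ni * ni * ni
        + P[P_GT] * pi_ * pi_ * qi
        + P[P_GL]
        + P[P_GKL]
    )
    Fm = 3.0 * P[P_GNA] * mi * mi * dm_inf(x, vna) * hi * (x - P[P_ENA])
    Fh = P[P_GNA] * mi * mi * mi * dh_inf(y, vna) * (x - P[P_ENA])
    Fn = 4.0 * P[P_GK] * ni * ni * ni * dn_inf(y, vk) * (x - P[P_EK])

    # The closed-form split has a pole where Fh + Fn crosses zero and
    # violates the non-negativity constraints of the underlying
    # optimization on one side of it; the constrained optimum there sits
    # on the boundary (the gate with the wrong-signed sensitivity gets
    # weight 0, the other the whole 1 - k).
    denom_hn = Fh + Fn
    if abs(denom_hn) < 1e-300:
        rho_h = 0.5 * (1.0 - k)
        rho_n = 0.5 * (1.0 - k)
    else:
        rho_h = (1.0 - k) * Fh / denom_hn
        rho_n = (1.0 - k) * Fn / denom_hn
        if rho_h < 0.0:
            rho_h = 0.0
            rho_n = 1.0 - k
        elif rho_n < 0.0:
            rho_n = 0.0
            rho_h = 1.0 - k

    a = P[P_C] * P[P_PHIM] / tau_m(x, vna)
    qa = FV + Fm
    qb = -(a + FV)
    qc = a
    if abs(qa) < 1e-12:
        rho_v = a / (a + FV)
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0.0:
            disc = 0.0
        sq = math.sqrt(disc)
        r1 = ((a + FV) - sq) / (2.0 * qa)
        r2 = ((a + FV) + sq) / (2.0 * qa)
        if 0.0 <= r1 <= 1.0:
            rho_v = r1
        elif 0.0 <= r2 <= 1.0:
            rho_v = r2
        else:
            rho_v = r1
            if rho_v < 0.0:
                rho_v = 0.0
            elif rho_v > 1.0:
                rho_v = 1.0
    return rho_v, 1.0 - rho_v, rho_h, rho_n, k


@njit(cache=False)
def F_total(x, y, z, P):
    """Total ionic current through equivalent potentials, y shared by h,n,p."""
    vna = P[P_VTHNA]
    vk = P[P_VTHK]
    vt = P[P_VTHT]
    mi = m_inf(x, vna)
    hi = h_inf(y, vna)
    ni = n_inf(y, vk)
    pi_ = p_inf(y, vt)
    qi = q_inf(z, vt)
    return (
        P[P_GNA] * mi * mi * mi * hi * (x - P[P_ENA])
        + P[P_GK] * ni * ni * ni * ni * (x - P[P_EK])
        + P[P_GT] * pi_ * pi_ * qi * (x - P[P_ET])
        + P[P_GL] * (x - P[P_EL])
        + P[P_GKL] * (x - P[P_EKL])
    )


_RHO_V_FLOOR = 1e-6
# Voltages fed to the kinetics are clamped to this physical band and the
# steady-state slopes in the equivalent-potential denominators are floored
# (sign-preserving) so that trial stages of the adaptive integrator can
# never divide by an underflowed zero; accepted steps stay far inside the
# band under error control.  Derivatives are additionally capped at
# _RATE_CAP mV/ms: on-attractor trajectories peak near 1e3 mV/ms, so the
# cap only regularizes the near-saturated corners of state space where
# the equivalent-potential change of variables is singular.
_V_CLAMP = 300.0
_SLOPE_FLOOR = 1e-12
_RATE_CAP = 1e5


@njit(cache=False)
def _cap_rate(d: float) -> float:
    if d > _RATE_CAP:
        return _RATE_CAP
    if d < -_RATE_CAP:
        return -_RATE_CAP
    return d


@njit(cache=False)
def _clamp_v(v):
    if v > _V_CLAMP:
        return _V_CLAMP
    if v < -_V_CLAMP:
        return -_V_CLAMP
    return v


@njit(cache=False)
def _floor_slope(s):
    if s >= 0.0:
        return s if s > _SLOPE_FLOOR else _SLOPE_FLOOR
    return s if s < -_SLOPE_FLOOR else -_SLOPE_FLOOR


@njit(cache=False)
def reduced_rhs(x, y, z, i_stim, P):
    """Time derivatives (dx, dy, dz) of the three-variable reduced model."""
    x = _clamp_v(x)
    y = _clamp_v(y)
    z = _clamp_v(z)
    vna = P[P_VTHNA]
    vk = P[P_VTHK]
    vt = P[P_VTHT]
    rho_v, rho_m, rho_h, rho_n, rho_p = reduction_weights(x, y, z, P)
    if rho_v < _RHO_V_FLOOR:
        rho_v = _RHO_V_FLOOR
    dx = (i_stim - F_total(x, y, z, P)) / (P[P_C] * rho_v)

    dy = (
        rho_h * P[P_PHIH] * (h_inf(x, vna) - h_inf(y, vna))
        / (tau_h(x, vna) * _floor_slope(dh_inf(y, vna)))
        + rho_n * P[P_PHIN] * (n_inf(x, vk) - n_inf(y, vk))
        / (tau_n(x, vk) * _floor_slope(dn_inf(y, vk)))
        + rho_p * P[P_PHIP] * (p_inf(x, vt) - p_inf(y, vt))
        / (tau_p(x, vt) * _floor_slope(dp_inf(y, vt)))
    )
    dz = P[P_PHIQ] * (q_inf(x, vt) - q_inf(z, vt)) / (
        tau_q(x, vt) * _floor_slope(dq_inf(z, vt))
    )
    return _cap_rate(dx), _cap_rate(dy), _cap_rate(dz)


@njit(cache=False)
def integrate_reduced_rk4(state0, i_stim, t0, t1, dt, P):
    """Fixed-step RK4 on the reduced model; returns (t, Y) with Y (n+1, 3)."""
    n = max(1, int(round((t1 - t0) / dt)))
    dt = (t1 - t0) / n
    t = np.empty(n + 1)
    Y = np.empty((n + 1, 3))
    x, y, z = state0[0], state0[1], state0[2]
    t[0] = t0
    Y[0, 0] = x
    Y[0, 1] = y
    Y[0, 2] = z
    for i in range(n):
        a1, b1, c1 = reduced_rhs(x, y, z, i_stim, P)
        a2, b2, c2 = reduced_rhs(
            x + 0.5 * dt * a1, y + 0.5 * dt * b1, z + 0.5 * dt * c1, i_stim, P
        )
        a3, b3, c3 = reduced_rhs(
            x + 0.5 * dt * a2, y + 0.5 * dt * b2, z + 0.5 * dt * c2, i_stim, P
        )
        a4, b4, c4 = reduced_rhs(x + dt * a3, y + dt * b3, z + dt * c3, i_stim, P)
        x += dt * (a1 + 2.0 * a2 + 2.0 * a3 + a4) / 6.0
        y += dt * (b1 + 2.0 * b2 + 2.0 * b3 + b4) / 6.0
        z += dt * (c1 + 2.0 * c2 + 2.0 * c3 + c4) / 6.0
        t[i + 1] = t0 + (i + 1) * dt
        Y[i + 1, 0] = x
        Y[i + 1, 1] = y
        Y[i + 1, 2] = z
    return t, Y


@njit(cache=False)
def fast_rhs(x, y, z, i_stim, P):
    """(dx, dy) of the fast subsystem with the slow potential z frozen."""
    dx, dy, _dz = reduced_rhs(x, y, z, i_stim, P)
    return dx, dy


# ------------------------------------------- adaptive Dormand-Prince 5(4)

# Butcher tableau of the Dormand-Prince RK5(4) pair (the classic DOPRI5
# coefficients); the error estimator row is b5 - b4.
_DP_C2, _DP_C3, _DP_C4, _DP_C5 = 0.2, 0.3, 0.8, 8.0 / 9.0
_A21 = 0.2
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)

STATUS_OK = 0
STATUS_UNDERFLOW = 1
STATUS_MAXSTEPS = 2


@njit(cache=False)
def integrate_reduced_dp45(state0, i_stim, t0, t1, rtol, atol, max_step, P):
    """Adaptive RK5(4) on the reduced model at constant stimulus.

    Returns (t, Y, status, t_fail): accepted steps only; status is one of
    STATUS_OK / STATUS_UNDERFLOW / STATUS_MAXSTEPS.
    """
    cap = 65536
    T = np.empty(cap)
    Y = np.empty((cap, 3))
    x, y, z = state0[0], state0[1], state0[2]
    t = t0
    T[0] = t
    Y[0, 0] = x
    Y[0, 1] = y
    Y[0, 2] = z
    n = 1
    h = min(max_step, 1e-3)
    hmin = 1e-12 * (t1 - t0)
    f1x, f1y, f1z = reduced_rhs(x, y, z, i_stim, P)
    max_steps = 50_000_000
    it = 0
    while t < t1:
        it += 1
        if it > max_steps:
            return T[:n], Y[:n], STATUS_MAXSTEPS, t
        if h < hmin:
            return T[:n], Y[:n], STATUS_UNDERFLOW, t
        if t + h > t1:
            h = t1 - t

        f2x, f2y, f2z = reduced_rhs(
            x + h * _A21 * f1x, y + h * _A21 * f1y, z + h * _A21 * f1z, i_stim, P
        )
        f3x, f3y, f3z = reduced_rhs(
            x + h * (_A31 * f1x + _A32 * f2x),
            y + h * (_A31 * f1y + _A32 * f2y),
            z + h * (_A31 * f1z + _A32 * f2z),
            i_stim,
            P,
        )
        f4x, f4y, f4z = reduced_rhs(
            x + h * (_A41 * f1x + _A42 * f2x + _A43 * f3x),
            y + h * (_A41 * f1y + _A42 * f2y + _A43 * f3y),
            z + h * (_A41 * f1z + _A42 * f2z + _A43 * f3z),
            i_stim,
            P,
        )
        f5x, f5y, f5z = reduced_rhs(
            x + h * (_A51 * f1x + _A52 * f2x + _A53 * f3x + _A54 * f4x),
            y + h * (_A51 * f1y + _A52 * f2y + _A53 * f3y + _A54 * f4y),
            z + h * (_A51 * f1z + _A52 * f2z + _A53 * f3z + _A54 * f4z),
            i_stim,
            P,
        )
        f6x, f6y, f6z = reduced_rhs(
            x + h * (_A61 * f1x + _A62 * f2x + _A63 * f3x + _A64 * f4x + _A65 * f5x),
            y + h * (_A61 * f1y + _A62 * f2y + _A63 * f3y + _A64 * f4y + _A65 * f5y),
            z + h * (_A61 * f1z + _A62 * f2z + _A63 * f3z + _A64 * f4z + _A65 * f5z),
            i_stim,
            P,
        )
        xn = x + h * (_B1 * f1x + _B3 * f3x + _B4 * f4x + _B5 * f5x + _B6 * f6x)
        yn = y + h * (_B1 * f1y + _B3 * f3y + _B4 * f4y + _B5 * f5y + _B6 * f6y)
        zn = z + h * (_B1 * f1z + _B3 * f3z + _B4 * f4z + _B5 * f5z + _B6 * f6z)
        f7x, f7y, f7z = reduced_rhs(xn, yn, zn, i_stim, P)

        ex = h * (
            _E1 * f1x + _E3 * f3x + _E4 * f4x + _E5 * f5x + _E6 * f6x + _E7 * f7x
        )
        ey = h * (
            _E1 * f1y + _E3 * f3y + _E4 * f4y + _E5 * f5y + _E6 * f6y + _E7 * f7y
        )
        ez = h * (
            _E1 * f1z + _E3 * f3z + _E4 * f4z + _E5 * f5z + _E6 * f6z + _E7 * f7z
        )
        sx = atol + rtol * max(abs(x), abs(xn))
        sy = atol + rtol * max(abs(y), abs(yn))
        sz = atol + rtol * max(abs(z), abs(zn))
        err = math.sqrt(((ex / sx) ** 2 + (ey / sy) ** 2 + (ez / sz) ** 2) / 3.0)
        if not math.isfinite(err):
            h *= 0.1
            continue
        if err <= 1.0:
            t += h
            x, y, z = xn, yn, zn
            f1x, f1y, f1z = f7x, f7y, f7z
            if n >= cap:
                cap *= 2
                T2 = np.empty(cap)
                Y2 = np.empty((cap, 3))
                T2[:n] = T[:n]
                Y2[:n] = Y[:n]
                T = T2
                Y = Y2
            T[n] = t
            Y[n, 0] = x
            Y[n, 1] = y
            Y[n, 2] = z
            n += 1
            fac = 0.9 * err ** -0.2 if err > 1e-10 else 10.0
            h = min(h * min(fac, 10.0), max_step)
        else:
            h *= max(0.9 * err ** -0.2, 0.2)
    return T[:n], Y[:n], STATUS_OK, t1


@njit(cache=False)
def integrate_fast_dp45(x0, y0, z, i_stim, t0, t1, rtol, atol, max_step, P):
    """Adaptive RK5(4) on the frozen-z fast subsystem; see
    integrate_reduced_dp45 for the return convention (Y has 2 columns)."""
    cap = 65536
    T = np.empty(cap)
    Y = np.empty((cap, 2))
    x, y = x0, y0
    t = t0
    T[0] = t
    Y[0, 0] = x
    Y[0, 1] = y
    n = 1
    h = min(max_step, 1e-3)
    hmin = 1e-12 * (t1 - t0)
    f1x, f1y = fast_rhs(x, y, z, i_stim, P)
    max_steps = 50_000_000
    it = 0
    while t < t1:
        it += 1
        if it > max_steps:
            return T[:n], Y[:n], STATUS_MAXSTEPS, t
        if h < hmin:
            return T[:n], Y[:n], STATUS_UNDERFLOW, t
        if t + h > t1:
            h = t1 - t
        f2x, f2y = fast_rhs(x + h * _A21 * f1x, y + h * _A21 * f1y, z, i_stim, P)
        f3x, f3y = fast_rhs(
            x + h * (_A31 * f1x + _A32 * f2x),
            y + h * (_A31 * f1y + _A32 * f2y),
            z,
            i_stim,
            P,
        )
        f4x, f4y = fast_rhs(
            x + h * (_A41 * f1x + _A42 * f2x + _A43 * f3x),
            y + h * (_A41 * f1y + _A42 * f2y + _A43 * f3y),
            z,
            i_stim,
            P,
        )
        f5x, f5y = fast_rhs(
            x + h * (_A51 * f1x + _A52 * f2x + _A53 * f3x + _A54 * f4x),
            y + h * (_A51 * f1y + _A52 * f2y + _A53 * f3y + _A54 * f4y),
            z,
            i_stim,
            P,
        )
        f6x, f6y = fast_rhs(
            x + h * (_A61 * f1x + _A62 * f2x + _A63 * f3x + _A64 * f4x + _A65 * f5x),
            y + h * (_A61 * f1y + _A62 * f2y + _A63 * f3y + _A64 * f4y + _A65 * f5y),
            z,
            i_stim,
            P,
        )
        xn = x + h * (_B1 * f1x + _B3 * f3x + _B4 * f4x + _B5 * f5x + _B6 * f6x)
        yn = y + h * (_B1 * f1y + _B3 * f3y + _B4 * f4y + _B5 * f5y + _B6 * f6y)
        f7x, f7y = fast_rhs(xn, yn, z, i_stim, P)
        ex = h * (
            _E1 * f1x + _E3 * f3x + _E4 * f4x + _E5 * f5x + _E6 * f6x + _E7 * f7x
        )
        ey = h * (
            _E1 * f1y + _E3 * f3y + _E4 * f4y + _E5 * f5y + _E6 * f6y + _E7 * f7y
        )
        sx = atol + rtol * max(abs(x), abs(xn))
        sy = atol + rtol * max(abs(y), abs(yn))
        err = math.sqrt(((ex / sx) ** 2 + (ey / sy) ** 2) / 2.0)
        if not math.isfinite(err):
            h *= 0.1
            continue
        if err <= 1.0:
            t += h
            x, y = xn, yn
            f1x, f1y = f7x, f7y
            if n >= cap:
                cap *= 2
                T2 = np.empty(cap)
                Y2 = np.empty((cap, 2))
                T2[:n] = T[:n]
                Y2[:n] = Y[:n]
                T = T2
                Y = Y2
            T[n] = t
            Y[n, 0] = x
            Y[n, 1] = y
            n += 1
            fac = 0.9 * err ** -0.2 if err > 1e-10 else 10.0
            h = min(h * min(fac, 10.0), max_step)
        else:
            h *= max(0.9 * err ** -0.2, 0.2)
    return T[:n], Y[:n], STATUS_OK, t1


@njit(cache=False)
def integrate_fast_rk4(x0, y0, z, i_stim, t0, t1, dt, P):
    """Fixed-step RK4 on the frozen-z fast subsystem; returns (t, X, Y)."""
    n = max(1, int(round((t1 - t0) / dt)))
    dt = (t1 - t0) / n
    t = np.empty(n + 1)
    X = np.empty(n + 1)
    Y = np.empty(n + 1)
    x, y = x0, y0
    t[0] = t0
    X[0] = x
    Y[0] = y
    for i in range(n):
        a1, b1 = fast_rhs(x, y, z, i_stim, P)
        a2, b2 = fast_rhs(x + 0.5 * dt * a1, y + 0.5 * dt * b1, z, i_stim, P)
        a3, b3 = fast_rhs(x + 0.5 * dt * a2, y + 0.5 * dt * b2, z, i_stim, P)
        a4, b4 = fast_rhs(x + dt * a3, y + dt * b3, z, i_stim, P)
        x += dt * (a1 + 2.0 * a2 + 2.0 * a3 + a4) / 6.0
        y += dt * (b1 + 2.0 * b2 + 2.0 * b3 + b4) / 6.0
        t[i + 1] = t0 + (i + 1) * dt
        X[i + 1] = x
        Y[i + 1] = y
    return t, X, Y
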