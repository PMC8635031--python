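"""Voltage-dependent gating kinetics of the TRN conductance model.

Five gates are modelled: Na+ activation ``m`` and inactivation ``h``,
delayed-rectifier K+ activation ``n`` (all three in transition-rate
alpha/beta form), and the T-type Ca2+ activation ``p`` and inactivation
``q`` (steady-state/time-constant form).  Each gate relaxes as

    d(theta)/dt = phi * (theta_inf(V) - theta) / tau_theta(V)

with a dimensionless temperature-like factor ``phi``.

All functions accept scalars or numpy arrays of membrane potential in mV
and return rates in 1/ms, time constants in ms, or dimensionless
steady-state fractions.  Removable singularities of the form
u / (exp(u/c) - 1) are evaluated by their analytic limit near u = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

_SING_EPS = 1e-7


def _rexp(u, c):
    """u / (exp(u/c) - 1), with the limit c - u/2 + u^2/(12 c) near u = 0."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _SING_EPS
    safe = np.where(small, 1.0, u)
    out = np.where(
        small,
        c - 0.5 * u + u * u / (12.0 * c),
        safe / np.expm1(safe / c),
    )
    return out if out.ndim else float(out)


def _drexp(u, c):
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _SING_EPS
    safe = np.where(small, 1.0, u)
    e = np.expm1(safe / c)
    out = np.where(small, -0.5 + u / (6.0 * c), (e - safe * (e + 1.0) / c) / (e * e))
    return out if out.ndim else float(out)


def _logistic(w):
    return 1.0 / (1.0 + np.exp(w))


@dataclass(frozen=True)
class ChannelKinetics:
    """Kinetics of one gating variable.

    ``form`` is ``"alpha-beta"`` (m, h, n) or ``"inf-tau"`` (p, q); the
    voltage threshold ``vth`` (mV) shifts the curves along the voltage
    axis (spike threshold for m/h/n, Ca2+ channel threshold for p/q).
    """

    name: str
    phi: float
    form: str
    vth: float
    _inf: Callable
    _tau: Callable
    _dinf: Callable
    _alpha: Callable | None = None
    _beta: Callable | None = None
    increasing: bool = True

    def alpha(self, V):
        if self._alpha is None:
            raise ValueError(f"gate {self.name!r} has no alpha/beta form")
        return self._alpha(V, self.vth)

    def beta(self, V):
        if self._beta is None:
            raise ValueError(f"gate {self.name!r} has no alpha/beta form")
        return self._beta(V, self.vth)

    def inf(self, V):
        return self._inf(V, self.vth)

    def tau(self, V):
        return self._tau(V, self.vth)

    def dinf(self, V):
        """d(theta_inf)/dV, analytic."""
        return self._dinf(V, self.vth)

    def inv_inf(self, fraction: float) -> float:
        """Equivalent potential: the voltage v with theta_inf(v) = fraction.

        Unique by strict monotonicity of the steady-state curve.  Inputs
        are clamped to the open interval (1e-12, 1 - 1e-12).
        """
        f = float(fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"gating fraction {f} outside [0, 1]")
        eps = 1e-12
        f = min(max(f, eps), 1.0 - eps)
        lo, hi = -400.0, 250.0
        g = lambda v: float(self.inf(v)) - f
        glo, ghi = g(lo), g(hi)
        if glo * ghi > 0:  # pragma: no cover - curves saturate well inside
            raise ValueError(f"fraction {f} unreachable for gate {self.name!r}")
        return float(brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


# -- alpha/beta expressions (vectorized references of trnkit._fastmath) --

def _alpha_m(V, vth):
    return 0.32 * _rexp(13.0 - np.asarray(V, float) + vth, 4.0)


def _beta_m(V, vth):
    return 0.28 * _rexp(np.asarray(V, float) - 40.0 - vth, 5.0)


def _alpha_h(V, vth):
    return 0.128 * np.exp((17.0 - np.asarray(V, float) + vth) / 18.0)


def _beta_h(V, vth):
    return 4.0 * _logistic((40.0 - np.asarray(V, float) + vth) / 5.0)


def _alpha_n(V, vth):
    return 0.032 * _rexp(15.0 - np.asarray(V, float) + vth, 5.0)


def _beta_n(V, vth):
    return 0.5 * np.exp((10.0 - np.asarray(V, float) + vth) / 40.0)


def _ab_inf(alpha, beta):
    def f(V, vth):
        a = alpha(V, vth)
        return a / (a + beta(V, vth))

    return f


def _ab_tau(alpha, beta):
    def f(V, vth):
        return 1.0 / (alpha(V, vth) + beta(V, vth))

    return f


def _dm_inf(V, vth):
    V = np.asarray(V, float)
    a, b = _alpha_m(V, vth), _beta_m(V, vth)
    da = -0.32 * _drexp(13.0 - V + vth, 4.0)
    db = 0.28 * _drexp(V - 40.0 - vth, 5.0)
    return (da * b - a * db) / (a + b) ** 2


def _dh_inf(V, vth):
    V = np.asarray(V, float)
    a, b = _alpha_h(V, vth), _beta_h(V, vth)
    da = -a / 18.0
    sig = b / 4.0
    db = 0.8 * sig * (1.0 - sig)
    return (da * b - a * db) / (a + b) ** 2


def _dn_inf(V, vth):
    V = np.asarray(V, float)
    a, b = _alpha_n(V, vth), _beta_n(V, vth)
    da = -0.032 * _drexp(15.0 - V + vth, 5.0)
    db = -b / 40.0
    return (da * b - a * db) / (a + b) ** 2


def _p_inf(V, vth):
    return _logistic((-52.0 - np.asarray(V, float) + vth) / 7.4)


def _tau_p(V, vth):
    V = np.asarray(V, float)
    return 3.0 + 1.0 / (
        np.exp((V + 27.0 - vth) / 10.0) + np.exp((-V - 102.0 + vth) / 15.0)
    )


def _dp_inf(V, vth):
    p = _p_inf(V, vth)
    return p * (1.0 - p) / 7.4


def _q_inf(V, vth):
    return _logistic((80.0 + np.asarray(V, float) - vth) / 5.0)


def _tau_q(V, vth):
    V = np.asarray(V, float)
    return 85.0 + 1.0 / (
        np.exp((V + 48.0 - vth) / 4.0) + np.exp((-V - 407.0 + vth) / 50.0)
    )


def _dq_inf(V, vth):
    q = _q_inf(V, vth)
    return -q * (1.0 - q) / 5.0


def standard_kinetics(
    VthNa: float = -55.0,
    VthK: float = -55.0,
    VthT: float = -3.0,
    phi_p: float = 6.9,
    phi_q: float = 3.7,
) -> dict[str, ChannelKinetics]:
    """The five TRN gates with the given kinetic shift thresholds (mV)."""
    return {
        "m": ChannelKinetics(
            "m", 1.0, "alpha-beta", VthNa,
            _ab_inf(_alpha_m, _beta_m), _ab_tau(_alpha_m, _beta_m), _dm_inf,
            _alpha_m, _beta_m, increasing=True,
        ),
        "h": ChannelKinetics(
            "h", 1.0, "alpha-beta", VthNa,
            _ab_inf(_alpha_h, _beta_h), _ab_tau(_alpha_h, _beta_h), _dh_inf,
            _alpha_h, _beta_h, increasing=False,
        ),
        "n": ChannelKinetics(
            "n", 1.0, "alpha-beta", VthK,
            _ab_inf(_alpha_n, _beta_n), _ab_tau(_alpha_n, _beta_n), _dn_inf,
            _alpha_n, _beta_n, increasing=True,
        ),
        "p": ChannelKinetics(
            "p", phi_p, "inf-tau", VthT, _p_inf, _tau_p, _dp_inf, increasing=True,
        ),
        "q": ChannelKinetics(
            "q", phi_q, "inf-tau", VthT, _q_inf, _tau_q, _dq_inf, increasing=False,
        ),
    }


def kinetics_for(params) -> dict[str, ChannelKinetics]:
    """Gate kinetics matching a :class:`trnkit.params.ModelParams`."""
    return standard_kinetics(
        params.VthNa, params.VthK, params.VthT, params.phi_p, params.phi_q
    )


def rate_value(kin: ChannelKinetics, which: str, V):
    """Evaluate one kinetic function: 'alpha', 'beta', 'inf' or 'tau'."""
    try:
        fn = {"alpha": kin.alpha, "beta": kin.beta, "inf": kin.inf, "tau": kin.tau}[
            which
        ]
    except KeyError:
        raise ValueError(f"unknown kinetic function {which!r}") from None
    return fn(V)
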