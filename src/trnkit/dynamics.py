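"""Fast-slow bifurcation analysis of the reduced TRN model.

The reduced system (x, y, z) separates into a fast (x, y) subsystem and
the slow T-channel de-inactivation potential z.  Freezing z as a
parameter, the fast subsystem's equilibria are the roots of the
current-voltage relation

    I(V, z) = F(V, y=V, z) - I_syn

(the y-nullcline is exactly the diagonal y = x, so fast equilibria sit
at y = V).  This module locates those roots, classifies their stability,
probes for the spiking limit cycle by direct simulation, and finds the
bifurcations that organize rebound bursting and tonic spiking: folds of
equilibria, saddle homoclinic orbits, folds of limit cycles, and
Andronov-Hopf points of the full three-variable system along the
stimulus axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from . import _fastmath as fm
from .channels import kinetics_for
from .params import ModelParams
from .spikes import burst_statistics, detect_spikes

DEFAULT_V_RANGE = (-100.0, 20.0)
DEFAULT_V_GRID = 0.05

# All I_syn arguments in this module are in the model's native stimulus
# units (nA, the numbers quoted with the protocols); they enter the
# membrane equation as densities via the 1e-3/A normalization.


def _dens(I_syn: float, params: ModelParams) -> float:
    return 1e-3 * I_syn / params.A


# ------------------------------------------------------------------ types

@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the fast (x, y) or full (x, y, z) system."""

    V: float
    y: float
    z: float
    subsystem: str  # "fast-2D" | "full-3D"
    eigenvalues: tuple
    classification: str
    residual: float
    marginal: bool = False


@dataclass(frozen=True)
class BifurcationPoint:
    """A located critical parameter value.

    ``kind`` is one of fold / saddle-homoclinic / fold-cycle / hopf;
    ``param_axis`` is "z" (mV) or "I_syn" (native stimulus units); the
    bracket is the final bisection interval containing the value.
    """

    kind: str
    param_axis: str
    value: float
    bracket: tuple[float, float]
    tol: float
    method: str
    info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "type": self.kind,
            "parameter_axis": self.param_axis,
            "value": self.value,
            "bracket": list(self.bracket),
            "tolerance": self.tol,
            "method": self.method,
        }


@dataclass(frozen=True)
class CycleProbe:
    """Outcome of a simulation-based limit-cycle existence test."""

    status: str  # "cycle" | "no-cycle" | "inconclusive"
    V_max: float = float("nan")
    V_min: float = float("nan")
    period: float = float("nan")
    n_spikes: int = 0
    end_state: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def exists(self) -> bool:
        if self.status == "inconclusive":
            raise RuntimeError("limit-cycle probe was inconclusive")
        return self.status == "cycle"


@dataclass
class BranchPoint:
    """One grid point of a one-parameter diagram."""

    param: float
    equilibria: list[FixedPoint]
    regime_rest: str
    regime_spike: str
    V_max: float
    V_min: float


@dataclass
class BranchDiagram:
    param_name: str
    grid: np.ndarray
    points: list[BranchPoint]
    bifurcations: list[BifurcationPoint]


# ------------------------------------------------------- I-V and equilibria

def iv_relation(V, z: float, params: ModelParams | None = None, I_syn: float = 0.0):
    """Net membrane current I(V, z) (uA/cm2) with y clamped to the
    diagonal y = V; its zeros are the fast-subsystem equilibria."""
    params = params or ModelParams()
    kin = kinetics_for(params)
    V = np.asarray(V, dtype=float)
    mi = kin["m"].inf(V)
    hi = kin["h"].inf(V)
    ni = kin["n"].inf(V)
    pi_ = kin["p"].inf(V)
    qi = kin["q"].inf(z)
    out = (
        params.gNa * mi**3 * hi * (V - params.ENa)
        + params.gK * ni**4 * (V - params.EK)
        + params.gT * pi_**2 * qi * (V - params.ET)
        + params.gL * (V - params.EL)
        + params.gKL * (V - params.EKL)
        - _dens(I_syn, params)
    )
    return out if out.ndim else float(out)


def find_iv_roots(
    z: float,
    I_syn: float = 0.0,
    params: ModelParams | None = None,
    V_range: tuple[float, float] = DEFAULT_V_RANGE,
    grid_step: float = DEFAULT_V_GRID,
) -> list[float]:
    """All roots of I(V, z) = 0 on the range (grid sign-scan + brentq).

    Interior near-tangencies (local minima of |I| without a sign change)
    are rescanned on a 10x finer local grid so that barely-separated
    fold pairs are still counted.
    """
    params = params or ModelParams()
    lo, hi = V_range
    Vs = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = iv_relation(Vs, z, params, I_syn)
    roots = _scan_roots(Vs, vals, lambda v: iv_relation(v, z, params, I_syn))
    return sorted(roots)


def _scan_roots(Vs, vals, f, depth: int = 0) -> list[float]:
    roots: list[float] = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(float(brentq(f, Vs[i], Vs[i + 1], xtol=1e-10)))
    for i in np.nonzero(sign == 0)[0]:
        roots.append(float(Vs[i]))
    if depth < 1:
        # near-tangent pairs hiding inside one grid cell
        absv = np.abs(vals)
        step = Vs[1] - Vs[0]
        for i in range(1, len(Vs) - 1):
            if absv[i] < absv[i - 1] and absv[i] < absv[i + 1] and absv[i] < 0.05:
                if any(Vs[i - 1] <= r <= Vs[i + 1] for r in roots):
                    continue
                sub = np.linspace(Vs[i - 1], Vs[i + 1], 41)
                roots.extend(
                    r
                    for r in _scan_roots(sub, np.array([f(v) for v in sub]), f, depth + 1)
                    if not any(abs(r - r0) < 1e-8 for r0 in roots)
                )
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 1e-7:
            uniq.append(r)
    return uniq


def classify_stability(eigenvalues, tol: float = 1e-9) -> tuple[str, bool]:
    """Node/focus/saddle label from eigenvalues; ``marginal`` flags a
    real part within ``tol`` of zero."""
    eig = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    re, im = eig.real, eig.imag
    marginal = bool(np.any(np.abs(re) < tol))
    has_pair = bool(np.any(np.abs(im) > 0))
    if has_pair:
        label = "stable focus" if np.all(re < 0) else "unstable focus"
    elif np.all(re < 0):
        label = "stable node"
    elif np.all(re > 0):
        label = "unstable node"
    else:
        label = "saddle"
    return label, marginal


def fast_jacobian(
    x: float, y: float, z: float, I_syn: float, params: ModelParams, eps: float = 1e-6
) -> np.ndarray:
    """Jacobian of the frozen-z fast subsystem by central differences."""
    P = params.as_array()
    J = np.empty((2, 2))
    dens = _dens(I_syn, params)
    for j, (dx, dy) in enumerate(((eps, 0.0), (0.0, eps))):
        fp = fm.fast_rhs(x + dx, y + dy, z, dens, P)
        fmn = fm.fast_rhs(x - dx, y - dy, z, dens, P)
        J[0, j] = (fp[0] - fmn[0]) / (2 * eps)
        J[1, j] = (fp[1] - fmn[1]) / (2 * eps)
    return J


def reduced_jacobian(
    x: float, y: float, z: float, I_syn: float, params: ModelParams, eps: float = 1e-6
) -> np.ndarray:
    """Jacobian of the full three-variable system by central differences."""
    P = params.as_array()
    J = np.empty((3, 3))
    dens = _dens(I_syn, params)
    for j in range(3):
        d = np.zeros(3)
        d[j] = eps
        fp = fm.reduced_rhs(x + d[0], y + d[1], z + d[2], dens, P)
        fmn = fm.reduced_rhs(x - d[0], y - d[1], z - d[2], dens, P)
        for i in range(3):
            J[i, j] = (fp[i] - fmn[i]) / (2 * eps)
    return J


def find_equilibria_fast(
    z: float,
    I_syn: float = 0.0,
    params: ModelParams | None = None,
    V_range: tuple[float, float] = DEFAULT_V_RANGE,
) -> list[FixedPoint]:
    """Fast-subsystem equilibria (on the diagonal y = V) with their 2x2
    eigenvalues and classification, in increasing V order."""
    params = params or ModelParams()
    P = params.as_array()
    pts = []
    for V in find_iv_roots(z, I_syn, params, V_range):
        J = fast_jacobian(V, V, z, I_syn, params)
        eig = np.linalg.eigvals(J)
        label, marginal = classify_stability(eig)
        res = float(np.max(np.abs(fm.fast_rhs(V, V, z, _dens(I_syn, params), P))))
        pts.append(
            FixedPoint(V, V, z, "fast-2D", tuple(eig), label, res, marginal)
        )
    return pts


def global_equilibria(
    I_syn: float = 0.0,
    params: ModelParams | None = None,
    V_range: tuple[float, float] = DEFAULT_V_RANGE,
) -> list[FixedPoint]:
    """Equilibria of the full three-variable system.

    Both the y- and z-nullclines are the diagonal, so global equilibria
    satisfy x = y = z = V with I(V, V) = 0; they are classified with the
    3x3 Jacobian.
    """
    params = params or ModelParams()
    P = params.as_array()

    def g(V):
        return iv_relation(V, V, params, I_syn)

    lo, hi = V_range
    Vs = np.arange(lo, hi + DEFAULT_V_GRID / 2, DEFAULT_V_GRID)
    vals = np.array([g(v) for v in Vs])
    pts = []
    for V in _scan_roots(Vs, vals, g):
        J = reduced_jacobian(V, V, V, I_syn, params)
        eig = np.linalg.eigvals(J)
        label, marginal = classify_stability(eig)
        res = float(np.max(np.abs(fm.reduced_rhs(V, V, V, _dens(I_syn, params), P))))
        pts.append(FixedPoint(V, V, V, "full-3D", tuple(eig), label, res, marginal))
    return pts


# ------------------------------------------------------- limit-cycle probe

def limit_cycle_probe(
    z: float,
    I_syn: float = 0.0,
    params: ModelParams | None = None,
    x0: float = -20.0,
    y0: float | None = None,
    init: tuple[float, float] | None = None,
    transient: float = 200.0,
    window: float = 500.0,
    threshold: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_extensions: int = 3,
) -> CycleProbe:
    """Simulation-based test for the fast-subsystem spiking limit cycle.

    Integrates from a superthreshold state — the standardized (x0, y0=z)
    by default, or an explicit ``init`` (used by the boundary detectors
    to continue an on-cycle state across a parameter sweep, mirroring the
    hysteresis of the slow dynamics) — skips a transient, and decides
    from the persistence of upward threshold crossings: "cycle" when
    crossings continue to the end of the window, "no-cycle" when the
    trajectory has stopped crossing and settled subthreshold.  The window
    doubles (up to ``max_extensions`` times) when the evidence is
    ambiguous; an undecided probe reports "inconclusive", never silently
    absent.
    """
    params = params or ModelParams()
    P = params.as_array()
    if init is not None:
        state = (float(init[0]), float(init[1]))
    else:
        state = (x0, z if y0 is None else y0)
    t_start = 0.0
    horizon = transient + window
    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    dens = _dens(I_syn, params)
    stable_eqs = [
        e
        for e in find_equilibria_fast(z, I_syn, params)
        if e.classification.startswith("stable")
    ]
    for _ in range(max_extensions + 1):
        t, XY, status, t_fail = fm.integrate_fast_dp45(
            state[0], state[1], z, dens, t_start, horizon, rtol, atol, 0.1, P
        )
        if status != fm.STATUS_OK:  # pragma: no cover - defensive
            raise RuntimeError(f"fast-subsystem integration failed at t={t_fail:.3f}")
        ts.append(t if not ts else t[1:])
        xs.append(XY[:, 0] if len(xs) == 0 else XY[1:, 0])
        state = (XY[-1, 0], XY[-1, 1])
        tt = np.concatenate(ts)
        xx = np.concatenate(xs)
        train = detect_spikes((tt, xx), threshold=threshold)
        up = train.times[train.times > transient]
        t_end = tt[-1]
        if up.size >= 3:
            isis = np.diff(up)
            recent = float(np.median(isis[-3:]))
            if t_end - up[-1] < 2.0 * recent:
                # periodic: measure over the last full cycle
                sel = tt >= up[-1] - recent
                return CycleProbe(
                    "cycle",
                    float(xx[sel].max()),
                    float(xx[sel].min()),
                    recent,
                    int(up.size),
                    state,
                )
        # absence of a spiking attractor: no crossing for a long tail, the
        # recent excursion subthreshold, and the trajectory parked at a
        # stable fast equilibrium (a slow fold-ghost passage is quiet too,
        # but has no stable point to settle on and must spike again)
        tail = max(200.0, 4.0 * _last_isi(up))
        quiet = up.size == 0 or (t_end - up[-1]) > tail
        sel = tt >= t_end - min(tail, t_end - transient)
        if quiet and xx[sel].max() < threshold:
            if any(
                abs(state[0] - e.V) < 1.0 and abs(state[1] - e.y) < 1.0
                for e in stable_eqs
            ):
                return CycleProbe("no-cycle", n_spikes=int(up.size), end_state=state)
            if not stable_eqs and up.size >= 1:
                # nowhere to rest: the spiking orbit persists with a very
                # long (ghost-dominated) period
                return CycleProbe(
                    "cycle",
                    float(xx.max()),
                    float(xx.min()),
                    float(_last_isi(up)) if up.size >= 2 else float("nan"),
                    int(up.size),
                    state,
                )
        t_start = t_end
        horizon = t_end + 2 * window
    return CycleProbe("inconclusive", n_spikes=int(up.size), end_state=state)


def _last_isi(up: np.ndarray) -> float:
    return float(up[-1] - up[-2]) if up.size >= 2 else 50.0


def _cycle_boundary(
    I_syn: float,
    params: ModelParams,
    z_bracket: tuple[float, float],
    tol: float,
    probe_kw: dict,
    n_march: int = 8,
) -> tuple[float, float, float, tuple[float, float]]:
    """Locate the z where the spiking cycle is lost, tracking the cycle.

    Marches z from the cycle side toward the cycle-free side carrying the
    end state of each on-cycle probe as the next initial condition (the
    discrete analogue of the slow drift along the spiking branch), then
    bisects the losing step the same way.  Returns (lo, hi, z_cycle_side,
    on-cycle state) with the cycle surviving at one bracket end.
    """
    lo, hi = z_bracket
    p_lo = limit_cycle_probe(lo, I_syn, params, **probe_kw)
    p_hi = limit_cycle_probe(hi, I_syn, params, **probe_kw)
    if p_lo.exists == p_hi.exists:
        raise ValueError("cycle existence does not change across the z bracket")
    z_cyc, z_no = (lo, hi) if p_lo.exists else (hi, lo)
    state = (p_lo if p_lo.exists else p_hi).end_state

    # march toward the cycle-free side with the inherited on-cycle state
    for zz in np.linspace(z_cyc, z_no, n_march + 1)[1:-1]:
        pr = limit_cycle_probe(zz, I_syn, params, init=state, **probe_kw)
        if pr.exists:
            z_cyc, state = float(zz), pr.end_state
        else:
            z_no = float(zz)
            break
    while abs(z_no - z_cyc) > tol:
        mid = 0.5 * (z_cyc + z_no)
        pr = limit_cycle_probe(mid, I_syn, params, init=state, **probe_kw)
        if pr.exists:
            z_cyc, state = mid, pr.end_state
        else:
            z_no = mid
    return min(z_cyc, z_no), max(z_cyc, z_no), z_cyc, state


# --------------------------------------------------------------- detectors

def _bisect_predicate(pred, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Bisect a boolean predicate that differs at lo and hi."""
    plo = pred(lo)
    if pred(hi) == plo:
        raise ValueError("predicate does not change across the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pred(mid) == plo:
            lo = mid
        else:
            hi = mid
    return lo, hi


def _div_dV(f, V: float, eps: float = 1e-6) -> float:
    return (f(V + eps) - f(V - eps)) / (2 * eps)


def find_fold(
    I_syn: float = 0.0,
    params: ModelParams | None = None,
    z_bracket: tuple[float, float] = (-80.0, -60.0),
    tol: float = 1e-3,
    V_range: tuple[float, float] = DEFAULT_V_RANGE,
) -> BifurcationPoint:
    """Fold (saddle-node) of the fast subsystem: the z where the stable
    node and the saddle of I(V, z) coalesce.

    Bisection on the root count of the I-V relation, then a Newton polish
    of the tangency system I = 0, dI/dV = 0 in (V, z).
    """
    params = params or ModelParams()

    def count(zz):
        return len(find_iv_roots(zz, I_syn, params, V_range))

    lo, hi = z_bracket
    if count(lo) == count(hi):
        raise ValueError("root count does not change across the z bracket")
    blo, bhi = _bisect_predicate(lambda zz: count(zz) == count(lo), lo, hi, tol)
    z_est = 0.5 * (blo + bhi)

    # coalescence voltage: on the many-root side the two merging roots are
    # the closest pair
    side = blo if count(blo) > count(bhi) else bhi
    roots = find_iv_roots(side, I_syn, params, V_range)
    gaps = np.diff(roots)
    V_est = 0.5 * (roots[int(np.argmin(gaps))] + roots[int(np.argmin(gaps)) + 1])

    def tangency(u):
        V, zz = u
        f = lambda vv: iv_relation(vv, zz, params, I_syn)
        return [f(V), _div_dV(f, V)]

    sol = root(tangency, [V_est, z_est], method="hybr", tol=1e-12)
    info = {"V_fold": float(sol.x[0]), "polished": bool(sol.success)}
    z_val = float(sol.x[1]) if sol.success and abs(sol.x[1] - z_est) < 50 * tol else z_est
    if sol.success:
        f = lambda vv: iv_relation(vv, z_val, params, I_syn)
        info["residual_I"] = abs(f(sol.x[0]))
        info["residual_dIdV"] = abs(_div_dV(f, sol.x[0]))
    return BifurcationPoint(
        "fold", "z", z_val, (blo, bhi), tol, "root-count bisection + tangency Newton",
        info,
    )


def find_homoclinic(
    I_syn: float = 0.0,
    params: ModelParams | None = None,
    z_bracket: tuple[float, float] = (-66.0, -60.0),
    tol: float = 1e-2,
    confirm_divergence: bool = True,
    **probe_kw,
) -> BifurcationPoint:
    """Saddle homoclinic orbit bifurcation: the z where the fast
    subsystem's spiking cycle dies against the saddle.

    Bisection on cycle existence; the equilibrium count must not change
    across the final bracket (otherwise the event is a fold and is
    reclassified), and the cycle period must grow toward the critical z
    (logarithmic divergence signature).
    """
    params = params or ModelParams()
    blo, bhi, z_cyc, state = _cycle_boundary(I_syn, params, z_bracket, tol, probe_kw)
    z_val = 0.5 * (blo + bhi)

    n_lo = len(find_iv_roots(blo - 5 * tol, I_syn, params))
    n_hi = len(find_iv_roots(bhi + 5 * tol, I_syn, params))
    kind = "saddle-homoclinic"
    info: dict = {}
    if n_lo != n_hi:
        kind = "fold"  # cycle loss coincides with an equilibrium-count change
        info["reclassified"] = "equilibrium count changes across bracket"
    elif confirm_divergence:
        inward = -1.0 if z_cyc < z_val else 1.0
        near = limit_cycle_probe(
            z_val + inward * 0.05, I_syn, params, init=state, **probe_kw
        )
        far = limit_cycle_probe(
            z_val + inward * 0.5, I_syn, params, init=state, **probe_kw
        )
        info["period_near"] = near.period
        info["period_far"] = far.period
        if (
            np.isfinite(near.period)
            and np.isfinite(far.period)
            and near.period < 1.5 * far.period
        ):
            kind = "fold-cycle"
            info["reclassified"] = "no period divergence near the critical z"
    return BifurcationPoint(
        kind, "z", z_val, (blo, bhi), tol, "tracked cycle-existence bisection", info
    )


def find_fold_cycle(
    I_syn: float = 0.0,
    params: ModelParams | None = None,
    z_bracket: tuple[float, float] = (-60.0, -50.0),
    tol: float = 1e-2,
    **probe_kw,
) -> BifurcationPoint:
    """Fold of limit cycles along z: the spiking cycle vanishes with
    finite period and no saddle connection."""
    params = params or ModelParams()
    blo, bhi, z_cyc, state = _cycle_boundary(I_syn, params, z_bracket, tol, probe_kw)
    z_val = 0.5 * (blo + bhi)
    inward = -1.0 if z_cyc < z_val else 1.0
    span = abs(z_bracket[1] - z_bracket[0])
    near = limit_cycle_probe(
        z_val + inward * 0.05, I_syn, params, init=state, **probe_kw
    )
    inside = limit_cycle_probe(
        z_val + inward * 0.1 * span, I_syn, params, init=state, **probe_kw
    )
    info = {"period_near": near.period, "period_inside": inside.period}
    kind = "fold-cycle"
    n_cyc = len(find_iv_roots(z_val + inward * 5 * tol, I_syn, params))
    n_no = len(find_iv_roots(z_val - inward * 5 * tol, I_syn, params))
    if n_cyc != n_no:
        # the spiking branch terminates where new fixed points are born on
        # or next to the cycle; the period may lengthen through the ghost
        # but the event is the fold, not a saddle connection
        info["coincides_with_equilibrium_fold"] = True
    elif (
        np.isfinite(near.period)
        and np.isfinite(inside.period)
        and near.period >= 2.0 * inside.period
    ):
        kind = "saddle-homoclinic"
        info["reclassified"] = "period divergence at the boundary"
    return BifurcationPoint(
        kind, "z", z_val, (blo, bhi), tol, "tracked cycle-existence bisection", info
    )


# -------------------------------------------- one-parameter (I_syn) analysis

def lowest_equilibrium(I_syn: float, params: ModelParams) -> FixedPoint:
    eqs = global_equilibria(I_syn, params)
    if not eqs:
        raise ValueError(f"no global equilibrium at I_syn={I_syn}")
    return eqs[0]


def _pair_max_re(fp: FixedPoint) -> float:
    eig = np.asarray(fp.eigenvalues, dtype=complex)
    pair = eig[np.abs(eig.imag) > 1e-12]
    if pair.size == 0:
        return float("nan")
    return float(np.max(pair.real))


def find_hopf(
    params: ModelParams | None = None,
    I_syn_range: tuple[float, float] = (-0.08, 0.01),
    grid_step: float = 0.002,
    tol: float = 1e-4,
    classify: bool = False,
) -> list[BifurcationPoint]:
    """Andronov-Hopf points of the lowest global equilibrium along I_syn.

    Tracks the real part of the 3x3 Jacobian's complex pair on a grid and
    refines each sign change by bisection.  With ``classify=True`` a
    small-orbit simulation just past each crossing labels it super- or
    sub-critical.
    """
    params = params or ModelParams()

    def pre(i):
        return _pair_max_re(lowest_equilibrium(i, params))

    lo, hi = I_syn_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = np.array([pre(i) for i in grid])
    out: list[BifurcationPoint] = []
    for i in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        a, b = grid[i], grid[i + 1]
        val = float(brentq(pre, a, b, xtol=1e-8))
        fp = lowest_equilibrium(val, params)
        info = {
            "equilibrium_V": fp.V,
            "pair_re": _pair_max_re(fp),
            "pair_im": float(
                np.max(np.abs(np.asarray(fp.eigenvalues, complex).imag))
            ),
        }
        if classify:
            info["supercritical"] = _hopf_small_orbit_is_stable(val, params)
        out.append(
            BifurcationPoint(
                "hopf", "I_syn", val, (val - tol, val + tol), tol,
                "eigenvalue sign-change bisection", info,
            )
        )
    return out


def _hopf_small_orbit_is_stable(i_hopf: float, params: ModelParams) -> bool:
    """Numerical criterion for a supercritical Hopf: just inside the
    unstable side a small perturbation settles onto a bounded orbit
    rather than escaping the neighbourhood immediately."""
    P = params.as_array()
    eps = 2e-4
    for side in (i_hopf + eps, i_hopf - eps):
        fp = lowest_equilibrium(side, params)
        if _pair_max_re(fp) > 0:
            _, Y, status, _ = fm.integrate_reduced_dp45(
                np.array([fp.V + 0.5, fp.V, fp.V]), _dens(side, params), 0.0,
                3000.0, 1e-8, 1e-10, 0.1, P,
            )
            if status != fm.STATUS_OK:  # pragma: no cover
                return False
            tail = Y[int(0.7 * len(Y)):, 0]
            return bool(np.all(np.isfinite(tail)))
    return False


def spike_start_state(
    params: ModelParams, I_ref: float = 0.14, settle: float = 1000.0
) -> np.ndarray:
    """A standardized on-attractor spiking state: the endpoint of a run
    under a strong depolarizing current where only the tonic cycle exists."""
    P = params.as_array()
    _, Y, status, _ = fm.integrate_reduced_dp45(
        np.array([-70.0, -70.0, -70.0]), _dens(I_ref, params), 0.0, settle,
        1e-8, 1e-10, 0.1, P,
    )
    if status != fm.STATUS_OK:  # pragma: no cover
        raise RuntimeError("spike-start preparation failed")
    return Y[-1]


def rest_start_state(params: ModelParams, settle: float = 2000.0) -> np.ndarray:
    """A standardized rest state: zero-stimulus relaxation endpoint."""
    P = params.as_array()
    _, Y, status, _ = fm.integrate_reduced_dp45(
        np.array([-70.0, -70.0, -70.0]), 0.0, 0.0, settle, 1e-8, 1e-10, 0.1, P
    )
    if status != fm.STATUS_OK:  # pragma: no cover
        raise RuntimeError("rest-start preparation failed")
    return Y[-1]


def near_equilibrium_state(
    params: ModelParams, I_syn: float, perturb: float = 0.1
) -> np.ndarray:
    """The lowest global equilibrium at this stimulus, nudged by
    ``perturb`` mV in x — the rest-attractor occupant for dual-initial-
    condition bistability tests."""
    fp = lowest_equilibrium(I_syn, params)
    return np.array([fp.V + perturb, fp.V, fp.V])


def on_cycle_state(
    params: ModelParams,
    I_target: float,
    I_from: float = 0.14,
    steps: int = 8,
    horizon: float = 1000.0,
) -> np.ndarray:
    """A state on the tonic limit cycle at ``I_target``, prepared by
    continuation from the strongly-depolarized attractor (the cycle's
    basin can be thin inside the bistable window, so a direct jump from
    a far-away state may miss it)."""
    state = spike_start_state(params, I_ref=I_from)
    for ii in np.linspace(I_from, I_target, steps + 1)[1:]:
        _, Y = long_run(params, float(ii), state, horizon)
        state = Y[-1]
    return state


def long_run(
    params: ModelParams,
    I_syn: float,
    init: np.ndarray,
    horizon: float = 2000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the three-variable system at constant stimulus."""
    P = params.as_array()
    t, Y, status, t_fail = fm.integrate_reduced_dp45(
        np.asarray(init, float), _dens(I_syn, params), 0.0, horizon, rtol, atol,
        0.1, P,
    )
    if status != fm.STATUS_OK:  # pragma: no cover
        raise RuntimeError(f"integration failed at t={t_fail:.3f} ms")
    return t, Y


def classify_regime(
    t: np.ndarray,
    V: np.ndarray,
    window: float = 500.0,
    threshold: float = 0.0,
    gap_threshold: float = 30.0,
    osc_amplitude: float = 1.0,
    tonic_isi_max: float = 80.0,
) -> str:
    """Long-run regime over the final window: "stationary",
    "subthreshold-oscillation", "bursting" or "tonic".

    Spiking is "bursting" when spikes group into multi-spike clusters
    separated by more than ``gap_threshold`` ms, or when regular single
    spikes recur slower than ``tonic_isi_max`` ms (the single-spike limit
    of the slow bursting cycle); fast regular firing is "tonic".
    """
    t_end = t[-1]
    sel = t >= t_end - window
    train = detect_spikes((t[sel], V[sel]), threshold=threshold)
    if len(train) == 0:
        return (
            "subthreshold-oscillation"
            if np.ptp(V[sel]) > osc_amplitude
            else "stationary"
        )
    if len(train) == 1:
        return "tonic"
    train = burst_statistics(train, gap_threshold)
    if len(train.bursts) == 1:
        return "tonic"
    if any(len(b) > 1 for b in train.bursts):
        return "bursting"
    return "tonic" if float(np.median(train.isis)) <= tonic_isi_max else "bursting"


def sustained_spiking(
    I_syn: float,
    params: ModelParams,
    init: np.ndarray,
    horizon: float = 2500.0,
    window: float = 400.0,
    threshold: float = 0.0,
) -> bool:
    """Whether spiking persists through the final window of a long run."""
    t, Y = long_run(params, I_syn, init, horizon)
    sel = t >= t[-1] - window
    return len(detect_spikes((t[sel], Y[sel, 0]), threshold=threshold)) > 0


def find_fold_cycle_isyn(
    params: ModelParams | None = None,
    bracket: tuple[float, float] = (0.0, 0.14),
    tol: float = 2e-4,
    horizon: float = 2000.0,
    window: float = 400.0,
    n_march: int = 10,
) -> BifurcationPoint:
    """Fold of limit cycles of the full three-variable system along
    I_syn: the smallest excitatory current sustaining the tonic cycle.

    The tonic branch is tracked by continuation: starting from the
    attractor at the strongly-depolarized end of the bracket, I_syn is
    stepped downward carrying the end state of each run (the cycle's own
    basin shrinks near the fold, so a fixed far-from-branch initial state
    would drop off early), and the losing step is bisected the same way.
    """
    params = params or ModelParams()
    hi_end = bracket[1]
    state = spike_start_state(params, I_ref=hi_end)

    def spiking(i, s):
        t, Y = long_run(params, i, s, horizon)
        sel = t >= t[-1] - window
        n = len(detect_spikes((t[sel], Y[sel, 0])))
        return n > 0, Y[-1]

    i_cyc = hi_end
    i_no = bracket[0]
    for ii in np.linspace(hi_end, bracket[0], n_march + 1)[1:]:
        ok, s = spiking(float(ii), state)
        if ok:
            i_cyc, state = float(ii), s
        else:
            i_no = float(ii)
            break
    while abs(i_cyc - i_no) > tol:
        mid = 0.5 * (i_cyc + i_no)
        ok, s = spiking(mid, state)
        if ok:
            i_cyc, state = mid, s
        else:
            i_no = mid
    val = 0.5 * (i_cyc + i_no)
    return BifurcationPoint(
        "fold-cycle", "I_syn", val,
        (min(i_cyc, i_no), max(i_cyc, i_no)), tol,
        "tracked sustained-spiking bisection",
    )


def find_fold_isyn(
    params: ModelParams | None = None,
    bracket: tuple[float, float] = (0.09, 0.2),
    tol: float = 1e-5,
    V_range: tuple[float, float] = DEFAULT_V_RANGE,
) -> BifurcationPoint:
    """Fold of global equilibria along I_syn: the stimulus at which the
    stable resting state is lost by node-saddle coalescence (closing the
    bistable window)."""
    params = params or ModelParams()

    def count(i):
        return len(global_equilibria(i, params, V_range))

    lo, hi = bracket
    if count(lo) == count(hi):
        raise ValueError("equilibrium count does not change across the bracket")
    blo, bhi = _bisect_predicate(lambda i: count(i) == count(lo), lo, hi, tol)
    i_est = 0.5 * (blo + bhi)

    side = blo if count(blo) > count(bhi) else bhi
    roots = _diag_roots(side, params, V_range)
    gaps = np.diff(roots)
    V_est = 0.5 * (roots[int(np.argmin(gaps))] + roots[int(np.argmin(gaps)) + 1])

    def tangency(u):
        V, i = u
        g = lambda vv: iv_relation(vv, vv, params, i)
        return [g(V), _div_dV(g, V)]

    sol = root(tangency, [V_est, i_est], method="hybr", tol=1e-12)
    val = float(sol.x[1]) if sol.success and abs(sol.x[1] - i_est) < 0.01 else i_est
    return BifurcationPoint(
        "fold", "I_syn", val, (blo, bhi), tol,
        "equilibrium-count bisection + tangency Newton",
        {"V_fold": float(sol.x[0]), "polished": bool(sol.success)},
    )


def _diag_roots(I_syn, params, V_range):
    def g(V):
        return iv_relation(V, V, params, I_syn)

    Vs = np.arange(V_range[0], V_range[1] + DEFAULT_V_GRID / 2, DEFAULT_V_GRID)
    return _scan_roots(Vs, np.array([g(v) for v in Vs]), g)


def one_parameter_diagram(
    params: ModelParams | None = None,
    I_syn_range: tuple[float, float] = (-0.08, 0.15),
    grid_step: float = 0.005,
    horizon: float = 2000.0,
    window: float = 500.0,
    detect_bifurcations: bool = True,
) -> BranchDiagram:
    """Regime survey of the three-variable system along the stimulus axis.

    Each grid point records the global equilibria with stability and the
    long-run regime from both a rest-like and an on-cycle initial state
    (the two attractors of the bistable window); the four organizing
    bifurcations (two Hopf points, the fold of cycles and the fold of
    equilibria) are appended when ``detect_bifurcations`` is set.
    """
    params = params or ModelParams()
    grid = np.arange(I_syn_range[0], I_syn_range[1] + grid_step / 2, grid_step)
    rest0 = rest_start_state(params)
    spike0 = spike_start_state(params)
    points: list[BranchPoint] = []
    for i_syn in grid:
        eqs = global_equilibria(i_syn, params)
        t_r, Y_r = long_run(params, i_syn, rest0, horizon)
        t_s, Y_s = long_run(params, i_syn, spike0, horizon)
        reg_r = classify_regime(t_r, Y_r[:, 0], window)
        reg_s = classify_regime(t_s, Y_s[:, 0], window)
        sel = t_s >= t_s[-1] - window
        points.append(
            BranchPoint(
                float(i_syn), eqs, reg_r, reg_s,
                float(Y_s[sel, 0].max()), float(Y_s[sel, 0].min()),
            )
        )
    bifs: list[BifurcationPoint] = []
    if detect_bifurcations:
        bifs.extend(find_hopf(params, (I_syn_range[0], 0.01)))
        bifs.append(find_fold_cycle_isyn(params))
        bifs.append(find_fold_isyn(params))
    return BranchDiagram("I_syn", grid, points, bifs)
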