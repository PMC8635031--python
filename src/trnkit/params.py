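"""Model parameters for the TRN neuron and its reduction.

The defaults are the analysis parameter set used throughout the
bifurcation work: a single-compartment membrane with fast Na+ and
delayed-rectifier K+ channels for spike generation, a low-threshold
T-type Ca2+ channel for rebound bursting, and two leaks (ohmic and
neuromodulator-controlled K+ leak).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any

import numpy as np

from . import _fastmath as fm


@dataclass(frozen=True)
class ModelParams:
    """Biophysical parameters of the TRN conductance model.

    Conductances in mS/cm2, potentials in mV, capacitance in uF/cm2,
    area in cm2.  ``k`` is the pinned grouping weight of the slow T-type
    activation gate in the reduction (dimensionless, in (0, 1)).
    """

    C: float = 1.0
    A: float = 1.43e-4
    gL: float = 0.06
    EL: float = -70.0
    gKL: float = 0.0065
    EKL: float = -100.0
    gNa: float = 100.0
    ENa: float = 50.0
    gK: float = 10.0
    EK: float = -100.0
    gT: float = 2.25
    ET: float = 120.0
    VthNa: float = -55.0
    VthK: float = -55.0
    VthT: float = -3.0
    phi_m: float = 1.0
    phi_h: float = 1.0
    phi_n: float = 1.0
    phi_p: float = 6.9
    phi_q: float = 3.7
    k: float = 0.01

    def __post_init__(self) -> None:
        for name in ("gL", "gKL", "gNa", "gK", "gT"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")
        if self.C <= 0:
            raise ValueError("capacitance C must be positive")
        if self.A <= 0:
            raise ValueError("membrane area A must be positive")
        if not 0.0 < self.k < 1.0:
            raise ValueError("grouping constant k must lie in (0, 1)")

    def with_(self, **overrides: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def as_array(self) -> np.ndarray:
        """Pack into the float64 layout consumed by the compiled kernels."""
        P = np.empty(fm.P_LEN)
        P[fm.P_C] = self.C
        P[fm.P_GL] = self.gL
        P[fm.P_EL] = self.EL
        P[fm.P_GKL] = self.gKL
        P[fm.P_EKL] = self.EKL
        P[fm.P_GNA] = self.gNa
        P[fm.P_ENA] = self.ENa
        P[fm.P_GK] = self.gK
        P[fm.P_EK] = self.EK
        P[fm.P_GT] = self.gT
        P[fm.P_ET] = self.ET
        P[fm.P_VTHNA] = self.VthNa
        P[fm.P_VTHK] = self.VthK
        P[fm.P_VTHT] = self.VthT
        P[fm.P_PHIM] = self.phi_m
        P[fm.P_PHIH] = self.phi_h
        P[fm.P_PHIN] = self.phi_n
        P[fm.P_PHIP] = self.phi_p
        P[fm.P_PHIQ] = self.phi_q
        P[fm.P_K] = self.k
        return P

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def nA_to_density(i_nA: float, A: float = ModelParams.A) -> float:
    """Convert an absolute current in nA to a density in uA/cm2.

    10^-3 * I[nA] / A[cm2] = I[uA] / A[cm2].
    """
    return 1e-3 * i_nA / A
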