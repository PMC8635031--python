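"""Simulation traces and their CSV/JSON serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Trace:
    """A time series produced by a simulation.

    ``columns`` maps column names (e.g. ``V_mV``, ``m``, ``I_Na``) to
    arrays of the same length as ``t`` (ms).  ``meta`` records the
    parameters, protocol and solver settings that produced the trace.
    """

    t: np.ndarray
    columns: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time grid must be strictly increasing")
        for name, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            if col.shape != self.t.shape:
                raise ValueError(f"column {name!r} length mismatch")
            self.columns[name] = col

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    @property
    def V(self) -> np.ndarray:
        """The membrane-potential column (V_mV for the full model, x_mV
        for the reduced one)."""
        for key in ("V_mV", "x_mV"):
            if key in self.columns:
                return self.columns[key]
        raise KeyError("trace has no membrane-potential column")

    def window(self, t0: float, t1: float) -> "Trace":
        """The sub-trace with t0 <= t <= t1."""
        sel = (self.t >= t0) & (self.t <= t1)
        return Trace(
            self.t[sel], {k: v[sel] for k, v in self.columns.items()}, dict(self.meta)
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.t})
        for name, col in self.columns.items():
            df[name] = col
        return df

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the trace as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            side = path.with_suffix(path.suffix + ".json")
            side.write_text(json.dumps(self.meta, indent=2, default=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        path = Path(path)
        df = pd.read_csv(path)
        side = path.with_suffix(path.suffix + ".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        t = df.pop("t_ms").to_numpy()
        return cls(t, {c: df[c].to_numpy() for c in df.columns}, meta)
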