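"""Experiment configuration: validation, file loading, and the runner.

Configs are flat JSON or TOML documents; unknown keys are rejected so a
typo cannot silently fall back to a default.  A config either names a
``preset`` (see :mod:`trnkit.presets`) with optional overrides, or
specifies the experiment from scratch.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import dynamics as dyn
from .full_model import simulate_full
from .params import ModelParams
from .presets import get_preset
from .protocol import StimulusProtocol
from .reduction import simulate_reduced
from .spikes import burst_statistics, detect_spikes
from .trace import Trace

_KNOWN_KEYS = {
    "preset",
    "model",
    "params",
    "protocol",
    "analysis",
    "k",
    "out_dir",
    "solver",
    "z_values",
    "I_syn",
    "I_syn_range",
    "z_bracket_fold",
    "z_bracket_homoclinic",
    "z_bracket_fold_cycle",
    "expected",
}

_ANALYSES = {"trace", "compare", "bursts", "dual-init", "ivcurve", "fastslow", "diagram"}


@dataclass
class ExperimentConfig:
    """A validated experiment description."""

    model: str = "reduced"
    params: ModelParams = field(default_factory=ModelParams)
    protocol: StimulusProtocol | None = None
    analysis: str = "trace"
    options: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("full", "reduced", "both"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.analysis not in _ANALYSES:
            raise ValueError(f"unknown analysis {self.analysis!r}")


def _from_dict(doc: dict[str, Any], provenance: dict) -> ExperimentConfig:
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    base: dict[str, Any] = {}
    if "preset" in doc:
        base = get_preset(doc["preset"])
        provenance = {**provenance, "preset": doc["preset"]}
    merged = {**base, **{k: v for k, v in doc.items() if k != "preset"}}

    params = merged.get("params", ModelParams())
    if isinstance(params, dict):
        params = ModelParams.from_dict(params)
    elif not isinstance(params, ModelParams):
        raise ValueError("params must be a table of parameter values")
    if "k" in merged:
        params = params.with_(k=float(merged["k"]))

    protocol = merged.get("protocol")
    if isinstance(protocol, dict):
        protocol = StimulusProtocol.from_dict(protocol)

    options = {
        k: merged[k]
        for k in (
            "z_values",
            "I_syn",
            "I_syn_range",
            "z_bracket_fold",
            "z_bracket_homoclinic",
            "z_bracket_fold_cycle",
            "solver",
            "expected",
        )
        if k in merged
    }
    overrides = sorted(set(doc) - {"preset"})
    if overrides:
        provenance = {**provenance, "overrides": overrides}
    return ExperimentConfig(
        model=merged.get("model", "reduced"),
        params=params,
        protocol=protocol,
        analysis=merged.get("analysis", "trace"),
        options=options,
        provenance=provenance,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a JSON (.json) or TOML (.toml) experiment config.

    An empty document yields the all-defaults config (the baseline
    analysis parameter set, trace analysis, no stimulation).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".toml":
        doc = tomllib.loads(text)
    elif path.suffix == ".json":
        doc = json.loads(text) if text.strip() else {}
    else:
        raise ValueError(f"config must be .json or .toml, got {path.suffix!r}")
    return _from_dict(doc or {}, {"path": str(path)})


def config_from_dict(doc: dict[str, Any]) -> ExperimentConfig:
    """Validate an in-memory config document."""
    return _from_dict(doc, {})


# ------------------------------------------------------------------ runner

def _simulate(cfg: ExperimentConfig, which: str) -> Trace:
    if which == "full":
        return simulate_full(cfg.params, cfg.protocol, record_stride=10)
    return simulate_reduced(cfg.params, cfg.protocol)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a configured experiment; deterministic by construction.

    Returns a summary dict; when ``out_dir`` is given, traces are written
    as CSV (with JSON sidecars) and the summary as ``summary.json``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "analysis": cfg.analysis,
        "model": cfg.model,
        "provenance": cfg.provenance,
        "results": {},
    }
    res = summary["results"]
    try:
        if cfg.analysis in ("trace", "compare", "bursts"):
            models = ("full", "reduced") if cfg.model == "both" else (cfg.model,)
            for which in models:
                tr = _simulate(cfg, which)
                train = detect_spikes(tr)
                entry: dict[str, Any] = {"n_spikes": len(train)}
                if len(train):
                    entry["first_spike_ms"] = float(train.times[0])
                if cfg.analysis == "bursts" and len(train):
                    half = tr.meta["protocol"]["duration"] / 2
                    train = burst_statistics(
                        detect_spikes(tr.window(half, tr.t[-1])), 30.0
                    )
                    entry["spikes_per_burst"] = train.spikes_per_burst
                res[which] = entry
                if out is not None:
                    tr.to_csv(out / f"trace_{which}.csv")
            if cfg.analysis == "compare" and cfg.model == "both":
                res["spike_count_difference"] = abs(
                    res["full"]["n_spikes"] - res["reduced"]["n_spikes"]
                )
        elif cfg.analysis == "dual-init":
            amp = cfg.protocol.segments[0].amplitude
            horizon = cfg.protocol.duration
            t1, Y1 = dyn.long_run(
                cfg.params, amp, dyn.near_equilibrium_state(cfg.params, amp), horizon
            )
            t2, Y2 = dyn.long_run(
                cfg.params, amp, dyn.on_cycle_state(cfg.params, amp), horizon
            )
            res["rest_init_regime"] = dyn.classify_regime(t1, Y1[:, 0])
            res["cycle_init_regime"] = dyn.classify_regime(t2, Y2[:, 0])
            res["bistable"] = res["rest_init_regime"] != res["cycle_init_regime"]
        elif cfg.analysis == "ivcurve":
            rows = []
            for i_syn in cfg.options.get("I_syn", [0.0]):
                for z in cfg.options.get("z_values", [-65.0]):
                    roots = dyn.find_iv_roots(z, i_syn, cfg.params)
                    rows.append({"I_syn": i_syn, "z": z, "roots": roots})
            res["iv"] = rows
        elif cfg.analysis == "fastslow":
            i_syn = float(cfg.options.get("I_syn", 0.0))
            points = []
            if "z_bracket_fold" in cfg.options:
                points.append(
                    dyn.find_fold(i_syn, cfg.params, tuple(cfg.options["z_bracket_fold"]))
                )
            if "z_bracket_homoclinic" in cfg.options:
                points.append(
                    dyn.find_homoclinic(
                        i_syn, cfg.params, tuple(cfg.options["z_bracket_homoclinic"])
                    )
                )
            if "z_bracket_fold_cycle" in cfg.options:
                points.append(
                    dyn.find_fold_cycle(
                        i_syn, cfg.params, tuple(cfg.options["z_bracket_fold_cycle"])
                    )
                )
            res["bifurcations"] = [bp.to_dict() for bp in points]
        elif cfg.analysis == "diagram":
            lo, hi = cfg.options.get("I_syn_range", (-0.08, 0.15))
            hopf = dyn.find_hopf(cfg.params, (lo, min(hi, 0.01)))
            fcb = dyn.find_fold_cycle_isyn(cfg.params)
            fb = dyn.find_fold_isyn(cfg.params)
            res["bifurcations"] = [bp.to_dict() for bp in [*hopf, fcb, fb]]
            labels = ["SHB1", "SHB2"][: len(hopf)] + ["FCB", "FB"]
            for label, bp in zip(labels, [*hopf, fcb, fb]):
                res[label] = bp.value
    except Exception as exc:
        raise RuntimeError(f"experiment stage {cfg.analysis!r} failed: {exc}") from exc

    expected = cfg.options.get("expected", {})
    if expected:
        checks = {}
        for key, spec in expected.items():
            got = res
            for part in key.split("."):
                got = got[part]
            target, tol = float(spec[0]), float(spec[1])
            checks[key] = {
                "value": got,
                "expected": target,
                "tolerance": tol,
                "pass": bool(abs(float(got) - target) <= tol),
            }
        summary["checks"] = checks
    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
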