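"""Named experiment presets.

Each preset bundles the parameter set, stimulation protocol and analysis
of one standard experiment on the TRN model: the rebound-burst and
tonic-spiking demonstrations, full-vs-reduced comparisons, I-V curve
families, fast-slow diagrams in z, and the one-parameter regime survey
in I_syn.
"""

from __future__ import annotations

from .params import ModelParams
from .protocol import StimulusProtocol, constant, step

#: the baseline analysis parameter set for the bifurcation work
ANALYSIS_PARAMS = ModelParams()  # gT=2.25, gKL=0.0065, EL=-70, k=0.01

#: the parameter set of the firing-pattern comparison protocols
COMPARISON_PARAMS = ANALYSIS_PARAMS.with_(gKL=0.0152)


def _p(**kw):
    return ANALYSIS_PARAMS.with_(**kw) if kw else ANALYSIS_PARAMS


PRESETS: dict[str, dict] = {
    # rebound burst of the full model under a hyperpolarizing step
    "rebound-full": {
        "model": "full",
        "params": _p(EL=-77.0, gKL=0.00793, gT=2.0),
        "protocol": step(-0.03, 0.0, 200.0, 600.0),
        "analysis": "trace",
    },
    # full-vs-reduced firing-pattern comparisons
    "compare-tonic": {
        "model": "both",
        "params": COMPARISON_PARAMS,
        "protocol": constant(0.2, 1000.0),
        "analysis": "compare",
    },
    "compare-step": {
        "model": "both",
        "params": COMPARISON_PARAMS,
        "protocol": step(0.2, 0.0, 200.0, 1000.0),
        "analysis": "compare",
    },
    "compare-rebound": {
        "model": "both",
        "params": COMPARISON_PARAMS,
        "protocol": step(-0.05, 0.0, 200.0, 1000.0),
        "analysis": "compare",
    },
    # phase-plane walkthroughs
    "rebound-reduced": {
        "model": "reduced",
        "params": _p(),
        "protocol": step(-0.03, 50.0, 250.0, 600.0),
        "analysis": "trace",
    },
    "tonic-reduced": {
        "model": "reduced",
        "params": _p(),
        "protocol": step(0.1, 50.0, 350.0, 600.0),
        "analysis": "trace",
    },
    # steady-state firing patterns along the stimulus axis
    "burst3": {
        "model": "reduced",
        "params": _p(),
        "protocol": constant(-0.03, 4000.0),
        "analysis": "bursts",
    },
    "burst1": {
        "model": "reduced",
        "params": _p(),
        "protocol": constant(-0.01, 4000.0),
        "analysis": "bursts",
    },
    "bistable": {
        "model": "reduced",
        "params": _p(),
        "protocol": constant(0.07, 3000.0),
        "analysis": "dual-init",
    },
    "tonic-only": {
        "model": "reduced",
        "params": _p(),
        "protocol": constant(0.14, 3000.0),
        "analysis": "dual-init",
    },
    # analysis presets (no protocol)
    "iv-curves": {
        "model": "reduced",
        "params": _p(),
        "analysis": "ivcurve",
        "z_values": [-75.0, -70.0, -65.0, -60.0],
        "I_syn": [0.0, -0.05, 0.1],
    },
    "fastslow-rest": {
        "model": "reduced",
        "params": _p(),
        "analysis": "fastslow",
        "I_syn": 0.0,
        "z_bracket_fold": [-80.0, -60.0],
        "z_bracket_homoclinic": [-66.0, -60.0],
    },
    "fastslow-depolarized": {
        "model": "reduced",
        "params": _p(),
        "analysis": "fastslow",
        "I_syn": 0.1,
        "z_bracket_fold_cycle": [-60.0, -50.0],
    },
    "one-parameter": {
        "model": "reduced",
        "params": _p(),
        "analysis": "diagram",
        "I_syn_range": [-0.08, 0.15],
    },
}


def get_preset(name: str) -> dict:
    try:
        return dict(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> list[str]:
    return sorted(PRESETS)
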