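"""Configuration loading, presets, the experiment runner, and the CLI."""

import json

import pytest

from trnkit import config_from_dict, get_preset, list_presets, load_config, run_experiment
from trnkit.cli import main as cli_main


def test_empty_config_gives_defaults(tmp_path):
    path = tmp_path / "empty.json"
    path.write_text("")
    cfg = load_config(path)
    assert cfg.model == "reduced"
    assert cfg.params.gT == 2.25
    assert cfg.params.gKL == 0.0065
    assert cfg.params.k == 0.01


def test_unknown_key_rejected(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"modle": "full"}))
    with pytest.raises(ValueError, match="modle"):
        load_config(path)


def test_invalid_parameter_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        config_from_dict({"params": {"gNa": -1.0}})


def test_toml_config_roundtrip(tmp_path):
    path = tmp_path / "exp.toml"
    path.write_text(
        'preset = "burst1"\nk = 0.02\n'
    )
    cfg = load_config(path)
    assert cfg.params.k == 0.02
    assert cfg.analysis == "bursts"
    assert cfg.provenance["preset"] == "burst1"
    assert "k" in cfg.provenance["overrides"]


def test_firing_pattern_preset_parameters():
    pre = get_preset("burst3")
    assert pre["params"].gKL == 0.0065
    assert pre["params"].gT == 2.25
    assert pre["params"].k == 0.01
    assert pre["protocol"].segments[0].amplitude == -0.03


def test_unknown_preset_lists_alternatives():
    with pytest.raises(KeyError, match="available"):
        get_preset("nope")
    assert "burst1" in list_presets()


def test_run_experiment_is_deterministic(tmp_path):
    """Re-running the same config produces byte-identical trace CSVs."""
    cfg = config_from_dict(
        {
            "preset": "rebound-full",
            "protocol": {
                "duration": 300.0,
                "segments": [{"t_start": 0.0, "t_end": 100.0, "amplitude": -0.03}],
            },
        }
    )
    out1, out2 = tmp_path / "a", tmp_path / "b"
    s1 = run_experiment(cfg, out1)
    s2 = run_experiment(cfg, out2)
    assert s1["results"] == s2["results"]
    assert (out1 / "trace_full.csv").read_bytes() == (out2 / "trace_full.csv").read_bytes()


def test_summary_schema_is_stable(tmp_path):
    cfg = config_from_dict(
        {"preset": "iv-curves", "z_values": [-65.0], "I_syn": [0.0]}
    )
    summary = run_experiment(cfg, tmp_path)
    assert set(summary) >= {"analysis", "model", "provenance", "results"}
    assert json.loads((tmp_path / "summary.json").read_text()) == json.loads(
        json.dumps(summary, default=float)
    )


def test_fold_only_fastslow_report():
    cfg = config_from_dict({"preset": "fastslow-rest"})
    # keep this a fast fold-only run
    cfg.options.pop("z_bracket_homoclinic", None)
    summary = run_experiment(cfg)
    [bif] = summary["results"]["bifurcations"]
    assert bif["type"] == "fold"
    assert bif["bracket"][0] <= bif["value"] <= bif["bracket"][1]


def test_cli_ivcurve_runs(capsys):
    assert cli_main(["ivcurve", "--z", "-65", "--isyn", "0"]) == 0
    out = json.loads(capsys.readouterr().out)
    assert len(out["results"]["iv"][0]["roots"]) == 3


def test_cli_preset_list(capsys):
    assert cli_main(["preset", "list"]) == 0
    assert "burst1" in capsys.readouterr().out
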