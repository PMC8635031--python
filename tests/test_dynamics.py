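"""Dynamics-toolkit tests: I-V roots, equilibrium classification,
limit-cycle probing and the bifurcation detectors' internal checks.

The expensive printed-value reproductions live in test_acceptance; here
the detectors are exercised on their structural guarantees.
"""

import numpy as np
import pytest

from trnkit import ModelParams
from trnkit import _fastmath as fm
from trnkit.dynamics import (
    classify_stability,
    fast_jacobian,
    find_equilibria_fast,
    find_fold,
    find_iv_roots,
    global_equilibria,
    iv_relation,
    limit_cycle_probe,
    lowest_equilibrium,
    reduced_jacobian,
)


def test_three_iv_roots_at_rest_conditions(params):
    roots = find_iv_roots(-65.0, 0.0, params, V_range=(-90.0, 0.0))
    assert len(roots) == 3


def test_depolarizing_current_leaves_single_root(params):
    roots = find_iv_roots(-65.0, 0.10, params)
    assert len(roots) == 1


def test_iv_grows_positive_at_high_voltage(params):
    assert iv_relation(60.0, -65.0, params, 0.0) > 0


def test_iv_root_count_changes_with_z(params):
    assert len(find_iv_roots(-67.5, 0.0, params)) == 1
    assert len(find_iv_roots(-64.0, 0.0, params)) == 3


@pytest.mark.parametrize(
    "eig, label",
    [
        ([-1.0, -2.0], "stable node"),
        ([-0.1 + 2j, -0.1 - 2j], "stable focus"),
        ([0.3, -0.5], "saddle"),
        ([0.2, 0.9], "unstable node"),
        ([0.05 + 1j, 0.05 - 1j, -0.3], "unstable focus"),
    ],
)
def test_classify_stability_standard_cases(eig, label):
    got, marginal = classify_stability(eig)
    assert got == label
    assert not marginal


def test_classify_stability_flags_marginal_eigenvalues():
    _, marginal = classify_stability([1e-12, -0.5])
    assert marginal


def test_fast_equilibria_pattern_at_intermediate_z(params):
    eqs = find_equilibria_fast(-65.0, 0.0, params)
    assert [e.classification.startswith("stable") for e in eqs] == [True, False, False]
    assert eqs[1].classification == "saddle"
    assert eqs[0].V < eqs[1].V < eqs[2].V
    for e in eqs:
        assert e.residual < 1e-8


def test_single_unstable_focus_at_low_z(params):
    eqs = find_equilibria_fast(-80.0, 0.0, params)
    assert len(eqs) == 1
    assert eqs[0].classification == "unstable focus"


def test_classification_matches_independent_eigensolve(params):
    for e in find_equilibria_fast(-65.0, 0.0, params):
        J = fast_jacobian(e.V, e.y, e.z, 0.0, params)
        label, _ = classify_stability(np.linalg.eigvals(J))
        assert label == e.classification


def test_stable_equilibrium_attracts_perturbations(params):
    """Integrating the fast subsystem from 0.1 mV off a stable
    equilibrium returns to it within 200 ms."""
    eq = find_equilibria_fast(-65.0, 0.0, params)[0]
    P = params.as_array()
    _, XY, status, _ = fm.integrate_fast_dp45(
        eq.V + 0.1, eq.y, eq.z, 0.0, 0.0, 200.0, 1e-8, 1e-10, 0.1, P
    )
    assert status == fm.STATUS_OK
    assert abs(XY[-1, 0] - eq.V) < 1e-3


def test_limit_cycle_exists_deep_in_spiking_region(params):
    probe = limit_cycle_probe(-70.0, 0.0, params)
    assert probe.exists
    assert probe.V_max > 0 > probe.V_min
    assert probe.period > 0


def test_no_cycle_beyond_the_spiking_region(params):
    assert not limit_cycle_probe(-60.0, 0.0, params).exists


def test_cycle_period_grows_toward_homoclinic(params):
    """The spiking period lengthens monotonically as z rises toward the
    saddle connection (logarithmic divergence signature)."""
    periods = []
    init = None
    for z in (-65.0, -64.0, -63.5):
        pr = limit_cycle_probe(z, 0.0, params, init=init)
        assert pr.exists
        periods.append(pr.period)
        init = pr.end_state
    assert periods[0] < periods[1] < periods[2]


def test_fold_tangency(params):
    """At the detected fold both I and dI/dV vanish at the coalescence
    voltage."""
    bp = find_fold(0.0, params, (-80.0, -60.0))
    V = bp.info["V_fold"]
    f = lambda v: iv_relation(v, bp.value, params, 0.0)
    assert abs(f(V)) < 1e-3
    assert abs((f(V + 1e-6) - f(V - 1e-6)) / 2e-6) < 1e-3


def test_fold_bracket_is_a_true_bracket(params):
    bp = find_fold(0.0, params, (-80.0, -60.0))
    lo, hi = bp.bracket
    assert lo <= bp.value <= hi
    assert hi - lo <= bp.tol
    n_lo = len(find_iv_roots(lo - 0.01, 0.0, params))
    n_hi = len(find_iv_roots(hi + 0.01, 0.0, params))
    assert n_lo != n_hi


def test_fold_requires_count_change():
    with pytest.raises(ValueError, match="does not change"):
        find_fold(0.0, ModelParams(), (-62.0, -61.0))


def test_global_equilibria_residuals_and_order(params):
    eqs = global_equilibria(0.0, params)
    assert len(eqs) >= 1
    assert all(a.V < b.V for a, b in zip(eqs, eqs[1:]))
    for e in eqs:
        assert e.residual < 1e-8
        assert e.subsystem == "full-3D"


def test_lowest_equilibrium_stability_flips_with_inhibition(params):
    """Strong inhibition stabilizes the resting state; moderate
    inhibition leaves an unstable focus that drives periodic bursting."""
    assert lowest_equilibrium(-0.06, params).classification == "stable focus"
    assert lowest_equilibrium(-0.03, params).classification == "unstable focus"


def test_one_parameter_diagram_smoke(params):
    """A coarse stimulus sweep records equilibria, both-init regimes and
    oscillation extremes at every grid point."""
    from trnkit.dynamics import one_parameter_diagram

    d = one_parameter_diagram(
        params, I_syn_range=(-0.04, 0.1), grid_step=0.07,
        horizon=1200.0, window=400.0, detect_bifurcations=False,
    )
    assert len(d.points) == len(d.grid) >= 3
    for pt in d.points:
        assert pt.equilibria
        assert pt.V_max >= pt.V_min
        assert pt.regime_rest in (
            "stationary", "subthreshold-oscillation", "bursting", "tonic"
        )


def test_jacobians_have_expected_shapes(params):
    assert fast_jacobian(-65.0, -65.0, -65.0, 0.0, params).shape == (2, 2)
    assert reduced_jacobian(-65.0, -65.0, -65.0, 0.0, params).shape == (3, 3)
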