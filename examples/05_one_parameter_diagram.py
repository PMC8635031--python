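"""Regime survey along the stimulus axis.

Sweeping the synaptic current maps out the discharge repertoire of the
three-variable model: a stable rest under strong inhibition, periodic
bursting between two Andronov-Hopf points, a quiescent window, a
bistable band (rest + tonic cycle) and finally pure tonic spiking.
"""

from trnkit import ModelParams
from trnkit import dynamics as dyn

params = ModelParams()

hopf = dyn.find_hopf(params, (-0.08, 0.01))
fcb = dyn.find_fold_cycle_isyn(params)
fb = dyn.find_fold_isyn(params, (0.09, 0.2))

print("organizing bifurcations (I_syn, native units):")
print(f"  SHB1 (rest destabilizes):   {hopf[0].value:+.4f}")
print(f"  SHB2 (rest restabilizes):   {hopf[1].value:+.4f}")
print(f"  FCB  (tonic cycle is born): {fcb.value:+.4f}")
print(f"  FB   (rest disappears):     {fb.value:+.4f}")

print("\nlong-run regime from rest-like and spiking initial states:")
for i_syn in (-0.06, -0.03, 0.02, 0.07, 0.14):
    t, Y = dyn.long_run(params, i_syn, dyn.near_equilibrium_state(params, i_syn), 3000.0)
    rest = dyn.classify_regime(t, Y[:, 0])
    t, Y = dyn.long_run(params, i_syn, dyn.on_cycle_state(params, i_syn), 3000.0)
    spike = dyn.classify_regime(t, Y[:, 0])
    both = rest if rest == spike else f"{rest} / {spike}  (bistable)"
    print(f"  I_syn = {i_syn:+.2f}: {both}")
# Between FCB and FB the two initial conditions end on different
# attractors — the bistable band that lets brief inputs switch the
# neuron between silence and tonic firing.
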