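# trnkit

Simulation, model reduction and fast-slow bifurcation analysis for
thalamic reticular nucleus (TRN) neurons.

TRN neurons fire in a continuum from rebound bursting (during sleep and
hyperpolarized states) to tonic spiking (during wakefulness), and the
switch between the two shapes thalamocortical gating and sleep rhythms.
`trnkit` implements, for users who want to *analyze* this repertoire
rather than just simulate it:

1. **The full conductance-based model** — a single-compartment
   Hodgkin-Huxley-type membrane with fast Na⁺ (m³h), delayed-rectifier
   K⁺ (n⁴), low-threshold T-type Ca²⁺ (p²q) and two leak currents:

   C dV/dt = 10⁻³ I_syn(t)/A − [g_Na m³h (V−E_Na) + g_K n⁴ (V−E_K)
             + g_T p²q (V−E_T) + g_L (V−E_L) + g_KL (V−E_KL)],

   with each gate relaxing as dθ/dt = φ_θ (θ∞(V) − θ)/τ_θ(V).

2. **A three-variable reduction by equivalent potentials.** Each gating
   fraction θ maps to the voltage v_θ with θ = θ∞(v_θ); variables on a
   common time scale are grouped into weighted averages
   x = ρ_V V + ρ_m v_m, y = ρ_h v_h + ρ_n v_n + ρ_p v_p, z = v_q,
   with the weights recomputed at every state from closed-form
   optimality conditions (ρ_p is pinned to a small constant k = 0.01,
   ρ_h:ρ_n follows the current sensitivities ∂F/∂v_h:∂F/∂v_n, and ρ_V
   solves a quadratic balancing membrane and Na⁺-activation rates).
   Channel currents remain recoverable from (x, y, z).

3. **A fast-slow bifurcation toolkit.** With the slow T-channel
   potential z frozen, the fast (x, y) subsystem's equilibria are roots
   of the current-voltage relation I(V, z); the toolkit locates folds
   (saddle-node), saddle-homoclinic orbits and folds of limit cycles in
   z, Andronov-Hopf and fold bifurcations along the stimulus axis, and
   classifies long-run regimes — exposing rebound bursting as
   "fold/homoclinic" bursting and tonic spiking as a fold-cycle
   phenomenon.

## Worked example

```python
from trnkit import ModelParams, find_fold, find_homoclinic

params = ModelParams()            # g_T=2.25, g_KL=0.0065, k=0.01
fold = find_fold(0.0, params, (-80, -60))
hom  = find_homoclinic(0.0, params, (-66, -60))
print(f"fold at z = {fold.value:.2f} mV, homoclinic at z = {hom.value:.2f} mV")
```

prints

```
fold at z = -66.56 mV, homoclinic at z = -63.33 mV
```

meaning: for z below −66.56 mV the fast subsystem can only spike, above
−63.33 mV it can only rest, and in between it is bistable.  A burst is
the slow variable z sweeping across this hysteresis window — spiking
drives z up until the limit cycle dies on the saddle (the homoclinic
end), quiescence lets z fall until the rest state folds away, and the
loop repeats.

The `examples/` directory contains short narrative scripts, one per
capability (rebound bursting, full-vs-reduced comparison, I-V analysis,
fast-slow decomposition, and the one-parameter regime survey):

```bash
python examples/04_fastslow_bifurcations.py
```

A thin CLI mirrors the library:

```bash
trnkit preset list
trnkit fastslow --isyn 0 --fold-bracket -80 -60 --homoclinic-bracket -66 -60
trnkit simulate --model both --amplitude 0.2 --duration 1000
```

Stimulus amplitudes are the synaptic current I_syn in the model's
native units (nA); the membrane equation converts them to current
density with the 10⁻³/A factor shown above.

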