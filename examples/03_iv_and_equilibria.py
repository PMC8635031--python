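"""Current-voltage relation and fast-subsystem equilibria.

Freezing the slow T-channel potential z turns the reduced model into a
fast (x, y) subsystem whose rest states are the roots of the I-V
relation I(V, z) with y clamped to the diagonal y = V.
"""

from trnkit import ModelParams, find_equilibria_fast, find_iv_roots

params = ModelParams()

for z in (-80.0, -65.0):
    eqs = find_equilibria_fast(z, 0.0, params)
    print(f"z = {z:.0f} mV: {len(eqs)} equilibrium point(s)")
    for e in eqs:
        print(f"   V = {e.V:8.3f} mV  {e.classification:15s} "
              f"residual {e.residual:.1e}")
# At hyperpolarized z only the spiking-related unstable point survives
# (the neuron must fire); at higher z a stable resting state and a saddle
# appear, giving the bistability that underlies burst generation.

print("\nDepolarizing current removes the resting states:")
print("roots at z=-65, I_syn=0.10:", [round(v, 2) for v in
                                      find_iv_roots(-65.0, 0.10, params)])
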