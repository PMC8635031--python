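"""Rebound bursting in the full TRN conductance model.

A 200 ms hyperpolarizing step de-inactivates the low-threshold T-type
Ca2+ channel; on release the neuron fires a burst of fast spikes riding
a slow Ca2+ depolarization.
"""

from trnkit import ModelParams, simulate_full, step
from trnkit.spikes import detect_spikes

params = ModelParams(EL=-77.0, gKL=0.00793, gT=2.0)
protocol = step(-0.03, 0.0, 200.0, 600.0)  # I_syn in nA, 0-200 ms

trace = simulate_full(params, protocol, record_stride=5)
train = detect_spikes(trace)

print(f"resting potential before release: {trace.window(150, 199).V.mean():.2f} mV")
print(f"spikes fired after release:       {len(train)}")
print(f"first spike at:                   {train.times[0]:.1f} ms "
      f"({train.times[0] - 200:.1f} ms after release)")
print(f"peak depolarization:              {trace.V.max():.1f} mV")
# The burst is the signature of the T current: hyperpolarization recovers
# its inactivation gate, so the release triggers a Ca2+-driven spike barrage.
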