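"""Fast-slow decomposition: the bifurcations that shape a burst.

Treating the slow potential z as a parameter, the fast subsystem's
resting state is born at a fold (saddle-node) and its spiking limit
cycle dies against a saddle (homoclinic orbit).  The hysteresis loop
between the two is the rebound burst; in Izhikevich's taxonomy this is
"fold/homoclinic" bursting.
"""

from trnkit import ModelParams, find_fold, find_homoclinic, limit_cycle_probe

params = ModelParams()

fold = find_fold(0.0, params, (-80.0, -60.0))
hom = find_homoclinic(0.0, params, (-66.0, -60.0))

print(f"fold of equilibria:        z = {fold.value:8.3f} mV")
print(f"saddle-homoclinic orbit:   z = {hom.value:8.3f} mV  ({hom.kind})")
print(f"bistable z interval width: {hom.value - fold.value:.2f} mV")

# period divergence is the homoclinic fingerprint
for dz in (0.5, 0.1, 0.05):
    pr = limit_cycle_probe(hom.value - dz, 0.0, params)
    print(f"  spiking period {dz:4.2f} mV below the critical z: "
          f"{pr.period:7.1f} ms")
# The period grows without bound as the cycle approaches the saddle —
# the slow z drift therefore always reaches the boundary and the burst
# terminates in finitely many spikes.
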