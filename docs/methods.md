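# Methods

## The full model

The membrane is a single isopotential compartment,

    C dV/dt = 10^-3 I_syn(t) / A - I_ion(V, m, h, n, p, q),
    I_ion = g_Na m^3 h (V - E_Na) + g_K n^4 (V - E_K)
          + g_T p^2 q (V - E_T) + g_L (V - E_L) + g_KL (V - E_KL),

with C = 1 uF/cm2, A = 1.43e-4 cm2, g_Na = 100, g_K = 10, g_L = 0.06
mS/cm2, E_Na = 50, E_K = E_KL = -100, E_L = -70, E_T = 120 mV.  The
defaults g_T = 2.25 and g_KL = 0.0065 mS/cm2 are the analysis set used
throughout the bifurcation work; experiment presets override them where
a protocol calls for a different cell configuration.  g_KL is the
neuromodulator-controlled K+ leak: raising it mimics withdrawal of
acetylcholine/noradrenaline and hyperpolarizes the cell toward burst
mode.  Gates relax as d(theta)/dt = phi (theta_inf - theta)/tau(V) with
phi = 1 for m, h, n and phi_p = 6.9, phi_q = 3.7 (temperature
correction of the Ca2+ kinetics).

Two readings of the printed kinetics required a decision:

* **beta_n.**  We use the Traub-type delayed-rectifier deactivation
  beta_n = 0.5 exp((10 - V + VthK)/40), the form in the source kinetics
  this model family descends from.  The alternative /10 reading shifts
  the saddle-homoclinic boundary by ~2 mV and breaks the agreement
  between the reduced model and the frozen-q full model; /40 makes the
  two agree to a few hundredths of a millivolt, so we treat /40 as the
  model's definition.
* **Stimulus units.**  Protocol amplitudes are I_syn in the native nA
  units of the membrane equation and are scaled by 10^-3/A ~ 6.99
  (uA/cm2)/nA inside the right-hand side.  This is the only convention
  under which the current-dependent bifurcation structure (the fold
  positions under -0.06 nA inhibition, the closing fold of the bistable
  window near 0.13 nA) is internally consistent; a helper
  (`trnkit.params.nA_to_density`) exposes the density form.

Removable singularities of the u/(exp(u/c)-1) rate forms are replaced
by their series expansion for |u| < 1e-7, keeping the rates and their
derivatives smooth through the singular voltage.

## Reduction by equivalent potentials

Each gating fraction is mapped to its equivalent potential,
v_theta = theta_inf^{-1}(theta), so all six state variables carry mV
units, and variables sharing a time scale are grouped:

    x = rho_V V + rho_m v_m        (spike generation)
    y = rho_h v_h + rho_n v_n + rho_p v_p   (recovery)
    z = v_q                        (slow T-channel de-inactivation)

The weights minimize the first-order discrepancy between the grouped
and original voltage dynamics and are recomputed at every state (with
v_m identified with x and v_h, v_n, v_p with y):

* rho_p = k, fixed; k = 0.01 by default and exposed as a parameter.
  The T-activation sensitivity opposes those of h and n
  (anti-synergistic), so it receives a small pinned weight.
* rho_h and rho_n split 1 - k in proportion to dF/dv_h and dF/dv_n,
  where F is the total ionic current through equivalent potentials.
  These closed forms have a pole where dF/dv_h + dF/dv_n crosses zero
  and violate the non-negativity constraints of the underlying
  optimization beyond it; there the constrained optimum lies on the
  boundary, so the implementation projects (the gate with the
  wrong-signed sensitivity gets 0, the other 1 - k).  On-attractor
  trajectories stay inside the interior regime; the projection matters
  for far-from-equilibrium initial conditions.
* rho_V solves (F_V + F_m) r^2 - (a + F_V) r + a = 0 with
  a = C phi_m / tau_m(x).  The branch continuous with the limit
  a/(a + F_V) is taken; if it leaves [0, 1] the other root is used, and
  failing that the value is clamped (never observed on trajectories).
  rho_V is floored at 1e-6 in the voltage equation to avoid division
  blow-up.

The reduced dynamics follow by substituting the groups into the chain
rule: dx/dt = (stimulus - F(x, y, z)) / (C rho_V), and dy/dt, dz/dt are
the rho-weighted equivalent-potential velocities with theta_inf'
evaluated analytically.  Both the y- and z-nullclines are then exactly
the diagonal (y = x, z = x) — asserted on a grid in the tests.  Channel
currents are recovered from (x, y, z) by evaluating the steady-state
curves at the group potentials.

## Numerics

The equivalent-potential equations are mildly stiff: 1/theta_inf'
factors grow without bound when a spike pushes y toward a gate's
saturated range.  The default integrator is therefore an adaptive
Dormand-Prince 5(4) pair (rtol 1e-8, atol 1e-10, max step 0.1 ms),
compiled with numba when available; a fixed-step RK4 (dt = 0.01 ms) is
the default for the non-stiff full model and available for the reduced
one.  Three regularizations keep trial stages of the adaptive pair
finite without affecting accepted steps: voltages entering the kinetics
are clamped to +-300 mV, theta_inf' denominators are floored
(sign-preserving) at 1e-12, and each derivative is capped at 1e5 mV/ms
— two orders of magnitude above the largest value observed on
attractors (~1e3 mV/ms).

"Steady" initialization relaxes the model for 2000 ms at zero stimulus.
Simulations are deterministic end to end; there is no random number
generator anywhere in the pipeline.

## Bifurcation detection

* **I-V relation and equilibria.**  I(V, z) = F(V, y=V, z) - stimulus;
  roots are located by a 0.05 mV sign scan plus Brent refinement, with
  a 10x local rescan around near-tangent minima so barely-separated
  fold pairs are still counted.  Jacobians (2x2 fast, 3x3 full) are
  central differences of the actual right-hand side at step 1e-6, so
  the state-dependence of the weights is included.  Classification is
  by eigenvalues (focus iff a complex pair; stable iff all real parts
  negative; real parts within 1e-9 of zero are flagged marginal).
* **Folds** are bisected on the root count of I(V, z) (tolerance 1e-3
  mV) and polished by Newton on the tangency system I = 0, dI/dV = 0.
* **Limit-cycle existence** is decided by simulation.  Probes start
  from a standardized superthreshold state (x = -20 mV, y = z) or, in
  sweeps, from the end state of the previous on-cycle probe — the
  discrete analogue of the slow drift along the spiking branch, which
  avoids basin-of-attraction artifacts near the boundaries.  A probe
  reports "cycle" while upward 0 mV crossings continue, "no-cycle" only
  when the trajectory has parked at a stable fast equilibrium, and
  extends its window (up to 3 doublings of 500 ms after a 200 ms
  transient) otherwise; an undecided probe raises rather than guesses.
  When no stable equilibrium exists at that z, a quiet trajectory that
  has spiked is classified as a (ghost-dominated, long-period) cycle.
* **Saddle-homoclinic vs fold-cycle.**  Cycle-loss boundaries are
  bisected to 1e-2 mV with state continuation.  If the equilibrium
  count changes across the boundary the event is the cycle terminating
  on a fold of equilibria (reported as the fold-cycle end of the
  spiking branch, with the coincidence noted); if the count is
  unchanged and the period grows >= 1.5x approaching the boundary, it
  is a saddle-homoclinic orbit; finite-period loss without a count
  change is a fold of cycles.
* **Hopf points** are tracked along the stimulus axis via the real part
  of the 3x3 Jacobian's complex pair at the lowest diagonal
  equilibrium, refined by Brent to 1e-8; supercriticality can be
  confirmed by a small-orbit simulation just past the crossing.
* **Stimulus-axis folds** reuse the tangency machinery on the diagonal
  I-V relation; the tonic-cycle onset is bisected (2e-4) on sustained
  spiking over a 2000 ms horizon with downward continuation of the
  cycle state from the strongly-depolarized attractor.

Regime labels ("stationary", "subthreshold-oscillation", "bursting",
"tonic") are read from the final 500 ms of a run: spikes grouped by a
30 ms gap; multi-spike groups are bursting; regular isolated spikes
count as tonic when the median interval is <= 80 ms and as single-spike
bursting beyond (the slow bursting cycle degenerates to one spike per
cycle, so the cut is a convention, stated here once).

## Scope of the synthetic protocols

All inputs are generated in-package: piecewise-constant current steps
standing in for synaptic drive.  They emulate the square-pulse
stimulation of slice experiments, not conductance-based synaptic input
(no reversal-potential dependence, no kinetics) and no channel noise;
agreement of the reduced and full models under these protocols
therefore demonstrates fidelity of the reduction, not biological
realism of the stimulus.

## Known limitations

* The reduced model tracks the full model's stationary regimes and
  response classes; transient burst phases can differ in spike count
  (the reduced model fires faster during the initial barrage under
  strong depolarization).
* The bursting orbit's z-excursion overshoots the static fold and
  homoclinic boundaries (slow-passage effects), so spikes-per-burst
  under mid-range inhibition is sensitive to the spiral-out rate of the
  weakly unstable resting focus; counts there should be read as
  order-of-magnitude, not exact, predictions.
* Equilibrium classification distinguishes node from focus via the
  Jacobian of the state-dependent-weight flow; where the weights vary
  strongly this can differ from a constant-weight linearization even
  though stability itself agrees.
* One-parameter sweeps use simulation-based attractor detection, not
  numerical continuation; unstable limit cycles are not tracked.
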