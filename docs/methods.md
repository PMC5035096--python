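# Methods

## Model

Each neuron is a branched tree of cylindrical/frustum sections
discretized into isopotential compartments.  The default
discretization splits every section into an odd number of compartments
whose length does not exceed one tenth of the AC length constant at
100 Hz, λ₁₀₀ = ½·√(d / (π f R_a C_m)); a fixed-maximum-length policy is
available for controlled tests.  Compartment surface areas are
trapezoidal integrals of the local circumference over arc length (a
linearly interpolated diameter between reconstruction points, i.e.
frustum slices), and half axial resistances integrate 4R_a/(πd²) over
each half of the compartment.

Membrane currents per compartment:

* leak: G_m (V − E_leak), with region-specific passive parameters.
  Defaults (soma/dendrites): C_m = 0.9 µF/cm², R_a = 255 Ω·cm,
  G_m = 1.9·10⁻⁵ S/cm².  A trimmed axon stub instead carries C_m = 4,
  R_a = 300, G_m = 1.85·10⁻⁴ to stand in for the passive load of the
  removed arbor.  E_leak defaults to the target resting potential
  (−69.7 mV): with voltage-independent leak only, the passive resting
  potential equals E_leak everywhere, so no separate fit is needed;
  active channels shift rest by well under 1 mV at the default
  densities.
* voltage-gated channels in Hodgkin–Huxley form,
  I = ḡ · ∏ x_i^{p_i} · (V − E), with E_Na = 50 mV and E_K = −77 mV.
  Gating steady states are Boltzmann sigmoids; time constants come from
  a three-member family (constant; bell-shaped
  τ_min + a/(e^{(V−v)/s₁} + e^{−(V−v)/s₂}); sigmoid).

### Channel kinetics are synthetic

The published kinetics table for this channel set exists only as an
image and the archived channel models it references are not bundled, so
`data/channels_synthetic.yaml` is a synthetic transcription authored for
this package.  The parameters were selected by a coarse grid search over
gate midpoints and slopes with a fixed acceptance rule: the published
final conductance-density ranges must reproduce the four signature
regimes (sag-free hyperpolarization at −100 pA, a passive response at
+20 pA, ≥3 spikes with repolarization at +50 pA, and depolarization
block with a silent recovery at +500 pA) on the bundled fixture
morphology, for the somatic (S.2) and proximal-dendrite (SDprox)
scenarios.  Three mechanisms turned out to be load-bearing:

* a steep, high-midpoint delayed rectifier (Kv3-like; activation n⁴,
  midpoint −22 mV) that is silent at rest but terminates spikes and
  caps depolarized plateaus;
* transient-Na inactivation with slow subthreshold recovery
  (sigmoid τ_h, ~20 ms below −45 mV), which produces depolarization
  block at strong drive and prevents rebound spikes during recovery;
* an A-type current whose inactivation midpoint (−62 mV) leaves a
  window conductance in the −45…−30 mV corridor, removing the
  bistable plateau that the Na window plus persistent Na would
  otherwise sustain at zero current.

Consequences worth knowing: the model's +50 pA firing is faster
(~40 Hz, sub-millisecond half-widths) and its spike threshold higher
(≈ −32 mV) than the reference cell's measurements, and the
uniform-dendrite (SD) scenario fails the elimination criteria at every
density probed — it either spikes at +20 pA or not enough at +50 pA.
The SD scenario is retained for backpropagation analyses, which do not
require surviving the screen.  Anyone with the original kinetics can
drop them into the YAML schema and re-run everything.

## Numerical integration

Gating variables advance by exponential (Rush–Larsen) updates at the
previous voltage; the voltage step then solves the linear
tree-structured system (C/Δt + θG)V' = C/Δt·V + θb + (1−θ)(b − GV)
exactly with a leaf-to-root Hines elimination (compartments ordered so
every parent precedes its children).  θ = 1 is backward Euler — the
screening default, unconditionally stable and robust over wide
conductance grids — and θ = ½ is Crank–Nicolson, second-order accurate.
Backward Euler's first-order phase error accumulates over a long spike
train (~0.2 ms per spike at Δt = 0.025 ms), so the timestep-convergence
test (< 0.2 ms spike-time shift under Δt halving) is run with
Crank–Nicolson; backward Euler still pins the first spike to within
0.2 ms.  Default Δt = 0.025 ms.  Every protocol is preceded by a 500 ms
settle-to-steady-state pre-run (discarded); the settled state is reused
across the four protocols of one model.

Units are fixed internally: mV, ms, µm, S/cm², µF/cm², Ω·cm; point
currents nA (protocol amplitudes in pA are converted once); synaptic
weights µS.  The single conversion site is the model assembly
(`BiophysicalModel`).

Synapses are double-exponential conductances
G = w·f·(e^{−t/τ₂} − e^{−t/τ₁}) with τ₁ = 0.2 ms, τ₂ = 2 ms, reversal
0 mV, and f chosen so the peak after one presynaptic spike equals the
weight (peak time τ₁τ₂/(τ₂−τ₁)·ln(τ₂/τ₁) ≈ 0.51 ms).  The conductance
enters the implicit voltage solve, not as an explicit current.
Optional Gaussian white-noise current injection is seeded and
off during screening.

## Protocols and measurements

The four screening steps are −100, +20, +50, +500 pA.  Durations are
not dictated by the data this reimplements, so they are package
choices: 100 ms baseline, 1000 ms pulse, 200 ms recovery; measurements
that reference "the final 700 ms" or "the initial 100 ms" are taken
relative to pulse onset, so any pulse ≥ 800 ms is compatible.

Measurement sets per step (the {5, 1, 10, 2} contract): membrane-
potential difference means are pulse mean minus baseline mean; the
block-step difference uses only the final 700 ms.  Definitions the
source toolbox leaves unstated are fixed here and configurable: spike
peaks are local maxima above 0 mV, thresholds sit at the last upward
crossing of dV/dt = 20 mV/ms before the peak, half-width is measured at
threshold + amplitude/2, AHP depth is threshold minus the post-spike
minimum; sag is the minimum-to-plateau rebound (plateau = mean of the
last 10 % of the pulse) and its time constant a least-squares single
exponential from the minimum to pulse end; spike rate is count/pulse
duration; adaptation is mean(last two ISIs)/mean(first two ISIs).  The
packaged reference table is used verbatim in the distance metric — its
spike-count/rate/ISI triple is internally inconsistent with any single
pulse duration, so no attempt is made to re-derive one measurement from
another.

Elimination: spikes at +20 pA; fewer than three spikes at +50 pA;
failure to repolarize after the +50 or +500 pA step (the mean of the
last 50 ms of recovery must return to within 10 mV of baseline — the
criterion is stated without a tolerance in the source, 10 mV is the
package's choice); spikes in the final 700 ms of the +500 pA pulse;
spikes in its recovery.  The hyperpolarizing step never eliminates.

## Distance metric and ranking

d(x, y) = Σ|x_i − y_i|/(N σ_i) with σ_i = 1 — implemented exactly as
printed in its source even though it is a scaled mean absolute
deviation rather than a Euclidean distance; a true L2 variant sits
behind `metric="l2"` for sensitivity checks.  Per-CIP distances are
averaged with equal weight per protocol (so individual measurements are
implicitly weighted by 1/N of their protocol).  Eliminated or failed
models carry the sentinel 100.  Ranks are unique: survivors by
distance, eliminated models after them, ties broken lexicographically
on parameter values.

## CBDR

Parameter "impact" is the range (max − min) of per-level marginal mean
distances — the stacking criterion is not specified by the source, so
this heuristic is a package decision.  Parameters are assigned
alternately to the y then x axis in descending impact (outermost =
highest), making the low-conductance corner the image origin.
Eliminated pixels render black; a sidecar table maps every pixel to its
model.

## Analyses

*Electrotonic.*  At DC the passive network is linear, so both
directions come from one dense transfer-impedance matrix Z = G⁻¹:
away from the soma A(x) = Z_ss/Z_sx, toward the soma A(x) = Z_xx/Z_xs,
L = ln A (natural log per the method's definition; its companion figure
caption implies log₁₀, a recorded inconsistency — the base is an
argument).  L is additive along unbranched paths up to the constant
junction term at the reference.

*bAP profiles.*  Three 2 ms, 800 pA somatic pulses at 20 ms intervals
(the inter-pulse interval is not stated in the source; 20 ms is the
package default).  Amplitude = per-location peak minus pre-train
baseline, sampled every 10 µm along a tree's distal-most path.

*Threshold-weight scan.*  Per location, bisection on log-weight between
10⁻⁴ and 10 µS (≈3 significant figures) for the smallest weight whose
single presynaptic spike drives the soma past −20 mV; the first-1 ms
local deflection (max − min at the synapse) is recorded at threshold,
and saturation is flagged when it reaches 95 % of the driving force
|V_rest − e|.  Locations where even 10 µS fails are recorded as
unreachable rather than scanned indefinitely.

## Synthetic fixtures

The reference reconstruction is not deposited, so all tests run on a
stylized morphology: a 15 × 12 µm somatic cylinder; one long, sparsely
branched tree (stem 200 µm, two bifurcation levels, 420 µm distal
reach); two shorter, heavily branched trees (depth 3, ~160–180 µm
reach); and a 90 × 3 µm axon stub.  Diameters taper 1.4 → 0.4 µm.
Total area ≈ 6,038 µm² and lumped passive input resistance ≈ 390 MΩ,
chosen to sit near the reference model's reported passive numbers
(7,297 µm², 414 MΩ).  The generator is deterministic given its seed and
emits valid SWC.

Ground-truth screening references are generated by simulating a known
grid member, which turns the whole strategy into a parameter-recovery
experiment: the generator must return at rank 1 with distance 0, and
off-grid generators must rank a grid neighbor first.  What passing
shows: the pipeline is self-consistent and can discriminate models
within published density ranges on a realistic-scale morphology.  What
it does not show: agreement with the original cell's recordings
(biological variability, session noise and the true morphology are not
emulated), or that the synthetic kinetics match the real channels.

## Problem sizes

The test suite screens an 18-model somatic grid and a 9-model
proximal-dendrite grid (with the 55/75/95 µm cutoff axis), scans
synapse locations at 10–60 µm spacing, and verifies solver oracles on
single compartments and 500 µm cables; the suite completes in under two
minutes on one CPU.  The acceptance script screens a 4-model grid
containing a passive-step-spiking member.  Grids of several hundred
models (the scale of the original study) run in tens of minutes through
the same entry points.

## Known limitations

* Kinetics are a synthetic stand-in; all quantitative spike-shape
  measurements inherit that.
* No calcium channels, calcium dynamics, HCN current, temperature/Q10
  scaling, or stochastic channel gating (white-noise current is the
  only stochastic element); sag is therefore ≈ 0 in every model.
* Parameter-space refinement across screening cycles (adjusting grids
  between runs) is deliberately human-in-the-loop: the package reports
  survivor maps and CBDR images but does not automate grid updates.
* The soma is a cylinder sequence; spines and axonal spike initiation
  are not modelled.
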