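# Model and methods

`dbsnet` simulates a cortico–subthalamic–pallidal network in which deep
brain stimulation (DBS) is applied extracellularly to the axon
collaterals of cortical pyramidal neurons projecting to the subthalamic
nucleus (STN) through the hyperdirect pathway.  The purpose of the model
is to separate the *antidromic* route of action (stimulus-evoked spikes
travelling from the collateral back to the cortical soma, where they
disrupt pathological beta-band firing) from the *orthodromic* route
(stimulus-evoked spikes travelling to the cortico-STN synapse, where
they drive the STN at the stimulus rate).

## Populations and cell models

Four populations of 100 neurons each:

* **Cortical pyramidal neurons** — the only multicompartment cells.
  Soma (35 × 25 µm cylinder), axon initial segment (20 × 1.2 µm), ten
  nodes of Ranvier (2 × 0.5 µm) alternating with ten internodes
  (500 × 1.4 µm), and a 500 µm unmyelinated collateral (0.5 µm,
  5 compartments) attached to the last node.  The soma is the minimal
  regular-spiking Hodgkin–Huxley model (I_Na, I_Kd, slow adaptation
  current I_M, leak; C_m = 1 µF/cm², g_M = 0.075 mS/cm²,
  τ_max = 608 ms).  Axon compartments carry I_Na⁺, a fast rectifier
  I_K⁺, a slowly inactivating D-type I_Kd and leak, with kind-specific
  densities (in pS/µm², Na: 90/200/533/500 and K: 120/30/10/50 for
  AIS/node/collateral/internode; Kd: 6/3/10/0; leak 0.23 everywhere;
  1 pS/µm² = 0.1 mS/cm²).
* **Cortical interneurons** — two-variable quadratic spiking neurons
  (fast-spiking parameterization a = 0.1, b = 0.2, d = 2 with the reset
  potential c = −65 mV), coupled all-to-all with the pyramidal cells.
* **STN neurons** — single-compartment model with Na, K, A-type K,
  L-type Ca, T-type Ca, Ca-activated K and leak currents and an
  intracellular Ca pool; it fires tonically (~15 Hz) and produces
  rebound bursts after release from hyperpolarization.
* **GPe neurons** — single-compartment pallidal model (leak, Na, K,
  T-type Ca, Ca, afterhyperpolarization currents); tonic at ~35 Hz and
  silenced by sustained inhibition.

The STN, GPe, soma and interneuron parameter sets are reconstructions
of the standard published formulations of those cell classes, shipped
as a versioned defaults file; every value can be overridden from a
YAML/JSON config.  Two constants (STN and GPe applied currents, 0.5 and
1.0 µA/cm²) were chosen so the autonomous rates land in the canonical
range.

### Axonal Na⁺ kinetics

The density table above fixes the conductances but not the gating.  Two
constraints shaped the chosen axonal Na kinetics:

1. The collateral carries 53.3 mS/cm² of Na against only 1 mS/cm² of
   fast K.  Any inactivation gate with h∞(−30 mV) ≳ 0.01 leaves enough
   persistent Na to sustain a stable depolarized plateau, which turns
   the collateral into a self-oscillator after the strong stimulus
   transient.  The collateral therefore uses node-type sigmoid gating
   with half-inactivation at −62 mV and a steep slope (complete
   inactivation when depolarized) and fast recovery (τ_h ≈ 6 ms at
   rest), so it reliably follows stimulus trains up to 250 Hz.
2. Antidromic invasion of the large soma through the low-Na AIS is a
   marginal, slow event (the soma charges through ~60 MΩ of proximal
   axial resistance).  The main axon (AIS, nodes, internodes) uses the
   same activation (half −46 mV, τ_m = 0.08 ms) but half-inactivation
   at −58 mV and *slow* recovery from inactivation (τ_h ≈ 20 ms near
   rest).  Slow recovery produces the frequency-dependent failure of
   antidromic invasion that the antidromic experiments measure: full
   recovery between 10 Hz pulses, partial recovery at ≥130 Hz.

Myelin is represented in the reduced single-cable way: internodal
specific capacitance and voltage-gated conductances are divided by a
wrap factor (default 40); leak is left unscaled, which is what
repolarizes the internode.  Axial resistivity is 30 Ω·cm.  Measured
conduction: ~2 ms along the 5 mm main axon, ~1.5 ms along the
collateral; antidromic somatic invasion (conduction plus somatic
ignition) takes 4–9 ms in total.

## Stimulation

The electrode is a point current source in a homogeneous medium
(σ = 0.2 S/m) at the origin of the collateral cloud.  The stimulus is
the monophasic rectangular pulse train
I_DBS(t) = i_D·H(sin 2πt/ρ_D)·[1 − H(sin 2π(t+δ_D)/ρ_D)] with the
pulse occupying (ρ_D/2 − δ_D, ρ_D/2] of each period.  Pulse edges are
aligned to the integration grid (a 60 µs pulse covers exactly six
0.01 ms steps) and the stimulus is held constant over each step.

The extracellular potential V_e = I/(4πσr) is sampled at collateral
compartment centers and coupled through the activating-function form:
the second spatial difference of V_e enters the cable equation through
the same axial-difference operator as the membrane potentials.  The
field drive acts on the edges interior to the collateral (the stated
DBS target); the junction edge carries no field term because the main
axon is treated as distant (zero field) and the jump would otherwise be
an artifact of that simplification.  A `full_field` switch applies the
field to every compartment instead.

Collateral geometry: all collaterals run parallel to z, centers drawn
uniformly in an annulus 270–340 µm around the electrode with ±120 µm
axial jitter.  The annulus is the region in which a 2.1–2.5 mA, 60 µs
pulse reliably initiates collateral spikes that also invade the soma
(closer collaterals see nonphysically large field transients for a
point source; farther ones are not recruited).  The STN box
(700 × 700 × 400 µm) surrounds the synaptic terminals of the cloud and
the GPe box sits adjacent to it.

Interneurons are driven directly during the stimulus train (standing in
for their activation through cortical afferents): each pulse delivers a
1 ms depolarizing current (amplitude 60 model units) with a
per-interneuron latency uniform on [0, 12] ms, representing the
dispersion of the disynaptic route.  The jitter matters: it converts
the interneuron volley from a synchronous veto of every antidromic
invasion into a rate-dependent background inhibition, which is what
differentiates low- from high-frequency stimulation at the soma.

## Propagation modes

* `both` — the physiological case; the collateral is bidirectionally
  coupled, receives the field, and its terminal drives the STN.
* `orthodromic` — the junction between the last node and the collateral
  becomes one-way: descending cortical spikes still enter the
  collateral, but collateral depolarization does not influence the main
  axon (its axial conductance toward the node is zero), so no
  antidromic invasion occurs.
* `antidromic` — each collateral is represented by a pair of twins.
  Twin A is embedded in the cable, receives the field and carries
  antidromic spikes into the main axon, but has no synapse.  Twin B
  carries the cortical *output* to the STN synapses as an event copy of
  descending last-node spikes, delayed by the measured collateral
  transit time (1 ms default); descending spikes are recognized by the
  penultimate node having fired within the preceding 2 ms.  This
  arrangement does not capture spike cancellation inside the collateral
  itself; at high stimulus rates almost all cancellation happens in the
  main axon, so the approximation is cheap and close.

Collision annihilation of counter-propagating spikes in the main axon
is emergent from the membrane dynamics (verified against the fine-step
reference cable), not hard-coded.

## Parkinsonian state and synapses

Synapses are alpha-function conductances s(t) = (Δt/τ)·e^(1−Δt/τ) with
pathway rise times 0.8 ms (cortex→STN, GPe→STN), 0.2 ms (STN→GPe),
0.86 ms (GPe→GPe), 0.5 ms (cortex→interneuron) and 0.93 ms
(interneuron→cortex); excitatory reversal 0 mV, inhibitory −80/−85 mV.
Connectivity: each collateral contacts its 10 nearest STN neurons
(mean STN in-degree 10), each STN neuron is inhibited by its nearest
GPe neuron and excites its two closest GPe neurons, each GPe neuron is
inhibited by its two closest GPe neighbours, and cortex↔interneuron is
all-to-all.

The dopamine-depleted state combines (i) a per-neuron half-rectified
20 Hz sinusoidal current into each cortical soma (4.5 µA/cm² peak,
2 ms per-neuron phase jitter) producing synchronized beta-burst firing
at ~20 Hz, and (ii) gain multipliers
relative to the normal state: cortex→STN ×3, GPe↔STN ×1.5, GPe→GPe
×0.5.  `calibrate_parkinsonian` reproduces this calibration: it scales
the cortex→STN multiplier until the DBS-off STN beta-band power exceeds
the normal state's by a target factor with the low-frequency spectral
peak inside 13–30 Hz (the peak search is restricted to below 35 Hz
because the raw population-Vm spectrum of burst-locked spiking carries
strong harmonics of the rhythm).

Membrane current noise is Gaussian, zero-mean, SD 0.001 µA/cm², added
per neuron per step with √dt scaling.

## Numerics

Fixed step dt = 0.01 ms.  All nonlinear membrane dynamics (including
point neurons and the interneuron reset-after-step rule) advance with
classical RK4; gating rates of cable compartments are read from dense
lookup tables (0.05 mV grid) built from the exact rate functions.
Alpha-synapse states are advanced exactly (the alpha function is the
impulse response of a linear two-state filter).  The *linear* axial +
extracellular coupling of the cable advances by an implicit
backward-Euler step per dt using a precomputed 27 × 27 propagator per
network: the node–AIS coupling has λ·dt ≈ 15, far outside the explicit
RK4 stability region, so a fully explicit scheme at this step size is
impossible for this morphology.  The implicit step damps only sub-step
axial equilibration; halving dt changes population rates by well under
5 %, and single-neuron spike times agree with a pure RK4 reference
integration at dt = 0.25 µs to better than 0.2 ms over hundreds of
milliseconds.

Spikes are upward crossings of −10 mV with a 1 ms per-detector lockout.
A divergence guard aborts any run in which |V_m| exceeds 200 mV.

## Analysis

Population signals are the mean-subtracted sums of somatic membrane
potentials, decimated (anti-aliased) to 1 kHz.  Spectra use Welch's
method with 1 s Hann segments and 50 % overlap; the 1 s DBS-on epoch
therefore reduces to a single full-length segment.  Band powers are
trapezoidal integrals (beta 13–30 Hz; stimulus band f_DBS ± 2 Hz).

Antidromic attribution: every somatic spike is assigned to the most
recent pulse no more than 10 ms before it (the window covers the
measured 4–9 ms invasion latency); the probability of antidromic firing
is answered pulses over delivered pulses — equivalently the number of
antidromic spikes over the number of stimuli with at most one spike per
pulse — and the antidromic spike frequency is attributed spikes per
second of train.  Unique assignment avoids double counting when the
window exceeds the interstimulus interval.  STN entrainment uses a 5 ms
latency window.

## Protocol and problem sizes

The standard protocol per condition is a settling transient (discarded),
a 1 s DBS-off epoch immediately before stimulus onset, and a 1 s DBS-on
epoch, with the pre-stimulus state snapshotted and shared across the
stimulation conditions of one seed and mode.  Repeats are five seeds
that redraw network geometry, phases and noise while sharing the
calibrated gains.  The acceptance script runs the full five-repeat,
100-neuron antidromic sweep; the test suite runs one repeat of the
same sweep and one seed for the spectral orderings.

## What the synthetic network does and does not capture

The generator reproduces the study conditions: population sizes, the
connectivity scheme, the parkinsonian beta regime and the stimulation
geometry.  It does not model the striatum, GPi or thalamus, synaptic
plasticity, conduction-delay heterogeneity beyond the cable itself,
realistic electrode geometry or encapsulation tissue, or ion-
concentration dynamics beyond the STN Ca pool.  Passing tests show that
the implemented mechanisms reproduce the published frequency dependence
under these idealized conditions, not that they would do so in tissue.

## Known limitations

* The ring-shaped collateral cloud leaves a handful of STN neurons
  (typically 4–8 of 100 per seed) without cortical input; population
  entrainment saturates just above 0.9 rather than at 1.
* The antidromic spike frequency at 130 Hz stimulation runs ~10 Hz
  above the published ≈30 Hz: under the high-frequency barrage the
  somatic firing of this parameterization exceeds the original model's
  ceiling even though the per-pulse probabilities match.
* The 10 Hz antidromic response depends on the phase relation between
  the periodic stimulus and the deterministic 20 Hz rhythm (10 Hz
  pulses sample the rhythm at a constant phase).  Under the default
  protocol the sampled phase is favourable and the response is >90 %;
  control runs with a randomized rhythm phase show that unfavourable
  phase relations reduce it to ~60–80 %, because invasions during the
  post-burst/trough part of the cycle are vetoed by the stimulated
  interneurons.  A few neurons with tail phase offsets respond at
  70–80 % even under the default protocol.
* 20 Hz stimulation in this calibration *reduces* STN beta power
  instead of producing the published slight resonant increase: the
  pulse-locked interneuron volleys and antidromic resets scramble the
  phase coherence of the endogenous rhythm more than the 20 Hz
  orthodromic volleys add to it, at every stimulus/rhythm phase
  relation tested.  The high-frequency suppression directions all
  reproduce.
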