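# Model and methods

`ictalwave` simulates the generation and propagation of ictal
(seizure-like) discharges in a 1-D strip of cortical tissue bathed in a
pro-epileptic medium. Two synaptically coupled neuronal populations —
regular-spiking pyramidal cells (E) and fast interneurons (I) — are
described with the conductance-based refractory density (CBRD)
formalism, coupled to a full ionic micro-environment: intracellular
K⁺/Cl⁻/Na⁺ of both populations, shared extracellular K⁺/Cl⁻/Na⁺,
dendritic calcium, an optional glial potassium buffer, and the
extracellular-space (ECS) volume. This note records the model's
assumptions, the numerical choices, and the places where the published
formulation was ambiguous and a decision had to be made.

## The refractory-density core

Each population carries a density ρ(t, t*) of neurons over the time t*
elapsed since their last spike, together with membrane voltage U(t, t*)
and gating variables (delayed-rectifier n, M-current, Ca-dependent AHP
current) parameterized by t*. The density obeys a transport equation

    ∂ρ/∂t + ∂ρ/∂t* = −ρ H(U, g_tot),

whose sink H — the hazard — is the instantaneous firing probability
rate of a neuron at distance T = (V_th − U)/(√2 σ_V) from threshold,
with σ_V = σ_V0 √(1 + g_syn/g_L) the voltage noise grown by synaptic
drive (σ_V0 = 3 mV; a config switch selects the linear scaling). H is
the sum of a noise-crossing term A (an exponential-polynomial fit in T
with a correction in k = τ_m/τ_noise) and a drift term
B = 2√(2/π)[−dT/dt]₊ exp(−T²)/(1 + erf(T)), evaluated through the
scaled complementary error function for stability at suprathreshold T.
The A-term polynomial is clamped below T = −2.5, outside its fitted
range (B dominates there).

Fired mass re-enters at t* = 0; for 0 < t* < Δt_AP = 1.5 ms the
voltage is clamped to V_reset = −40 mV and the delayed-rectifier gate
to 0.5, while the slow gates (M, AHP) re-enter with their values at
the peak of the spike-release distribution ρH, carrying the adaptation
state across spikes. Depolarization block is modeled by a dynamic
threshold V_th = V_th0 + 100 mV · S((U∞ − V_DB)/w) with S the logistic
function, V_DB = −40 mV, and U∞ the voltage low-passed at 100 ms.

**Block-sigmoid width.** The published width of 7 mV makes the
threshold rise faster than the membrane potential (gain 100/7 per mV)
already 17 mV below V_DB, which pins the threshold gap at ≥ 20 mV under
any slow depolarization; the network is then provably silent, which
contradicts the tonic firing up to ≈ −40 mV in the original study's voltage
traces. The default width is therefore 2.5 mV, which keeps the block
confined to U∞ ≳ −46 mV while leaving sub-threshold excitability
untouched. The width is a config parameter.

## Discretization

- t* grid: uniform bins of width dt (characteristics-aligned upwind
  transport — the density shifts exactly one bin per step, so transport
  adds no numerical diffusion and total mass is conserved to machine
  precision). The last bin is absorbing: survivors merge into it with
  mass-weighted averaging of their state (quasi-stationary old age).
- Voltage and gating advance by exponential-Euler per bin; the
  second-order synaptic kinetics use the exact 2×2 matrix exponential
  of their drive-free part, so sub-dt rise times (GABA: 0.5 ms) remain
  stable at any step.
- Empty cohorts are skipped exactly: a bin can only acquire mass at
  t* = 0, so the state of a zero-mass bin cannot influence anything.
- The production path is a fused numba kernel; transcendentals are
  looked up in densely sampled tables (grid steps 1/32 mV, 1/128 in T,
  1/256 in exp(−x); linear interpolation, relative error < 1e-5).
  Tables are tested against the exact reference functions, and the
  per-operation reference implementations are validated against
  analytic oracles and a Monte-Carlo neuron ensemble.

## Membrane currents and synapses

Voltage-gated potassium currents (delayed rectifier n⁴, M-current, AHP
n² with α·[Ca]²(1−n) − β·n kinetics) follow the published rate functions
with removable singularities resolved by local Taylor expansion. The
published channel maxima are used at face value (4, 0.7, 0.4 µS/cm²; M
and AHP absent in interneurons). The voltage-equation leak is fixed by
the published resting time constants (τ_m0 = 28/9 ms for E/I), while its
reversal potential is the conductance-weighted mixture of the dynamic
K⁺/Cl⁻/Na⁺ Nernst potentials with the published per-ion leak
conductances (20/20/7 µS/cm²) — the two published leak descriptions are
mutually inconsistent as a single conductance, and the dynamic leak
reversal is what couples rising [K⁺]ₒ to depolarization.

AMPA, NMDA (with the 1/(1 + Mg/3.57·e^(−0.062V)) magnesium block at
Mg = 0.25 mM) and GABA-A conductances obey second-order kinetics whose
normalization makes the peak response to a rate impulse independent of
the rise/decay times. Glutamatergic and GABAergic resources depress by
the use-dependent (Tsodyks–Markram) rule with u = 0.2/0.1 and 500 ms
recovery. The maximal AMPA conductance onto E cells grows linearly
from 0 at x = 0 to its published maximum at x = L.

Representative neurons — passive observers at the two virtual
electrode sites — integrate the same membrane equation as a total time
derivative with the explicit sodium current g_Na m³h(V − V_Na). With
the published g_Na = 7 µS/cm² regenerative sodium spikes are impossible,
so the observers use the population's threshold-and-reset convention
and mark each spike with a +30 mV overshoot sample in the trace.

## Ion and volume dynamics

Intracellular balances follow the published bookkeeping: leak, active
(voltage-gated) and glutamatergic channel currents at the
population-mean voltage, the electrogenic 3Na/2K ATPase, KCC2 and
NKCC1 cotransport, the per-spike sodium load q_Na·ν, and the NCX
sodium entry tied to calcium extrusion. Extracellular amounts are
tracked as v·[X]ₒ with β = 10 intra/extracellular volume ratio and
α_I = 0.25 interneuron fraction; only potassium exchanges with the
bath (0.25 s⁻¹), diffuses along the strip (0.39 µm²/ms), and couples
to the glial buffer. The ECS volume relaxes (τ = 250 ms) toward an
osmotic target that shrinks when cells gain osmolytes.

Resolved ambiguities (each with a config switch or documented
rationale; signs were chosen so the mechanism matches the original description of it):

- **KCC2 sign.** The published formula combined with the published balance
  signs would make KCC2 import KCl exactly when efflux is
  thermodynamically favourable; the numerator sign is flipped so that
  KCC2 extrudes KCl when V_Cl > V_K (positive transporter value =
  influx, the NKCC1 convention).
- **NKCC1 saturation.** The published linear drive evaluates to ~3.8×
  the transporter's own named maximum at rest and would pull
  interneuron chloride toward ≈ 66 mM; the flux saturates at ±I_max
  (the published KCC2 form saturates at its maximum by construction).
- **Na/K-ATPase.** The kinetic-cycle pump uses the standard 16-term
  King–Altman denominator (the published list contains a duplicate and
  omits one term) and voltage-dependent sodium affinities
  K_Nai = 2.49·e^(−0.386U), K_Nae = 15.5·e^(12.1U) (U in volts). Its
  overall normalization is under-determined by the published expression
  and is calibrated once, from published constants only, so that 2·I_pump
  balances the resting potassium leak plus KCC2 efflux of E cells.
- **Resting closure.** The published leak set cannot be jointly
  stationary for K⁺ and Na⁺ (the 3:2 stoichiometry pins the pump at
  the sodium balance point); the residual passive resting flux of K⁺
  and Na⁺ is subtracted as a constant homeostatic offset, computed at
  the published initial state and mirrored consistently in the ECS.
  Chloride is deliberately left free: its slow loading toward the
  passive equilibrium is the epileptogenic clock of the model.
- **GABA-A chloride flux.** The chloride balance receives the chloride
  component of the GABA current, 0.8·g_GABA·(U − V_Cl) (the 4:1
  Cl:HCO₃ permeability mixture), which sustains activity-driven
  chloride loading even when U has reached V_GABA — the
  bicarbonate-shunt mechanism by which GABAergic activity loads
  chloride. A switch restores the literal full-current routing.
- **Electrogenic pump in the voltage equation.** The pump's net
  outward charge appears as −(I_pump − I_pump,rest) in the membrane
  equation (deviation form, so resting potentials are unchanged). This
  is the hyperpolarizing force that terminates discharges and spaces
  them; the published voltage equation omits it but the original description states
  it explicitly.
- **Calcium influx** uses the (V_Ca − U) driving force (the published
  sign would make calcium decrease with NMDA activity), and the glial
  buffer variable is read as *free* buffer, so it binds K⁺ above
  ≈ 15 mM and releases it at rest (the published k₂ sigmoid direction).
- The A-type potassium current is part of the original current set but has
  no published equations or parameters; it is not modeled.

## Noise

Interneurons receive an Ornstein–Uhlenbeck current (stationary SD
25 pA over the 3·10⁻⁵ cm² membrane area, τ = 4 ms), one independent
stream per spatial node derived from the master seed by counter-based
splitting (changing the node count does not reorder streams). The OU
update is exact (decay plus scaled Gaussian increment). Runs are
bit-reproducible for a fixed seed.

## Simulated regime and its relation to the published one

With the published parameter set and the resolutions above, the model
produces, robustly across seeds: a stable quiet baseline at the published
concentrations; noise-seeded interneuron firing whose GABAergic events
load chloride; spontaneous repeating discharges with the published
event sequence (interneuron firing and outward GABAergic
holding-current events lead, glutamatergic components follow, [K⁺]ₒ
rises steeply to 9–11 mM and undershoots below baseline after
termination, [Na⁺]ᵢ peaks later than [K⁺]ₒ); ECS shrinkage of 30–40%
per cycle; propagating discharge fronts whose speed is proportional to
the connection length λ and insensitive to blocking potassium
diffusion; and near-synchronous initiation with weak pre-onset rises
when a 0.2 all-to-all fraction is added.

Two quantitative features of the published regime are not reproduced
and are reported as such rather than tuned toward: discharges last
seconds (clusters of 1–5 s) recurring every ~15 s instead of tens of
seconds recurring on a minutes scale, and all propagation speeds carry
a uniform factor ≈ 2 (speed/λ ≈ 11 s⁻¹ instead of 4.2 ± 0.7 s⁻¹;
control median ≈ 0.5 mm/s instead of 0.26). The root cause is a
near-synchronous population flash at discharge onset instead of a
sustained asynchronous tonic phase; the flash's synaptic output also
ignites adjacent tissue faster than local ionic ripening would. The
flash character is invariant under time-step refinement (0.25–1 ms)
and under the published alternatives that were tested (linear σ_V,
7 mV block width, literal hazard polynomial), so it appears to be a
property of this reconstruction of the model rather than a numerical
artifact.

## Measurement procedures

Discharges are detected at a site as [K⁺]ₒ exceeding baseline + 3 mM
(sustained ≥ 0.5 s), ending when it stays below baseline + 1 mM for
5 s; thresholds are config parameters (the original description fixes none). Front
speed is estimated two ways: (i) the slowest-fragment slope — first
threshold crossing (6 mM) per node, a line fitted over 5-node windows,
speed = 1/max|dt/dx|, excluding apparent fragments faster than 10 mm/s
and fragments spanning more time than their own discharge window; and
(ii) the half-maximum delay between the two electrode sites divided
into their separation, with unresolved (|lag| ≤ 50 ms) and
failed-to-propagate cases flagged rather than numbered. Per-run
statistics exclude the first discharge (initialization transient) and
report medians with 25–75% interquartile ranges. The K⁺-electrode
calibration transform [K⁺]ₒ = 2.5·e^(S·V), S = 0.044 mV⁻¹, and its
inverse are provided for electrode-style traces.

## Ensemble validation

The density approximation is validated against a Monte-Carlo ensemble
of 4000 individual neurons with identical membrane equations, dynamic
threshold and reset rules, individual OU noise calibrated to σ_V0, and
frozen ion concentrations, under a 0.7 µA/cm² step. The protocol uses
a classical sub-threshold reset (−55 mV) on both sides: with the
depolarized reset of the network model (−40 mV, above the base
threshold), each neuron becomes a threshold-adaptation burst oscillator
whose phase is carried by U∞ — a per-neuron slow variable outside the
t*-density state space — so the comparison would measure that
representational limit instead of transport accuracy. The relative L2
error of the rates (5 ms bins, 300 ms transient cut) is 0.12–0.14
across seeds.

## Problem sizes

The test suite and the reproduction script run at dt = 1 ms (one t*
bin per step), 80 ms of resolved refractory history plus the absorbing
bin, 48 spatial nodes over 2.5 mm, and 300–400 s of simulated time —
the package's desk-scale working point, chosen so a full scenario run
takes minutes on one core. The discharge regime is unchanged at finer
settings (dt down to 0.25 ms, 64 nodes, 100–120 ms of history were
checked); defaults in `ScenarioConfig` are dt = 0.5 ms, 64 nodes.

## Known limitations

- 1-D geometry, two populations, single-compartment neurons.
- The tonic-phase and absolute-speed mismatches described above.
- The hazard's A-term is an empirical fit; outside T ∈ (−2.5, 10) it
  is clamped/truncated.
- Bicarbonate is a fixed parameter; pH and dynamic HCO₃⁻ are out of
  scope, as are 2-D sheets and axonal conduction delays.
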