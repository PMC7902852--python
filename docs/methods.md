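# Model and methods

## The model

`boutonsim` simulates stochastic calcium handling and vesicle release in a
single CA3 presynaptic terminal ("bouton") with an intracellular calcium
store (endoplasmic reticulum, ER).  Seven molecular species are represented
as populations of continuous-time Markov chains:

* **VDCC** — a P/Q-type voltage-dependent calcium channel: four closed
  states and one open state; forward rates a_i(V) = a_i0 exp(V/V_i) and
  backward rates b_i(V) = b_i0 exp(−V/V_i).  An open channel conducts
  calcium at the Goldman-type single-channel flux
  A·V·N_A·[B − e^(−V/C)] / (2F·[1 − e^(V/C)]), scaled linearly by the
  extracellular concentration relative to the 2 mM reference.
* **RyR** — a ryanodine receptor with low- and high-activity gating modes
  (14 states, five open).  Open receptors release ER calcium at
  kFlux·[Ca²⁺]_ER per channel.
* **IP3R** — the eight-state ligand-binding scheme with one IP3 site, one
  activating and one inhibiting calcium site; only the state with IP3 and
  activating calcium bound conducts.  IP3 is a clamped configuration
  parameter (default 0; the production cascade is outside the model).
* **SERCA** — a six-state pump cycle with explicit sequential binding of two
  cytosolic ions, translocation, and luminal release; one forward cycle
  moves exactly 2 ions cytosol → ER.
* **PMCA** — a three-state extrusion cycle (bind, transport, reset) removing
  one ion per cycle, paired with a plasma-membrane leak (see below).
* **Calbindin-D28k** — an immobile buffer with an independent high- and
  medium-affinity pair of sites, sequential binding with combinatorial
  multiplicity.
* **Release sensor** — each of the 7 docked vesicles carries a dual sensor:
  a synchronous unit with 5 cooperative calcium sites (unbinding scaled by
  b^(j−1)) and an asynchronous unit with 2 sites.  Fusion fires at γ from
  the fully bound synchronous unit, at a·γ from the fully bound
  asynchronous unit, and at δ from any docked state (spontaneous).  A fused
  site is refractory with an exponential dead time ε before a reserve
  vesicle can dock at the refill rate.

All rate constants ship in a flat, override-able table keyed by the
conventional symbols; the values are the published set for this terminal,
used as printed at 34 °C without temperature rescaling.  The IP3R binding
rates are interpreted in M⁻¹s⁻¹ (the magnitudes 4×10⁸ … only reproduce the
original model's dissociation constants in those units, e.g. b1 = a1·d1 =
52 s⁻¹).  The unprinted SERCA first-binding rates default to the printed
second-binding rates (sequential equal-rate binding), and the unprinted
unbinding partners X21/Y21 default to X10/Y10.

## Geometry and compartments

The spatial bouton is reduced to well-mixed pools:

| pool  | volume (µm³) | contents |
|-------|--------------|----------|
| bulk  | 0.936        | most calbindin, 70 % of SERCA, PMCA + leak, IP3R |
| az    | 0.005        | active-zone shell sensed by the docked vesicles |
| vdcc  | 0.020        | VDCC influx, RyRs, 30 % of SERCA |
| er    | 0.039        | ER lumen (luminal side of SERCA, source of RyR/IP3R flux) |
| ext   | clamped      | extracellular reservoir, 2 mM (4 mM protocol supported) |

The canonical bouton is the 0.5 × 0.5 × 4 µm cuboid (plasma membrane
8.5 µm²) minus a 0.1 × 0.1 × 3.9 µm ER rod (membrane 1.58 µm²).  SERCA
count comes from the 5500 µm⁻² density on the ER membrane (8690 pumps);
PMCA density defaults to 180 µm⁻² (1530 pumps); RyR = 40 and IP3R = 20
copies; calbindin is 45 µM partitioned across the cytosolic pools in
proportion to volume.  PMCA density, RyR/IP3R counts and the calbindin
concentration are not published for this terminal and are exposed as
configuration parameters.  A geometry scaled to the 0.39 µm³ of an
EM-reconstructed terminal (same densities, conductances scaled with volume)
is provided as `reconstructed_like`.

Diffusion between pools is first-order exchange, flux a→b = g·[Ca]_a with a
symmetric conductance g (µm³/s).  The three conductances are the model's
spatial-coupling calibration:

* vdcc↔bulk = 25 — sets the ~1 ms residence of influx in the channel
  subdomain;
* vdcc↔az = 1.1 — the direct (distance-attenuated) coupling between the
  channel cluster and the active zone, calibrated so the single-AP release
  probability of the 80-VDCC Control model falls in 0.10–0.20 (shipped
  value gives ≈ 0.13–0.15);
* az↔bulk = 16 — returns AZ calcium to the bulk on a ~0.3 ms free-ion
  timescale (the buffered AZ residual relaxes over tens of milliseconds,
  which is the facilitation memory of the model).

Because the bouton is closed (no axonal escape), total residual calcium
decays at the pump-limited rate; with buffer capacity κ ≈ 200 this gives a
~1 s free-calcium tail rather than the ~100 ms seen with spatial escape.
The tens-of-milliseconds component of paired-pulse memory is instead
carried by the buffered AZ residual and by asynchronous-site occupancy
(koff = 13 s⁻¹, τ ≈ 77 ms).

**SERCA placement.**  The ER lies ~50 nm from the channel cluster in this
terminal, so 30 % of the SERCA population (and the RyRs) sense the VDCC
subdomain rather than the bulk.  This placement is what lets SERCA
buffering attenuate the active-zone transient: blocking the stores then
raises the single-AP release probability by a factor ≈ 2–3 at matched
channel count, reproducing the Control < Stores-Blocked ordering.  With all
SERCA on the bulk the two configurations are nearly indistinguishable in a
well-mixed model.

**Plasma-membrane leak.**  The leak is a fixed-rate source, first-order in
the clamped extracellular concentration: N_leak sites each firing at
kpmleak = 12.5 s⁻¹ (scaled by [Ca]_out/2 mM).  N_leak is calibrated at
build time so the mean-field net calcium flux into the cytosol vanishes at
the 100 nM resting point — it balances PMCA extrusion minus the small
resting influx through VDCCs at −70 mV and the net resting ER release.
This pins the resting state: the unstimulated model holds 100 nM cytosolic
and 250 µM ER calcium to within a few percent over seconds, and the printed
SERCA rates alone put the ER equilibrium at ≈ 248 µM with a refill time
constant of ≈ 9.8 s after emptying — no retuning of published rates.

## Stimulus

The AP template is a skewed Gaussian depolarization (rise σ = 0.30 ms,
decay σ = 0.55 ms, FWHM 1 ms), rest −70 mV.  The source model's waveform is
unpublished, so the template is a calibration input.  The default **peak is
0 mV**: at a +30 mV overshoot each AP would inject ~28,000 ions
(~350/channel), and a 20 Hz × 1 s train would then load the closed bouton
with ~0.5 mM-equivalent calcium against ~1.2×10⁵ ions of buffer capacity
and a ~1.5×10⁵ ions/s PMCA ceiling — calcium would stay micromolar for
seconds, newly docked vesicles would immediately re-fuse through the
asynchronous sensor, and the readily-releasable-pool recovery time constant
could never approach its ~3 s target.  At a 0 mV peak (~96 ions per channel
per AP) the pumps clear the train load between stimuli and the recovery is
refill-limited.  Protocols: single AP (50 ms), paired pulse (total
30 ms + ISI; ISI grid 20–100 ms by 10, 120–200 ms by 20), and trains
(20 AP at 10/20/50 Hz; tabulated totals 2.05 s at 20 Hz and 450 ms at
50 Hz).

## Stochastic integration

The configuration is compiled to a flat network: one integer species per
Markov state per population, one per free-calcium pool, plus cumulative
influx/efflux ledger counters.  Every transition, flux, leak and exchange
hop is a channel that is first-order in its source species.

The production integrator is an adaptive tau-leap with three exact
sub-schemes chosen per channel:

* **Pool outflows.**  Every calcium-consuming channel's propensity is
  proportional to its pool's free-ion count, so the pool's joint loss over a
  step is drawn as Binomial(N, min(1, C·τ/N)) — unbiased in the mean and
  structurally unable to overdraw the pool — and partitioned multinomially
  among the consuming channels.
* **Voltage-gated population at rest.**  Between APs the membrane sits at
  rest and the VDCC scheme is calcium-neutral, so its states are propagated
  *exactly* with cached matrix exponentials e^(Qτ) over a τ ladder
  (cap/2^k).  This removes the stiffest process in the model — subthreshold
  closed-state flicker at ~1.5×10⁴ s⁻¹ — from the step-size restriction
  while keeping the resting open probability (and hence resting influx)
  unbiased.
* **Sole-outflow channels** (e.g. the fast PMCA reset state) use exact-decay
  binomials.
* Everything else draws Poisson counts (with a three-term inversion for
  means < 0.02).

The step is capped at 1 µs while |V − rest| > 1 mV (matching the source
model's resolution during APs) and at 0.25 ms otherwise, with a per-pool
stability bound τ ≤ 0.8·N/C.  A step that would still drive any count
negative is halved and redrawn (hard failure below 10 ns).  Voltage-
dependent rates are evaluated at the step midpoint during APs.

An exact SSA kernel (Gillespie direct method, exact for propensities held
piecewise-constant on a 1 µs grid during APs) serves as the validation
oracle on reduced configurations, and a deterministic mean-field integrator
(scipy BDF on the expected-value equations of the identical network) is the
law-of-large-numbers oracle and the engine for the resting-state and
ER-refill calibrations.  Trials are seeded individually (base_seed + index)
and are bitwise reproducible.

Exact integer conservation holds by construction: every channel's
stoichiometry preserves free + sensor/pump/buffer-bound + extruded − influx,
and the test suite checks the identity along full trajectories.

## Release statistics

A trial is a success for a stimulus if ≥ 1 vesicle fuses (any pathway)
within 20 ms of that AP onset, truncated at the next onset for ISIs below
20 ms.  Pr is the success fraction; PPR = Pr₂/Pr₁; facilitation is
Pr_n/Pr₁; P₁₁ is the probability of a second-pulse success given a
first-pulse success.  Standard errors are bootstrap over trials (1000
resamples, seeded).  CV uses the population standard deviation (ddof = 0),
so the CV of a Bernoulli success indicator equals the binomial form
√((1 − Pr)/(n·Pr)) with n = 1.  Exponential recoveries (ER refill, RRP
recovery) are least-squares fits of y = A(1 − e^(−t/τ)) + y₀.

The readily-releasable-pool refill rate defaults to 0.34 s⁻¹ per empty
site (1/2.94 s).  After a depleting 20 Hz × 1 s train the fitted recovery
time constant of the mean docked-vesicle count is ≈ 3.0 s — slightly above
1/refill because rare asynchronous re-fusions during the post-train calcium
tail delay net docking.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions — canonical geometry, printed
rate tables, resting concentrations, VDCC sweep 40–160, RRP of 7,
Control/Stores-Blocked configurations — under a well-mixed three-pool
approximation of an intrinsically spatial system.  Nanodomain coupling,
spatially heterogeneous channel placements, mobile buffering and axonal
calcium escape are not represented; their net effects are folded into the
calibrated exchange conductances and SERCA placement.  Passing tests
therefore demonstrate the *mechanistic orderings* of the store's
contribution (higher Pr when stores are blocked; larger facilitation, P₁₁
and reliability with functional stores at matched Pr; PPR declining with
ISI and with intrinsic Pr) and the *calibrated absolute numbers* of the
resting state, ER refill and RRP recovery — not a quantitative match to
figure-level trajectories of the spatial model.  One known qualitative
departure: facilitation in this model grows with buffer saturation before
the Pr₂ ceiling cuts in, producing a local PPR maximum near Pr₁ ≈ 0.1
inside the otherwise inverse PPR–Pr₁ relation.

## Numerical choices and degenerate inputs

Initial states are the per-population stationary distributions at the
resting ligand values (largest-remainder rounding to integer counts), so
runs start at equilibrium rather than with a synthetic transient.  The
stationary solver flags reducible chains (e.g. IP3R at [IP3] = 0) and
returns the law of the terminal class.  Empty populations are compiled
away; a configuration whose stimulus window is not covered by the simulated
time is rejected at construction.  Exponential fits reject constant series
and report covariance; the PPR and P₁₁ estimators raise on zero
denominators rather than returning sentinels.
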