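# Model and methods

## The circuit

`barrelsim` simulates one layer-4 (L4) barrel of rodent somatosensory
cortex together with its thalamic input from one barreloid of the ventral
posterior medial nucleus (VPM). Three populations interact:

* **T** — 200 thalamic relay neurons, modeled as spike sources only;
* **E** — 1600 excitatory L4 neurons;
* **I** — 150 fast-spiking (FS, parvalbumin-type) inhibitory L4 neurons.

The scientific question the model addresses is how this circuit passes
brief, synchronous touch signals to the excitatory population while
suppressing the slow, self-generated (reafferent) signal of whisking,
even though both arrive through the same thalamic axons. The answer the
model embodies: feedforward inhibition tracks the thalamic rate and
cancels the slow signal, while the ~0.85 ms delay of the I→E synapse
leaves a brief *window of opportunity* after a synchronous thalamic
volley during which E cells can fire before inhibition arrives.

## Single neurons

Cortical neurons are single-compartment modified Wang–Buzsáki models with
a transient sodium current (instantaneous activation, `I_Na =
g_Na·m_inf(V)³·h·(V−V_Na)`), a delayed rectifier `g_Kdr·n⁴·(V−V_K)`, a
leak, and — in E cells only — a slow potassium adaptation current
`g_KZ·z·(V−V_K)` with `z → z_inf(V)` over `tau_z = 60 ms`. The h and n
kinetics are scaled by `phi_kin = 0.2`, producing relatively wide spikes;
the z kinetics are not scaled. E and I cells differ only in leak
(`g_L` = 0.05 vs 0.1 mS/cm²) and adaptation (`g_KZ` = 0.5 vs 0).
Populations are internally homogeneous.

Units are mV, ms, mS/cm², µA/cm², µF/cm²; with `C = 1` the membrane
equation reads `dV/dt = −ΣI_ion − I_syn + I_inj` numerically.

The resting state is found by slaving all gates to their steady states
and root-finding the voltage nullcline on [−90, −40] mV, taking the first
zero crossing from below (the second crossing is the spike threshold).
The reference resting potentials come out at −65.08 mV (E) and −65.04 mV
(I); these are regression-tested values of this implementation, not
published constants.

## Synapses and connectivity

Only fast receptors are modeled: AMPA (decay `t_AMPA = 2 ms`, reversal
0 mV) and GABA_A (`t_GABAA = 3 ms`, −85 mV). A presynaptic spike, after
the pathway delay, increments the presynaptic gate by `1/t_syn`; gates
decay exponentially. The conductance neuron i receives through pathway
post←pre is

    G_i(t) = tau_syn_all · (g / sqrt(K)) · Σ_j C_ij s_j(t),   tau_syn_all = 1 ms

with `C_ij ∈ {0,1}` sampled independently with probability `K/N_pre`
(binomial in-degree with mean K; no autapses in EE and II). The six
pathway parameter sets (delay ms / K / g mS/cm²) are ET 1.0/50/0.15,
IT 1.0/75/0.2, EE 1.0/200/0.2, IE 1.0/400/0.6, EI 0.85/25/0.7,
II 0.5/25/0.55.

**Why sqrt(K) scaling.** The normalization of the summed gates is the one
genuinely open design point: candidate conventions in the balanced-network
literature are `g`, `g/K`, and `g/sqrt(K)`. The choice is pinned down
empirically by the unitary PSP amplitudes the parameter set is
calibrated to (ET +1.1, IT +1.03, EE +0.73, IE +1.33, EI −1.92, II −1.28 mV):
with `g/sqrt(K)` the simulated single-connection PSPs land within 1% of
all six values (a leak-only closed form gives the same answer
analytically), while `g/K` misses them ~7× low and unscaled `g` ~7× high.
The package therefore implements `g/sqrt(K)` and regression-tests the
full PSP table at ±10%.

## Thalamic drive

All T neurons share one generating function

    F_T(t) = A_T [1 + B_T sin(2π t/tau_w + phi_w)] + (C_T/tau_c)·rect(t)

with `tau_w = 100 ms`, `B_T = 0.25`, `phi_w = π/2`, and a touch rectangle
of `tau_c = 3 ms` at `t_c = tau_w/2` in every cycle carrying `C_T` spikes.
States: (A_T, C_T) = (6, 0) quiescent, (14, 0) whisking, (14, 0.6)
whisking+touch. Spike trains are statistically independent inhomogeneous
Poisson processes with this intensity, sampled by per-step Bernoulli
draws at the integrator grid (`p = F_T·dt ≤ ~0.012` even at the touch
peak, so the at-most-one-spike-per-bin truncation is negligible); an
exact thinning sampler is included and cross-validated against it.
`B_T` is kept at 0.25 in all states — only A_T and C_T switch with
state, and no cycle-averaged statistic depends on B_T — but a drive with
`B_T = 0` can be configured where an unmodulated quiescent state is
wanted.

With `phi_w = π/2` the touch onset sits at the minimum of the sinusoid,
so the 25 ms pre- and post-touch windows receive identical sinusoidal
contributions and the thalamic touch response satisfies E[R_T] = C_T
exactly — a useful closed-form check on the whole sampling path.

## Integration

Classical RK4 with fixed step `dt = 0.05 ms`. Synaptic gates are *not*
integrated inside the RK4 stages: between arrivals the gate ODE is
exactly solvable, so each neuron's AMPA and GABA_A conductances are
decayed analytically to the substage times and arrival jumps are applied
at step boundaries. All AMPA inputs to a neuron share one state variable
(common decay time and reversal), likewise GABA_A; pathway strengths
enter through the per-edge jump `tau_syn_all·g/(sqrt(K)·t_syn)`. This
keeps the integrator's order intact in the presence of discontinuities
and reduces per-step work to one exponential decay plus sparse pushes of
the spikes that arrive that step.

Delays are integer multiples of dt (all reference delays are; off-grid
delays are an error unless rounding is explicitly enabled). Spike
delivery uses a ring buffer of per-step spike lists; a spike emitted at
step k first affects its targets at step `k + delay/dt`, verified on a
two-neuron fixture where the network path reproduces a standalone RK4
with closed-form conductance to machine precision.

Spikes are upward crossings of −20 mV with a 2 ms lockout. Model spikes
overshoot 0 mV, so counts are insensitive to the threshold (tested
against a 0 mV criterion).

**Gate projection.** At dt = 0.05 ms the spike upstroke is stiff enough
(g_Na = 100 mS/cm² with slow inactivation) that raw RK4 truncation error
can push h slightly above 1, which feeds back through I_Na and, under
sustained drive, eventually diverges; at dt = 0.025 ms the problem
disappears. Since the exact flow never leaves [0,1], the integrator
projects h, n, z back onto [0,1] after every step. The residual cost is
a small rate bias at the reference step (a few percent for a cell driven
by constant current near its periodic-firing regime); in the fluctuation-
driven network, halving dt changes population rates and touch responses
by less than the realization-to-realization spread, which is tested.

Initialization: every neuron at its resting state; the first 0.5 s is
discarded from all statistics. Runs are bit-reproducible from
configuration plus seed: connectivity, thalamic sampling and
halorhodopsin draws use independent substreams spawned from the run seed,
and experiment sweeps reuse the same per-realization seeds at every swept
value so comparisons across values are paired.

## Optogenetics

Halorhodopsin (a light-gated chloride pump) is expressed in a fraction
`f_halo` of I neurons (`round(f_halo·N_I)` cells, chosen by a seeded
shuffle). While the light is on, each expressing (Hr⁺) cell receives a
constant current `I_halo = −2 + 1·x` µA/cm², `x ~ U[−1,1]` (so
I_halo ∈ [−3,−1]), and its GABA_A reversal is depolarized by
`ΔV = −4·I_halo` mV (chloride loading), i.e. +4 to +12 mV. Hr⁻ cells and
light-off runs are untouched. At `f_halo = 1` light *increases* both E
and I rates (the paradoxical effect of inhibition-stabilized circuits);
at `f_halo = 0.5` the Hr⁺ cells are suppressed while Hr⁻ and E cells
increase — the sign pattern seen experimentally.

## Metrics

`nu` is the population- and time-averaged rate over the post-transient
window. The touch response `R` of a neuron is its spike count in the
25 ms after touch onset minus the count in the 25 ms before, averaged
over touches (only touches with full ±25 ms coverage) and neurons.
PSTHs use 1 ms bins (binning is a package choice). Runaway excitation is
flagged when `nu_E` exceeds 20 spikes/s in any sliding 500 ms window —
an order of magnitude above any excitatory rate the stable circuit
produces, so the flag is insensitive to the exact threshold.

## Problem sizes

The full network (1600 E + 150 I + 200 T) is always simulated; what is
scaled is sampling. Quantitative touch-response checks use 5.5 s of
analyzed time per realization with 3–5 realizations; sign and ordering
checks (rate curves, saturation, optogenetic patterns, runaway brackets)
use 2–3.5 s per condition, where the effects are many standard
deviations wide. The acceptance script uses 5 realizations × 5.5 s for
touch responses and 3 × 5.5 s for baseline rates.

## What the generator does and does not emulate

The synthetic thalamic drive reproduces the cycle-averaged rate, the
phase-locked modulation and the brief touch volley, with every T neuron
sharing one preferred phase and touch occurring once per cycle. It does
not model inter-neuron correlations beyond the shared rate, burst/tonic
firing modes, phase heterogeneity, whisk-to-whisk variability, or
synaptic short-term plasticity (absent from the circuit model as well).
Passing tests therefore demonstrate properties of this idealized drive
and circuit, not of recorded thalamic spike trains; in particular the
touch-response saturation and suppression effects depend on touch
volleys being synchronous across the population, which is an assumption,
not a measurement.

## Known limitations

* Baseline inhibitory rates: at quiescent drive (A_T = 6, C_T = 0) the
  reference circuit as parameterized here produces nu_I ≈ 9 spikes/s,
  which lines up with a balanced-rate estimate
  (√K_IT·g_IT·ΔV_exc·A_T / (√K_II·g_II·ΔV_inh) ≈ 7 Hz) and with the
  near-proportional nu_I–A_T curve the model itself produces, but is
  below the tens of Hz that FS neurons show in vivo at baseline. The
  mismatch is reported as computed.

* One barrel, homogeneous populations, no non-FS interneurons, no NMDA /
  GABA_B receptors, no synaptic depression or facilitation, no
  distance-dependent connectivity.

* The integrator is fixed-step by design; event-driven or adaptive
  schemes are out of scope.
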