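# barrelsim

A conductance-based spiking-network model of one layer-4 (L4) barrel of
rodent somatosensory cortex driven by thalamic (VPM) input, for
computational neuroscientists studying how cortical circuits separate
self-generated from external sensory signals.

During whisking, thalamic relay neurons carry both a slow reafferent
signal (the whisker's own motion) and brief, synchronous volleys evoked
by touch. L4 excitatory neurons respond almost exclusively to touch.
This package implements the circuit model that explains the computation:
fast-spiking (FS) inhibitory neurons track the thalamic rate and cancel
the slow signal (ν_I ∝ A_T, ν_E < 1 Hz), while the ~0.85 ms delay of the
I→E synapse opens a *window of opportunity* after each touch volley in
which excitatory cells fire before inhibition arrives (R_E ≈ 0.34
spikes/touch at the reference delay, ≈ 0.01 with the delay removed). It
also models optogenetic silencing of the FS population with
halorhodopsin, including the paradoxical effect that appears when all
inhibitory cells are hyperpolarized.

## The model

* **Populations** — 1600 excitatory (E) and 150 FS inhibitory (I)
  cortical neurons, driven by 200 thalamic (T) spike sources; each
  pathway post←pre is a sparse random graph with connection probability
  K/N_pre.
* **Neurons** — single-compartment modified Wang–Buzsáki:
  `C dV/dt = −I_L − I_Na − I_Kdr − I_KZ − I_syn + I_inj`, with
  instantaneous sodium activation m_inf(V), gating kinetics for h, n
  scaled by φ = 0.2, and a slow adaptation current (τ_z = 60 ms) in E
  cells only.
* **Synapses** — exponential AMPA (2 ms, 0 mV) and GABA_A (3 ms, −85 mV)
  conductances; the total input through a pathway is
  `G = τ_syn,all · (g/√K) · Σ_j C_ij s_j`, the balanced-network √K
  scaling, calibrated so that all six unitary PSP amplitudes match their
  reference values (see `docs/methods.md`).
* **Thalamic drive** — independent inhomogeneous Poisson trains with a
  shared intensity
  `F_T(t) = A_T[1 + B_T sin(2πt/τ_w + φ)] + (C_T/τ_c)·rect(t)`:
  a 10 Hz whisking modulation plus a 3 ms touch rectangle of integral
  C_T spikes per touch each cycle.
* **Integration** — fixed-step RK4 at Δt = 0.05 ms with exact
  (analytic) gate decay between spike arrivals and ring-buffer delay
  delivery; bit-reproducible from config + seed.

## Worked example

Unitary PSP table (one presynaptic spike through one connection onto a
resting neuron):

```
$ barrelsim psp-table
pathway receptor  tau_delay_ms   K  g_mS_cm2  V_extr_mV
     ET     AMPA          1.00  50      0.15      1.092
     IT     AMPA          1.00  75      0.20      1.021
     EE     AMPA          1.00 200      0.20      0.729
     IE     AMPA          1.00 400      0.60      1.325
     EI   GABA_A          0.85  25      0.70     -1.910
     II   GABA_A          0.50  25      0.55     -1.277
```

Positive values are EPSPs, negative are IPSPs, in mV. A full
whisking-and-touch run (5.5 s analyzed after a 0.5 s transient):

```python
from barrelsim import (reference_circuit, run_simulation,
                       SimulationProtocol, ThalamicDrive)
from barrelsim.drive import touch_onsets
from barrelsim.metrics import population_rate, touch_response

drive = ThalamicDrive.whisking_touch()          # A_T=14 Hz, C_T=0.6
proto = SimulationProtocol(duration=5500.0, transient=500.0, seed=4)
res = run_simulation(reference_circuit(), drive, proto)

onsets = touch_onsets(drive, 5500.0)
onsets = onsets[onsets >= 500.0]
print(touch_response(res.spikes["T"], onsets))  # 0.599  spikes/touch
print(touch_response(res.spikes["E"], onsets))  # 0.336
print(touch_response(res.spikes["I"], onsets))  # 1.283
print(population_rate(res.spikes["E"], (500, 5500)))  # 3.96 spikes/s
```

The thalamus adds 0.6 spikes per touch (by construction of F_T); each E
cell converts that into about a third of a spike per touch — almost all
of its firing — while I cells fire 1–2 spikes per touch on top of their
high background rate. Setting the I→E delay to zero
(`reference_circuit().with_pathway("EI", tau_delay=0.0)`) collapses the
E response to ~0.01 spikes/touch: the window of opportunity is the whole
effect.

The `barrelsim` CLI also exposes `simulate`, `sweep` (any dotted
parameter path, e.g. `circuit.pathways.EE.g`), `halo` (optogenetic
runs) and `reference-config` (dump the reference parameter set as YAML).

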