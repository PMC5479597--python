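"""Fixed-step RK4 network integrator with delayed synaptic interactions.

The circuit state is integrated with a classical 4th-order Runge-Kutta
scheme at a fixed step (0.05 ms reference).  Synaptic gates are not folded
into the RK4 stages: between spike arrivals the gate ODE is exactly
solvable, so within a step each neuron's conductances are decayed
analytically to the substage times, and arrival jumps are applied at step
boundaries.  This keeps the integrator's order intact in the presence of
the discontinuous gate updates.

Spikes are detected as upward crossings of -20 mV with a 2 ms lockout and
assigned to the step boundary at which the crossing is first seen.  A
spike emitted at step k by a pathway with delay d steps first affects its
targets' conductances during step k + d.  Because the six pathways have
fixed per-pathway delays, delivery uses a ring buffer of per-step spike
lists rather than per-synapse queues.

All AMPA conductances a neuron receives are accumulated in one state
variable (they share the 2 ms decay time and 0 mV reversal), and likewise
all GABA_A conductances (3 ms, -85 mV, possibly shifted per neuron by
halorhodopsin); pathway-specific strengths enter through the size of the
arrival jump, tau_syn_all * g / (sqrt(K) * t_syn) per edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from numba import njit

from .circuit import CircuitSpec, HaloAssignment, assign_halorhodopsin, build_connectivity
from .drive import SpikeTrainSet, ThalamicDrive, sample_thalamic_spikes
from .neurons import find_resting_state

__all__ = [
    "SimulationProtocol",
    "SimulationResult",
    "run_simulation",
    "detect_spikes",
]

SPIKE_THRESHOLD = -20.0  # mV, upward crossing
REFRACTORY_MS = 2.0      # lockout between detected spikes
_BLOWUP_V = 200.0        # |V| beyond any reversal potential -> numerical failure


@dataclass(frozen=True)
class SimulationProtocol:
    """Integration and recording settings for one run."""

    duration: float = 6000.0     # total simulated time, ms
    dt: float = 0.05             # integration step, ms
    transient: float = 500.0     # initial interval discarded by analysis, ms
    seed: int = 0
    record_voltages: tuple = ()  # global neuron ids (E: 0..N_E-1, I: N_E..)
    round_delays: bool = False   # permit off-grid delays by rounding

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.transient < self.duration):
            raise ValueError("transient must lie within the run duration")


@dataclass
class SimulationResult:
    """Spike trains per population plus optional voltage traces."""

    spikes: Dict[str, SpikeTrainSet]   # keys "T", "E", "I"
    halo: HaloAssignment
    circuit: CircuitSpec
    drive: ThalamicDrive
    protocol: SimulationProtocol
    voltages: Dict[int, np.ndarray] = field(default_factory=dict)

    def split_inhibitory(self) -> tuple[SpikeTrainSet, SpikeTrainSet]:
        """I population split into (Hr+, Hr-) train sets."""
        trains = self.spikes["I"].trains
        hr = [t for t, flag in zip(trains, self.halo.is_hr) if flag]
        non = [t for t, flag in zip(trains, self.halo.is_hr) if not flag]
        dur = self.spikes["I"].duration
        return (
            SpikeTrainSet("I_hr+", hr, dur),
            SpikeTrainSet("I_hr-", non, dur),
        )


def detect_spikes(V_trace, dt: float, threshold: float = SPIKE_THRESHOLD) -> np.ndarray:
    """Spike times (ms) from a uniformly sampled voltage trace.

    A spike is an upward crossing of ``threshold`` (default -20 mV);
    crossings within 2 ms of the previous accepted spike are suppressed
    (refractory guard against noisy peaks).  The time assigned is that of
    the first sample at or above threshold.  Model spikes overshoot 0 mV,
    so counts are insensitive to the threshold over a wide range.
    """
    V = np.asarray(V_trace, dtype=float)
    above = V >= threshold
    crossing = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = []
    last = -np.inf
    for idx in crossing:
        t = idx * dt
        if t - last >= REFRACTORY_MS:
            times.append(t)
            last = t
    return np.asarray(times)


@njit(cache=True, fastmath=True)
def _deriv(V, h, n, z, G_a, G_g, V_rev_g, g_L, g_KZ, I_inj,
           C, g_Na, g_Kdr, V_L, V_Na, V_K, phi, tau_z):
    # gating rates; removable singularities handled by a series branch
    u = 0.1 * (V + 30.0)
    if abs(u) < 1e-6:
        a_m = 1.0 + 0.5 * u
    else:
        a_m = u / (1.0 - math.exp(-u))
    b_m = 4.0 * math.exp(-(V + 55.0) / 18.0)
    a_h = 0.7 * math.exp(-(V + 44.0) / 20.0)
    b_h = 10.0 / (1.0 + math.exp(-0.1 * (V + 14.0)))
    w = 0.1 * (V + 34.0)
    if abs(w) < 1e-6:
        a_n = 1.0 + 0.5 * w
    else:
        a_n = w / (1.0 - math.exp(-w))
    b_n = 1.25 * math.exp(-(V + 44.0) / 80.0)

    m_inf = a_m / (a_m + b_m)
    i_ion = (g_L * (V - V_L)
             + g_Na * m_inf * m_inf * m_inf * h * (V - V_Na)
             + (g_Kdr * n * n * n * n + g_KZ * z) * (V - V_K))
    i_syn = G_a * V + G_g * (V - V_rev_g)  # AMPA reversal is 0 mV
    dV = (-i_ion - i_syn + I_inj) / C
    dh = phi * (a_h * (1.0 - h) - b_h * h)
    dn = phi * (a_n * (1.0 - n) - b_n * n)
    z_inf = 1.0 / (1.0 + math.exp(-0.7 * (V + 30.0)))
    dz = (z_inf - z) / tau_z
    return dV, dh, dn, dz


@njit(cache=True, fastmath=True)
def _run_kernel(
    n_steps, dt, N_E, N,
    # per-neuron parameters / inputs
    g_L, g_KZ, I_inj, V_rev_g,
    # shared scalars
    C, g_Na, g_Kdr, V_L, V_Na, V_K, phi, tau_z,
    # state (modified in place)
    V, h, n, z, G_a, G_g,
    # conductance decay: per-step and per-substage factors
    dec_a, dec_g, sub_a, sub_g,
    # six pathway CSRs (pre -> postsynaptic targets), jump sizes, delays
    et_ptr, et_idx, et_jump, et_d,
    it_ptr, it_idx, it_jump, it_d,
    ee_ptr, ee_idx, ee_jump, ee_d,
    ie_ptr, ie_idx, ie_jump, ie_d,
    ei_ptr, ei_idx, ei_jump, ei_d,
    ii_ptr, ii_idx, ii_jump, ii_d,
    # thalamic spikes: CSR over steps (spike step -> thalamic neuron ids)
    th_ptr, th_idx,
    # ring buffer for cortical spikes
    ring, ring_count,
    # outputs
    spike_neuron, spike_step, rec_ids, V_rec, fail_info,
):
    horizon = ring.shape[0]
    refrac = int(round(REFRACTORY_MS / dt))
    last_spike = np.full(N, -refrac - 1, dtype=np.int64)
    n_out = 0
    cap = spike_neuron.shape[0]
    n_rec = rec_ids.shape[0]
    for r in range(n_rec):
        V_rec[r, 0] = V[rec_ids[r]]

    for k in range(n_steps):
        # --- deliver arrivals due at step k ---------------------------------
        # thalamic spikes from step k - d through ET / IT
        j = k - et_d
        if 0 <= j < n_steps:
            for q in range(th_ptr[j], th_ptr[j + 1]):
                pre = th_idx[q]
                for e in range(et_ptr[pre], et_ptr[pre + 1]):
                    G_a[et_idx[e]] += et_jump
        j = k - it_d
        if 0 <= j < n_steps:
            for q in range(th_ptr[j], th_ptr[j + 1]):
                pre = th_idx[q]
                for e in range(it_ptr[pre], it_ptr[pre + 1]):
                    G_a[it_idx[e]] += it_jump
        # cortical spikes read from the ring at their emission step
        j = k - ee_d
        if j >= 0:
            slot = j % horizon
            for q in range(ring_count[slot]):
                pre = ring[slot, q]
                if pre < N_E:
                    for e in range(ee_ptr[pre], ee_ptr[pre + 1]):
                        G_a[ee_idx[e]] += ee_jump
        j = k - ie_d
        if j >= 0:
            slot = j % horizon
            for q in range(ring_count[slot]):
                pre = ring[slot, q]
                if pre < N_E:
                    for e in range(ie_ptr[pre], ie_ptr[pre + 1]):
                        G_a[ie_idx[e]] += ie_jump
        j = k - ei_d
        if j >= 0:
            slot = j % horizon
            for q in range(ring_count[slot]):
                pre = ring[slot, q]
                if pre >= N_E:
                    for e in range(ei_ptr[pre - N_E], ei_ptr[pre - N_E + 1]):
                        G_g[ei_idx[e]] += ei_jump
        j = k - ii_d
        if j >= 0:
            slot = j % horizon
            for q in range(ring_count[slot]):
                pre = ring[slot, q]
                if pre >= N_E:
                    for e in range(ii_ptr[pre - N_E], ii_ptr[pre - N_E + 1]):
                        G_g[ii_idx[e]] += ii_jump

        # --- integrate step k -> k+1 ---------------------------------------
        new_slot = (k + 1) % horizon
        ring_count[new_slot] = 0
        for i in range(N):
            Vi = V[i]; hi = h[i]; ni = n[i]; zi = z[i]
            Ga = G_a[i]; Gg = G_g[i]
            Vg = V_rev_g[i]; gl = g_L[i]; gkz = g_KZ[i]; inj = I_inj[i]

            d1V, d1h, d1n, d1z = _deriv(
                Vi, hi, ni, zi, Ga * sub_a[0], Gg * sub_g[0], Vg, gl, gkz, inj,
                C, g_Na, g_Kdr, V_L, V_Na, V_K, phi, tau_z)
            d2V, d2h, d2n, d2z = _deriv(
                Vi + 0.5 * dt * d1V, hi + 0.5 * dt * d1h,
                ni + 0.5 * dt * d1n, zi + 0.5 * dt * d1z,
                Ga * sub_a[1], Gg * sub_g[1], Vg, gl, gkz, inj,
                C, g_Na, g_Kdr, V_L, V_Na, V_K, phi, tau_z)
            d3V, d3h, d3n, d3z = _deriv(
                Vi + 0.5 * dt * d2V, hi + 0.5 * dt * d2h,
                ni + 0.5 * dt * d2n, zi + 0.5 * dt * d2z,
                Ga * sub_a[2], Gg * sub_g[2], Vg, gl, gkz, inj,
                C, g_Na, g_Kdr, V_L, V_Na, V_K, phi, tau_z)
            d4V, d4h, d4n, d4z = _deriv(
                Vi + dt * d3V, hi + dt * d3h, ni + dt * d3n, zi + dt * d3z,
                Ga * sub_a[3], Gg * sub_g[3], Vg, gl, gkz, inj,
                C, g_Na, g_Kdr, V_L, V_Na, V_K, phi, tau_z)

            V_new = Vi + (dt / 6.0) * (d1V + 2.0 * d2V + 2.0 * d3V + d4V)
            # project gates back onto their invariant range [0, 1]: the exact
            # flow never leaves it, only truncation error during the stiff
            # spike upstroke does, and letting h escape above 1 feeds back
            # into the sodium current explosively
            h_new = hi + (dt / 6.0) * (d1h + 2.0 * d2h + 2.0 * d3h + d4h)
            n_new = ni + (dt / 6.0) * (d1n + 2.0 * d2n + 2.0 * d3n + d4n)
            z_new = zi + (dt / 6.0) * (d1z + 2.0 * d2z + 2.0 * d3z + d4z)
            h[i] = min(max(h_new, 0.0), 1.0)
            n[i] = min(max(n_new, 0.0), 1.0)
            z[i] = min(max(z_new, 0.0), 1.0)

            if not (-_BLOWUP_V < V_new < _BLOWUP_V):
                fail_info[0] = i; fail_info[1] = k
                fail_info[2] = Vi; fail_info[3] = hi
                fail_info[4] = ni; fail_info[5] = zi
                fail_info[6] = Ga; fail_info[7] = Gg
                return n_out, 1  # numerical blow-up

            # spike: upward crossing of threshold, assigned to step k+1
            if V_new >= SPIKE_THRESHOLD and Vi < SPIKE_THRESHOLD:
                if (k + 1) - last_spike[i] >= refrac:
                    last_spike[i] = k + 1
                    q = ring_count[new_slot]
                    ring[new_slot, q] = i
                    ring_count[new_slot] = q + 1
                    if n_out >= cap:
                        return n_out, 2  # spike capacity exhausted
                    spike_neuron[n_out] = i
                    spike_step[n_out] = k + 1
                    n_out += 1
            V[i] = V_new
            G_a[i] = Ga * dec_a
            G_g[i] = Gg * dec_g

        for r in range(n_rec):
            V_rec[r, k + 1] = V[rec_ids[r]]

    return n_out, 0


def _delay_steps(delay: float, dt: float, round_ok: bool) -> int:
    steps = delay / dt
    if abs(steps - round(steps)) > 1e-9:
        if not round_ok:
            raise ValueError(
                f"pathway delay {delay} ms is not a multiple of dt={dt} ms; "
                "set round_delays=True to round to the grid"
            )
        import warnings

        warnings.warn(f"rounding delay {delay} ms to the {dt} ms grid")
    return int(round(steps))


def _pre_to_post_csr(adj, jump_sign_check=None):
    """Convert a (post x pre) adjacency to pre-major CSR (indptr, post ids)."""
    csc = adj.tocsc()
    return csc.indptr.astype(np.int64), csc.indices.astype(np.int64)


def run_simulation(
    circuit: CircuitSpec,
    drive: ThalamicDrive,
    protocol: SimulationProtocol,
    thalamic_spikes: SpikeTrainSet | None = None,
) -> SimulationResult:
    """Integrate the full circuit and return spike trains for T, E and I.

    Randomness (connectivity, thalamic sampling, halorhodopsin draws) is
    derived from ``protocol.seed`` through independent spawned substreams,
    so a run is bit-reproducible from its configuration.  A pre-sampled
    thalamic :class:`SpikeTrainSet` may be supplied instead of sampling.
    """
    dt = protocol.dt
    n_steps = int(round(protocol.duration / dt))
    N_E, N_I, N_T = circuit.N_E, circuit.N_I, circuit.N_T
    N = N_E + N_I

    ss = np.random.SeedSequence(protocol.seed)
    conn_ss, drive_ss, halo_ss = ss.spawn(3)

    # connectivity (pre-major CSR) and arrival jump per pathway
    conn_seeds = conn_ss.spawn(6)
    sizes = {"T": N_T, "E": N_E, "I": N_I}
    csr = {}
    for (name, cseed) in zip(("ET", "IT", "EE", "IE", "EI", "II"), conn_seeds):
        pw = circuit.pathways[name]
        adj = build_connectivity(
            sizes[pw.pre], sizes[pw.post], pw.K,
            exclude_self=(pw.pre == pw.post), seed=cseed,
        )
        ptr, idx = _pre_to_post_csr(adj)
        if pw.post == "I":  # store global neuron ids
            idx = idx + N_E
        csr[name] = (ptr, idx, pw.conductance_jump,
                     _delay_steps(pw.tau_delay, dt, protocol.round_delays))

    # thalamic drive, gridded to spike steps
    if thalamic_spikes is None:
        thalamic_spikes = sample_thalamic_spikes(
            drive, N_T, protocol.duration, drive_ss, dt=dt
        )
    th_step_lists = [[] for _ in range(n_steps)]
    for neuron_id, train in enumerate(thalamic_spikes.trains):
        for t in train:
            step = int(round(t / dt))
            if 0 <= step < n_steps:
                th_step_lists[step].append(neuron_id)
    th_counts = np.array([len(s) for s in th_step_lists], dtype=np.int64)
    th_ptr = np.zeros(n_steps + 1, dtype=np.int64)
    np.cumsum(th_counts, out=th_ptr[1:])
    th_idx = np.array(
        [i for s in th_step_lists for i in s], dtype=np.int64
    ) if th_ptr[-1] else np.zeros(0, dtype=np.int64)

    # halorhodopsin
    halo = assign_halorhodopsin(N_I, circuit.halo, halo_ss)
    I_inj = np.zeros(N)
    V_rev_g = np.full(N, -85.0)
    if circuit.halo.light:
        I_inj[N_E:] = halo.I_halo  # zero for Hr- neurons
        V_rev_g[N_E:] += halo.dV_gaba

    # per-neuron intrinsic parameters (populations are internally homogeneous)
    pE, pI = circuit.params_E, circuit.params_I
    for a, b in (("C", "C"), ("g_Na", "g_Na"), ("g_Kdr", "g_Kdr"),
                 ("V_L", "V_L"), ("V_Na", "V_Na"), ("V_K", "V_K"),
                 ("phi_kin", "phi_kin"), ("tau_z", "tau_z")):
        if getattr(pE, a) != getattr(pI, b):
            raise ValueError(f"populations must share {a}")
    g_L = np.concatenate([np.full(N_E, pE.g_L), np.full(N_I, pI.g_L)])
    g_KZ = np.concatenate([np.full(N_E, pE.g_KZ), np.full(N_I, pI.g_KZ)])

    rest_E = find_resting_state(pE)
    rest_I = find_resting_state(pI)
    V = np.concatenate([np.full(N_E, rest_E.V), np.full(N_I, rest_I.V)])
    h = np.concatenate([np.full(N_E, rest_E.h), np.full(N_I, rest_I.h)])
    n_gate = np.concatenate([np.full(N_E, rest_E.n), np.full(N_I, rest_I.n)])
    z = np.concatenate([np.full(N_E, rest_E.z), np.full(N_I, rest_I.z)])
    G_a = np.zeros(N)
    G_g = np.zeros(N)

    t_ampa = circuit.pathways["EE"].t_syn
    t_gaba = circuit.pathways["EI"].t_syn
    dec_a = math.exp(-dt / t_ampa)
    dec_g = math.exp(-dt / t_gaba)
    stage_offsets = np.array([0.0, dt / 2.0, dt / 2.0, dt])
    sub_a = np.exp(-stage_offsets / t_ampa)
    sub_g = np.exp(-stage_offsets / t_gaba)

    max_delay = max(c[3] for c in csr.values())
    horizon = max(max_delay + 1, 2)
    ring = np.zeros((horizon, N), dtype=np.int64)
    ring_count = np.zeros(horizon, dtype=np.int64)

    cap = max(int(N * protocol.duration / 1000.0 * 600), 10_000)
    spike_neuron = np.zeros(cap, dtype=np.int64)
    spike_step = np.zeros(cap, dtype=np.int64)

    rec_ids = np.asarray(protocol.record_voltages, dtype=np.int64)
    V_rec = np.zeros((len(rec_ids), n_steps + 1))
    fail_info = np.zeros(8)

    n_out, status = _run_kernel(
        n_steps, dt, N_E, N,
        g_L, g_KZ, I_inj, V_rev_g,
        pE.C, pE.g_Na, pE.g_Kdr, pE.V_L, pE.V_Na, pE.V_K, pE.phi_kin, pE.tau_z,
        V, h, n_gate, z, G_a, G_g,
        dec_a, dec_g, sub_a, sub_g,
        *csr["ET"], *csr["IT"], *csr["EE"], *csr["IE"], *csr["EI"], *csr["II"],
        th_ptr, th_idx,
        ring, ring_count,
        spike_neuron, spike_step, rec_ids, V_rec, fail_info,
    )
    if status == 1:
        i, k = int(fail_info[0]), int(fail_info[1])
        err = RuntimeError(
            "numerical blow-up: non-finite or out-of-range membrane potential "
            f"(neuron {i} at t={k * dt:.2f} ms; "
            f"V={fail_info[2]:.2f}, h={fail_info[3]:.4f}, n={fail_info[4]:.4f}, "
            f"z={fail_info[5]:.4f}, G_ampa={fail_info[6]:.4f}, "
            f"G_gaba={fail_info[7]:.4f})"
        )
        err.voltages = {int(gid): V_rec[r] for r, gid in enumerate(rec_ids)}
        err.n_spikes = n_out
        raise err
    if status == 2:
        raise RuntimeError(
            "spike capacity exhausted (sustained runaway excitation); "
            "reduce duration or treat as runaway"
        )

    neuron = spike_neuron[:n_out]
    times = spike_step[:n_out] * dt
    order = np.argsort(neuron, kind="stable")  # times already ascending
    neuron_sorted = neuron[order]
    times_sorted = times[order]
    bounds = np.searchsorted(neuron_sorted, np.arange(N + 1))
    trains = [times_sorted[bounds[i]:bounds[i + 1]] for i in range(N)]
    trains_E = trains[:N_E]
    trains_I = trains[N_E:]
    spikes = {
        "T": thalamic_spikes,
        "E": SpikeTrainSet("E", trains_E, protocol.duration, protocol.seed),
        "I": SpikeTrainSet("I", trains_I, protocol.duration, protocol.seed),
    }
    voltages = {int(gid): V_rec[r] for r, gid in enumerate(rec_ids)}
    return SimulationResult(
        spikes=spikes, halo=halo, circuit=circuit, drive=drive,
        protocol=protocol, voltages=voltages,
    )
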