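"""Three-population L4 circuit: connectivity, synapses, optogenetics.

The circuit has N_E excitatory (E) and N_I fast-spiking inhibitory (I)
cortical neurons driven by N_T thalamic (T) relay neurons through six
synaptic pathways, named post-pre: ET, IT, EE, IE (AMPA) and EI, II
(GABA_A).  Each admissible edge of a pathway with mean in-degree K is
present independently with probability K/N_pre.

Synaptic gates follow single-exponential kinetics: a presynaptic spike,
after the pathway delay, adds 1/t_syn to the presynaptic gate s, which
then decays with time constant t_syn.  The total conductance a neuron
receives through a pathway is

    G = tau_syn_all * (g / sqrt(K)) * sum_j C_ij * s_j ,

i.e. conductances are scaled with the square root of the in-degree, the
balanced-network convention.  This scaling is a calibration fact, not a
notational choice: with it the six single-connection PSP amplitudes of the
reference pathways reproduce the target values (ET +1.1 mV ... II -1.28
mV), which a 1/K scaling misses by ~7x (see docs/methods.md).

Halorhodopsin activation is modeled in a fraction f_halo of the I
neurons as (i) a constant hyperpolarizing current drawn uniformly from
[-3, -1] uA/cm^2 and (ii) a depolarizing shift of the GABA_A reversal
potential proportional to that current.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np
import scipy.sparse as sp

from .neurons import NeuronParameters, NeuronState, find_resting_state, ionic_current, \
    gating_rate_functions, steady_state_gates

__all__ = [
    "SynapticPathway",
    "HalorhodopsinConfig",
    "HaloAssignment",
    "CircuitSpec",
    "build_connectivity",
    "decay_and_jump",
    "total_conductance",
    "assign_halorhodopsin",
    "measure_unitary_psp",
    "reference_pathways",
    "reference_circuit",
]

TAU_SYN_ALL = 1.0  # normalization constant, ms

RECEPTOR_PARAMS = {
    # receptor -> (decay time t_syn in ms, reversal potential in mV)
    "AMPA": (2.0, 0.0),
    "GABA_A": (3.0, -85.0),
}


@dataclass(frozen=True)
class SynapticPathway:
    """Parameters of one post<-pre pathway."""

    pre: str                # presynaptic population: T | E | I
    post: str               # postsynaptic population: E | I
    receptor: str           # AMPA | GABA_A
    tau_delay: float        # transmission delay, ms
    K: float                # mean number of presynaptic inputs
    g: float                # conductance scale, mS/cm^2

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTOR_PARAMS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.tau_delay < 0:
            raise ValueError("tau_delay must be non-negative")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.g < 0:
            raise ValueError("g must be non-negative")

    @property
    def name(self) -> str:
        return self.post + self.pre

    @property
    def t_syn(self) -> float:
        return RECEPTOR_PARAMS[self.receptor][0]

    @property
    def V_rev(self) -> float:
        return RECEPTOR_PARAMS[self.receptor][1]

    @property
    def conductance_scale(self) -> float:
        """Prefactor tau_syn_all * g / sqrt(K) applied to the summed gates."""
        if self.K == 0:
            return 0.0
        return TAU_SYN_ALL * self.g / np.sqrt(self.K)

    @property
    def conductance_jump(self) -> float:
        """Increment of G (mS/cm^2) when one spike arrives through one edge."""
        return self.conductance_scale / self.t_syn


def reference_pathways() -> Dict[str, SynapticPathway]:
    """The six reference pathways (delay ms, in-degree K, strength mS/cm^2)."""
    rows = [
        ("E", "T", "AMPA", 1.0, 50, 0.15),
        ("I", "T", "AMPA", 1.0, 75, 0.2),
        ("E", "E", "AMPA", 1.0, 200, 0.2),
        ("I", "E", "AMPA", 1.0, 400, 0.6),
        ("E", "I", "GABA_A", 0.85, 25, 0.7),
        ("I", "I", "GABA_A", 0.5, 25, 0.55),
    ]
    return {
        post + pre: SynapticPathway(pre, post, rec, d, K, g)
        for post, pre, rec, d, K, g in rows
    }


# Target single-connection PSP amplitudes (mV) used to calibrate the
# conductance scaling; positive = EPSP, negative = IPSP.
REFERENCE_PSP_MV = {
    "ET": 1.1, "IT": 1.03, "EE": 0.73, "IE": 1.33, "EI": -1.92, "II": -1.28,
}


@dataclass(frozen=True)
class HalorhodopsinConfig:
    """Optogenetic perturbation of the I population."""

    f_halo: float = 0.0        # fraction of I neurons expressing
    I_halo0: float = -2.0      # mean pump current, uA/cm^2
    I_halo1: float = 1.0       # half-range of the expression spread, uA/cm^2
    beta_halo: float = -4.0    # GABA_A reversal shift per unit current, mV cm^2/uA
    light: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_halo <= 1.0):
            raise ValueError("f_halo must lie in [0, 1]")


@dataclass
class HaloAssignment:
    """Per-I-neuron expression flags and light-on effects."""

    is_hr: np.ndarray       # bool, Hr+ membership
    I_halo: np.ndarray      # uA/cm^2; 0 for Hr- neurons
    dV_gaba: np.ndarray     # depolarizing GABA_A reversal shift, mV; 0 for Hr-


def assign_halorhodopsin(N_I: int, config: HalorhodopsinConfig, seed) -> HaloAssignment:
    """Draw Hr+ membership and per-neuron pump currents.

    round(f_halo * N_I) neurons are flagged Hr+ (the first indices of a
    seeded shuffle, for reproducibility); each receives a current
    ``I_halo0 + I_halo1 * x`` with x ~ U[-1, 1] and a reversal shift
    ``beta_halo * I_halo`` applied to GABA_A synapses it receives.
    The returned currents/shifts describe the light-on effect; whether they
    are applied is decided by ``config.light`` at simulation time.
    """
    rng = np.random.default_rng(seed)
    n_hr = int(round(config.f_halo * N_I))
    order = rng.permutation(N_I)
    is_hr = np.zeros(N_I, dtype=bool)
    is_hr[order[:n_hr]] = True
    x = rng.uniform(-1.0, 1.0, N_I)
    I_halo = np.where(is_hr, config.I_halo0 + config.I_halo1 * x, 0.0)
    dV_gaba = config.beta_halo * I_halo
    return HaloAssignment(is_hr=is_hr, I_halo=I_halo, dV_gaba=dV_gaba)


@dataclass
class CircuitSpec:
    """Complete circuit description: sizes, pathways, cell types, optogenetics."""

    N_E: int = 1600
    N_I: int = 150
    N_T: int = 200
    pathways: Dict[str, SynapticPathway] = field(default_factory=reference_pathways)
    params_E: NeuronParameters = field(default_factory=NeuronParameters.excitatory)
    params_I: NeuronParameters = field(default_factory=NeuronParameters.inhibitory)
    halo: HalorhodopsinConfig = field(default_factory=HalorhodopsinConfig)

    def __post_init__(self) -> None:
        if min(self.N_E, self.N_I, self.N_T) <= 0:
            raise ValueError("population sizes must be positive")
        if set(self.pathways) != {"ET", "IT", "EE", "IE", "EI", "II"}:
            raise ValueError("exactly the six pathways ET,IT,EE,IE,EI,II required")
        sizes = {"T": self.N_T, "E": self.N_E, "I": self.N_I}
        for pw in self.pathways.values():
            if pw.K > sizes[pw.pre]:
                raise ValueError(f"{pw.name}: K={pw.K} exceeds N_pre={sizes[pw.pre]}")

    def with_pathway(self, name: str, **changes) -> "CircuitSpec":
        """Copy of the circuit with one pathway's parameters replaced."""
        pathways = dict(self.pathways)
        pathways[name] = replace(pathways[name], **changes)
        return replace(self, pathways=pathways)

    def n_pre(self, pathway: SynapticPathway) -> int:
        return {"T": self.N_T, "E": self.N_E, "I": self.N_I}[pathway.pre]

    def n_post(self, pathway: SynapticPathway) -> int:
        return {"E": self.N_E, "I": self.N_I}[pathway.post]


def reference_circuit(**overrides) -> CircuitSpec:
    """The reference parameter set as a ready-to-use CircuitSpec."""
    return CircuitSpec(**overrides)


def build_connectivity(
    N_pre: int, N_post: int, K: float, exclude_self: bool = False, seed=None
) -> sp.csr_matrix:
    """Sample a binary adjacency (post x pre) with edge probability K/N_pre.

    Each admissible edge is an independent Bernoulli draw, so the in-degree
    is binomial with mean K.  ``exclude_self`` removes the diagonal
    (within-population pathways have no autapses).
    """
    if not (0 <= K <= N_pre):
        raise ValueError("K must lie in [0, N_pre]")
    rng = np.random.default_rng(seed)
    p = K / N_pre
    dense = rng.random((N_post, N_pre)) < p
    if exclude_self:
        np.fill_diagonal(dense, False)
    return sp.csr_matrix(dense)


def connectivity_edge_list(adjacencies: Dict[str, sp.spmatrix]):
    """Flatten per-pathway adjacencies into a tidy (pathway, post, pre) table."""
    import pandas as pd

    rows = []
    for name, adj in adjacencies.items():
        post, pre = adj.nonzero()
        rows.append(pd.DataFrame({"pathway": name, "post_id": post, "pre_id": pre}))
    return pd.concat(rows, ignore_index=True)


def decay_and_jump(s, elapsed: float, arrivals: int, t_syn: float):
    """Advance a synaptic gate: exponential decay over ``elapsed`` ms, then
    an instantaneous increment of ``arrivals/t_syn`` (1/ms per spike).

    This update exactly reproduces the sum-of-decaying-exponentials gate for
    any spike sequence, because exponentials with a common time constant are
    closed under superposition.
    """
    if elapsed < 0:
        raise ValueError("elapsed must be non-negative")
    s = np.asarray(s, dtype=float)
    out = s * np.exp(-elapsed / t_syn) + arrivals / t_syn
    return out if out.ndim else float(out)


def total_conductance(pathway: SynapticPathway, s, C_row):
    """Total pathway conductance G = tau_syn_all*(g/sqrt(K)) * sum_j C_ij s_j."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("gate values must be non-negative")
    C_row = np.asarray(C_row, dtype=float)
    return float(pathway.conductance_scale * (C_row @ s))


def passive_psp_peak(pathway: SynapticPathway, post_params: NeuronParameters) -> float:
    """Closed-form unitary PSP peak for a leak-only membrane (oracle).

    For a single-exponential conductance transient dG*exp(-t/t_syn) on a
    passive membrane with time constant tau_m = C/g_L, linearizing the
    driving force around rest gives a double-exponential PSP whose extremum
    is at t* = ln(tau_m/t_syn) * tau_m*t_syn/(tau_m - t_syn).
    """
    tau_m = post_params.C / post_params.g_L
    t_syn = pathway.t_syn
    V_rest = post_params.V_L
    dG = pathway.conductance_jump
    t_star = np.log(tau_m / t_syn) * tau_m * t_syn / (tau_m - t_syn)
    amp = dG * (pathway.V_rev - V_rest) * t_syn / (post_params.C * (1.0 - t_syn / tau_m))
    return float(amp * (np.exp(-t_star / tau_m) - np.exp(-t_star / t_syn)))


def _rk4_single_neuron(
    params: NeuronParameters,
    state: NeuronState,
    dt: float,
    n_steps: int,
    G0: float,
    V_rev: float,
    t_syn: float,
    jump_step: int,
    I_inj: float = 0.0,
) -> np.ndarray:
    """Fixed-step RK4 of one neuron with a piecewise-exponential conductance.

    The conductance is G0 from ``jump_step`` on, decaying with t_syn; within
    each step the RK4 substages see the analytically decayed conductance
    (the gate ODE is exactly solvable, so it is not folded into the stages).
    Returns the voltage trace sampled at step boundaries (length n_steps+1).
    """
    V, h, n, z = state.V, state.h, state.n, state.z
    dec = np.exp(-np.array([0.0, dt / 2.0, dt / 2.0, dt]) / t_syn)
    trace = np.empty(n_steps + 1)
    trace[0] = V
    G = 0.0

    def deriv(V, h, n, z, G_sub):
        a_m, b_m, a_h, b_h, a_n, b_n = gating_rate_functions(V)
        i_ion = ionic_current(V, h, n, z, params)
        dV = (-i_ion - G_sub * (V - V_rev) + I_inj) / params.C
        dh = params.phi_kin * (a_h * (1 - h) - b_h * h)
        dn = params.phi_kin * (a_n * (1 - n) - b_n * n)
        z_inf = 1.0 / (1.0 + np.exp(-0.7 * (V + 30.0)))
        dz = (z_inf - z) / params.tau_z
        return np.array([dV, dh, dn, dz])

    y = np.array([V, h, n, z])
    step_decay = np.exp(-dt / t_syn)
    for k in range(n_steps):
        if k == jump_step:
            G += G0
        k1 = deriv(*y, G * dec[0])
        k2 = deriv(*(y + 0.5 * dt * k1), G * dec[1])
        k3 = deriv(*(y + 0.5 * dt * k2), G * dec[2])
        k4 = deriv(*(y + dt * k3), G * dec[3])
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y[1:] = np.clip(y[1:], 0.0, 1.0)  # gates stay in their invariant range
        G *= step_decay
        trace[k + 1] = y[0]
    return trace


def measure_unitary_psp(
    pathway: SynapticPathway,
    post_params: NeuronParameters,
    dt: float = 0.05,
    t_max: float = 50.0,
) -> float:
    """Extremal membrane-potential deflection (mV) from one presynaptic spike.

    A single postsynaptic neuron is initialized at rest; one spike travels
    through one connection of the pathway (gate jump 1/t_syn scaled by
    tau_syn_all*g/sqrt(K)), and the neuron is integrated for ``t_max`` ms.
    Returns the signed extremal deviation of V from rest: positive for an
    EPSP, negative for an IPSP.  Raises if the neuron spikes, in which case
    a unitary PSP is undefined.
    """
    rest = find_resting_state(post_params)
    n_steps = int(round(t_max / dt))
    jump_step = int(round(pathway.tau_delay / dt))
    trace = _rk4_single_neuron(
        post_params, rest, dt, n_steps,
        G0=pathway.conductance_jump,
        V_rev=pathway.V_rev, t_syn=pathway.t_syn, jump_step=jump_step,
    )
    if np.max(trace) > -20.0:
        raise RuntimeError("postsynaptic neuron spiked; unitary PSP undefined")
    dV = trace - rest.V
    return float(dV[np.argmax(np.abs(dV))])
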