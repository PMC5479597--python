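"""Single-compartment modified Wang-Buzsaki neuron.

The model neuron carries a transient sodium current with instantaneous
activation (``I_Na = g_Na * m_inf(V)**3 * h * (V - V_Na)``), a delayed
rectifier (``I_Kdr = g_Kdr * n**4 * (V - V_K)``), a slow potassium
adaptation current (``I_KZ = g_KZ * z * (V - V_K)``, present only in
excitatory cells) and a leak.  Units throughout the package are mV, ms,
mS/cm^2, uA/cm^2 and uF/cm^2, so with C = 1 uF/cm^2 the membrane equation
``C dV/dt = -I_ion - I_syn + I_inj`` makes dV/dt numerically equal to the
total current density.

Gating kinetics for h and n are scaled by a dimensionless rate factor
``phi_kin`` (0.2 in the reference cells, producing comparatively wide
spikes); the adaptation gate z relaxes to ``z_inf(V)`` with an unscaled
time constant ``tau_z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NeuronParameters",
    "NeuronState",
    "gating_rate_functions",
    "steady_state_gates",
    "membrane_derivative",
    "find_resting_state",
]

# Width of the series branch around the removable singularities of alpha_m
# (V = -30 mV) and alpha_n (V = -34 mV).
_SINGULARITY_EPS = 1e-6


@dataclass(frozen=True)
class NeuronParameters:
    """Biophysical constants of one model neuron.

    Defaults are the shared values; use :meth:`excitatory` /
    :meth:`inhibitory` for the two reference cell types, which differ only
    in leak conductance and the presence of the adaptation current.
    """

    C: float = 1.0          # membrane capacitance, uF/cm^2
    g_L: float = 0.05       # leak conductance, mS/cm^2
    g_Na: float = 100.0     # sodium conductance, mS/cm^2
    g_Kdr: float = 40.0     # delayed-rectifier conductance, mS/cm^2
    g_KZ: float = 0.5       # adaptation conductance, mS/cm^2
    V_L: float = -65.0      # leak reversal, mV
    V_Na: float = 55.0      # sodium reversal, mV
    V_K: float = -90.0      # potassium reversal, mV
    tau_z: float = 60.0     # adaptation time constant, ms
    phi_kin: float = 0.2    # gating rate scale for h and n

    def __post_init__(self) -> None:
        for name in ("C", "g_L", "g_Na", "g_Kdr", "g_KZ"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_z <= 0:
            raise ValueError("tau_z must be positive")
        if self.phi_kin <= 0:
            raise ValueError("phi_kin must be positive")

    @classmethod
    def excitatory(cls) -> "NeuronParameters":
        """Reference excitatory (regular-spiking, adapting) cell."""
        return cls(g_L=0.05, g_KZ=0.5)

    @classmethod
    def inhibitory(cls) -> "NeuronParameters":
        """Reference fast-spiking interneuron: higher leak, no adaptation."""
        return cls(g_L=0.1, g_KZ=0.0)

    def passive(self) -> "NeuronParameters":
        """Leak-only variant (active conductances removed)."""
        return replace(self, g_Na=0.0, g_Kdr=0.0, g_KZ=0.0)


@dataclass
class NeuronState:
    """Dynamic variables of one neuron: V (mV) and gates h, n, z in [0,1].

    Sodium activation m is not a state variable; it is slaved to the
    membrane potential as ``m = m_inf(V)``.
    """

    V: float
    h: float
    n: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.n, self.z])


def _expm1_ratio(x):
    """x / (1 - exp(-x)) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SINGULARITY_EPS
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 + x / 2.0, safe / (-np.expm1(-safe)))
    return out


def gating_rate_functions(V):
    """Voltage-dependent transition rates (1/ms) of the m, h, n gates.

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)``.
    The removable singularities of alpha_m at V = -30 mV and alpha_n at
    V = -34 mV are evaluated by their analytic limits.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    alpha_m = 0.1 * 10.0 * _expm1_ratio(0.1 * (V + 30.0))
    beta_m = 4.0 * np.exp(-(V + 55.0) / 18.0)
    alpha_h = 0.7 * np.exp(-(V + 44.0) / 20.0)
    beta_h = 10.0 / (1.0 + np.exp(-0.1 * (V + 14.0)))
    alpha_n = 0.1 * 10.0 * _expm1_ratio(0.1 * (V + 34.0))
    beta_n = 1.25 * np.exp(-(V + 44.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def steady_state_gates(V):
    """Steady-state gate values ``(m_inf, h_inf, n_inf, z_inf)`` at V."""
    a_m, b_m, a_h, b_h, a_n, b_n = gating_rate_functions(V)
    V = np.asarray(V, dtype=float)
    m_inf = a_m / (a_m + b_m)
    h_inf = a_h / (a_h + b_h)
    n_inf = a_n / (a_n + b_n)
    z_inf = 1.0 / (1.0 + np.exp(-0.7 * (V + 30.0)))
    return m_inf, h_inf, n_inf, z_inf


def ionic_current(V, h, n, z, p: NeuronParameters):
    """Total intrinsic current (leak + Na + Kdr + KZ), uA/cm^2, at gates h,n,z."""
    m_inf = steady_state_gates(V)[0]
    i_L = p.g_L * (V - p.V_L)
    i_Na = p.g_Na * m_inf**3 * h * (V - p.V_Na)
    i_Kdr = p.g_Kdr * n**4 * (V - p.V_K)
    i_KZ = p.g_KZ * z * (V - p.V_K)
    return i_L + i_Na + i_Kdr + i_KZ


def membrane_derivative(
    state: NeuronState,
    params: NeuronParameters,
    G_syn=(),
    I_inj: float = 0.0,
) -> NeuronState:
    """Time derivative of the neuron state.

    Parameters
    ----------
    G_syn
        Iterable of ``(G, V_rev)`` pairs: per-receptor synaptic conductance
        (mS/cm^2) and its reversal potential (mV).
    I_inj
        Injected current density (uA/cm^2); positive depolarizes.
    """
    V, h, n, z = state.V, state.h, state.n, state.z
    a_m, b_m, a_h, b_h, a_n, b_n = gating_rate_functions(V)
    i_syn = 0.0
    for G, V_rev in G_syn:
        if G < 0:
            raise ValueError("synaptic conductance must be non-negative")
        i_syn += G * (V - V_rev)
    dV = (-ionic_current(V, h, n, z, params) - i_syn + I_inj) / params.C
    dh = params.phi_kin * (a_h * (1.0 - h) - b_h * h)
    dn = params.phi_kin * (a_n * (1.0 - n) - b_n * n)
    z_inf = 1.0 / (1.0 + np.exp(-0.7 * (V + 30.0)))
    dz = (z_inf - z) / params.tau_z
    return NeuronState(V=float(dV), h=float(dh), n=float(dn), z=float(dz))


def find_resting_state(params: NeuronParameters, tol: float = 1e-12) -> NeuronState:
    """Resting state of an isolated neuron (no synaptic input, no injection).

    Eliminates the gates by setting them to their steady-state values and
    root-finds the V-nullcline ``I_total(V, h_inf(V), n_inf(V), z_inf(V)) = 0``
    on [-90, -40] mV.  Raises if no zero crossing exists in that bracket,
    which signals pathological parameters.
    """

    def residual(V: float) -> float:
        _, h_inf, n_inf, z_inf = steady_state_gates(V)
        return float(ionic_current(V, h_inf, n_inf, z_inf, params))

    # The nullcline can cross zero more than once in the bracket (the upper
    # crossing is the spike threshold); the resting state is the first
    # crossing coming up from hyperpolarized potentials.
    grid = np.arange(-90.0, -40.0 + 1e-9, 0.5)
    res = np.array([residual(v) for v in grid])
    sign_change = np.flatnonzero(np.sign(res[:-1]) * np.sign(res[1:]) <= 0)
    if len(sign_change) == 0:
        raise ValueError("no resting potential in [-90, -40] mV")
    i = sign_change[0]
    V_rest = brentq(residual, grid[i], grid[i + 1], xtol=tol)
    _, h_inf, n_inf, z_inf = steady_state_gates(V_rest)
    return NeuronState(V=float(V_rest), h=float(h_inf), n=float(n_inf), z=float(z_inf))
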