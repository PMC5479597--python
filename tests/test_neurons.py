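"""Single-neuron dynamics: gating kinetics, currents, resting state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barrelsim.neurons import (
    NeuronParameters,
    NeuronState,
    find_resting_state,
    gating_rate_functions,
    ionic_current,
    membrane_derivative,
    steady_state_gates,
)
from barrelsim.circuit import _rk4_single_neuron
from barrelsim.engine import detect_spikes


@pytest.mark.parametrize(
    "V, index, expected",
    [
        (-30.0, 0, 1.0),   # alpha_m at its removable singularity (limit)
        (-55.0, 1, 4.0),   # beta_m where its exponent vanishes
        (-44.0, 2, 0.7),   # alpha_h where its exponent vanishes
        (-14.0, 3, 5.0),   # beta_h at its half-activation voltage
        (-34.0, 4, 1.0),   # alpha_n at its removable singularity (limit)
        (-44.0, 5, 1.25),  # beta_n where its exponent vanishes
    ],
)
def test_gating_rates_at_landmark_voltages(V, index, expected):
    rates = gating_rate_functions(V)
    assert rates[index] == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("V0", [-30.0, -34.0])
def test_removable_singularities_are_continuous(V0):
    near = [V0 - 1e-7, V0, V0 + 1e-7]
    vals = np.array([gating_rate_functions(v) for v in near])
    assert np.all(np.isfinite(vals))
    assert np.allclose(vals[0], vals[1], rtol=1e-6)
    assert np.allclose(vals[2], vals[1], rtol=1e-6)


def test_gating_rates_reject_non_finite_voltage():
    with pytest.raises(ValueError):
        gating_rate_functions(np.nan)


def test_steady_state_gates():
    m_inf, h_inf, n_inf, z_inf = steady_state_gates(-30.0)
    assert z_inf == pytest.approx(0.5, abs=1e-15)
    # alpha_m = 1, beta_m = 4 exp(-25/18)
    assert m_inf == pytest.approx(1.0 / (1.0 + 4.0 * np.exp(-25.0 / 18.0)), rel=1e-12)
    assert m_inf == pytest.approx(0.50065, abs=5e-5)
    # depolarized limits: m activates, h inactivates
    m_hi, h_hi, _, _ = steady_state_gates(100.0)
    assert m_hi > 0.999 and h_hi < 1e-3


@settings(derandomize=True, max_examples=60)
@given(st.floats(min_value=-120.0, max_value=60.0))
def test_rates_positive_and_gates_bounded(V):
    rates = gating_rate_functions(V)
    assert all(np.isfinite(r) and r >= 0 for r in rates)
    for x in steady_state_gates(V):
        assert 0.0 <= x <= 1.0


def test_membrane_derivative_leak_equilibrium():
    p = NeuronParameters.excitatory()
    s = NeuronState(V=p.V_L, h=0.0, n=0.0, z=0.0)
    d = membrane_derivative(s, p)
    assert d.V == pytest.approx(0.0, abs=1e-12)


def test_membrane_derivative_gate_fixed_points():
    p = NeuronParameters.excitatory()
    V = -48.3
    _, h_inf, n_inf, z_inf = steady_state_gates(V)
    d = membrane_derivative(NeuronState(V, h_inf, n_inf, z_inf), p)
    assert d.h == pytest.approx(0.0, abs=1e-12)
    assert d.n == pytest.approx(0.0, abs=1e-12)
    assert d.z == pytest.approx(0.0, abs=1e-12)


def test_phi_scales_h_n_kinetics_only():
    from dataclasses import replace

    p = NeuronParameters.excitatory()
    p2 = replace(p, phi_kin=2 * p.phi_kin)
    s = NeuronState(V=-50.0, h=0.3, n=0.4, z=0.1)
    d1 = membrane_derivative(s, p)
    d2 = membrane_derivative(s, p2)
    assert d2.h == pytest.approx(2 * d1.h, rel=1e-12)
    assert d2.n == pytest.approx(2 * d1.n, rel=1e-12)
    assert d2.V == pytest.approx(d1.V, rel=1e-12)
    assert d2.z == pytest.approx(d1.z, rel=1e-12)


def test_membrane_derivative_rejects_negative_conductance():
    p = NeuronParameters.excitatory()
    with pytest.raises(ValueError):
        membrane_derivative(NeuronState(-65, 0.5, 0.1, 0.0), p, G_syn=[(-0.1, 0.0)])


def test_resting_state_passive_is_leak_reversal():
    p = NeuronParameters.excitatory().passive()
    rest = find_resting_state(p)
    assert rest.V == pytest.approx(-65.0, abs=1e-9)


@pytest.mark.parametrize(
    "params, V_expected",
    [
        (NeuronParameters.excitatory(), -65.0786),  # regression (root finder)
        (NeuronParameters.inhibitory(), -65.0395),
    ],
)
def test_resting_state_reference_cells(params, V_expected):
    rest = find_resting_state(params)
    assert -66.0 < rest.V < -62.0
    assert rest.V == pytest.approx(V_expected, abs=1e-3)
    # by contract: all derivatives vanish at the returned state
    d = membrane_derivative(rest, params)
    assert abs(d.V) < 1e-9 and abs(d.h) < 1e-9
    assert abs(d.n) < 1e-9 and abs(d.z) < 1e-9


@pytest.mark.parametrize(
    "params", [NeuronParameters.excitatory(), NeuronParameters.inhibitory()]
)
def test_trajectories_converge_to_rest(params):
    """Without input, a perturbed neuron relaxes back to the resting state."""
    rest = find_resting_state(params)
    kicked = NeuronState(rest.V + 10.0, rest.h, rest.n, rest.z)
    trace = _rk4_single_neuron(
        params, kicked, dt=0.05, n_steps=8000,
        G0=0.0, V_rev=0.0, t_syn=2.0, jump_step=-1,
    )
    assert abs(trace[-1] - rest.V) < 0.01


def test_adaptation_current_slows_excitatory_firing():
    """Constant drive: E cells adapt over ~tau_z; I cells (g_KZ=0) do not."""
    dt, n_steps = 0.05, 12000  # 600 ms
    pE, pI = NeuronParameters.excitatory(), NeuronParameters.inhibitory()
    isis = {}
    for label, p, I in (("E", pE, 2.0), ("I", pI, 2.0)):
        trace = _rk4_single_neuron(
            p, find_resting_state(p), dt, n_steps,
            G0=0.0, V_rev=0.0, t_syn=2.0, jump_step=-1, I_inj=I,
        )
        t = detect_spikes(trace, dt)
        assert len(t) > 6
        isis[label] = np.diff(t)
    # E: interspike intervals lengthen as z builds up
    assert isis["E"][-1] > 1.15 * isis["E"][0]
    # I: steady firing, no systematic slowdown
    assert abs(isis["I"][-1] - isis["I"][0]) < 0.05 * isis["I"][0]


def test_gates_remain_bounded_along_unclamped_trajectory():
    """The exact flow keeps h, n, z in [0,1]; check with a fine-step RK4."""
    p = NeuronParameters.inhibitory()
    rest = find_resting_state(p)
    y = rest.as_array()
    dt = 0.01
    lo = np.inf
    hi = -np.inf
    for _ in range(10000):  # 100 ms of sustained spiking
        def deriv(arr):
            d = membrane_derivative(NeuronState(*arr), p, I_inj=3.0)
            return np.array([d.V, d.h, d.n, d.z])

        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        lo = min(lo, y[1:].min())
        hi = max(hi, y[1:].max())
    assert lo >= -1e-6 and hi <= 1.0 + 1e-6
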