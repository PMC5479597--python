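"""Circuit construction: connectivity, synaptic gates, optogenetics, PSPs."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barrelsim.circuit import (
    HalorhodopsinConfig,
    SynapticPathway,
    assign_halorhodopsin,
    build_connectivity,
    decay_and_jump,
    measure_unitary_psp,
    passive_psp_peak,
    reference_pathways,
    total_conductance,
    REFERENCE_PSP_MV,
)
from barrelsim.neurons import NeuronParameters


# ---------------------------------------------------------------- connectivity

def test_connectivity_full_and_empty():
    full = build_connectivity(10, 5, K=10, seed=0)
    assert full.toarray().all()
    empty = build_connectivity(10, 5, K=0, seed=0)
    assert empty.nnz == 0


def test_connectivity_rejects_excess_indegree():
    with pytest.raises(ValueError):
        build_connectivity(10, 5, K=11)


def test_connectivity_indegree_statistics():
    # binomial sampling: population mean in-degree within 3 sigma of K
    N_pre, N_post, K = 200, 1600, 50
    adj = build_connectivity(N_pre, N_post, K, seed=42)
    indeg = np.asarray(adj.sum(axis=1)).ravel()
    sem = np.sqrt(K * (1 - K / N_pre) / N_post)
    assert abs(indeg.mean() - K) < 3 * sem


def test_connectivity_edge_list_round_trip():
    from barrelsim.circuit import connectivity_edge_list

    adj = build_connectivity(20, 30, K=5, seed=1)
    table = connectivity_edge_list({"ET": adj})
    assert len(table) == adj.nnz
    rebuilt = np.zeros((30, 20), dtype=bool)
    rebuilt[table["post_id"], table["pre_id"]] = True
    assert np.array_equal(rebuilt, adj.toarray())


def test_connectivity_excludes_autapses_and_is_reproducible():
    a = build_connectivity(50, 50, K=20, exclude_self=True, seed=7)
    assert a.diagonal().sum() == 0
    b = build_connectivity(50, 50, K=20, exclude_self=True, seed=7)
    assert (a != b).nnz == 0
    c = build_connectivity(50, 50, K=20, exclude_self=True, seed=8)
    assert (a != c).nnz > 0


# ------------------------------------------------------------- synaptic gates

def test_gate_jump_and_decay_basics():
    # one arrival from empty gate: jump of 1/t_syn
    assert decay_and_jump(0.0, 0.0, 1, t_syn=2.0) == pytest.approx(0.5)
    # pure decay over one time constant
    assert decay_and_jump(1.2, 3.0, 0, t_syn=3.0) == pytest.approx(1.2 / np.e)
    # simultaneous arrivals superpose linearly
    assert decay_and_jump(0.0, 0.0, 2, t_syn=2.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        decay_and_jump(0.1, -1.0, 0, t_syn=2.0)


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(min_value=0.01, max_value=5.0), min_size=1, max_size=12))
def test_gate_update_matches_sum_of_exponentials(gaps):
    """Iterated decay-and-jump equals the closed-form sum over spikes."""
    t_syn = 2.0
    arrival_times = np.cumsum(gaps)
    t_eval = arrival_times[-1] + 1.7
    s = 0.0
    t_prev = 0.0
    for t_arr in arrival_times:
        s = decay_and_jump(s, t_arr - t_prev, 1, t_syn)
        t_prev = t_arr
    s = decay_and_jump(s, t_eval - t_prev, 0, t_syn)
    closed = np.sum(np.exp(-(t_eval - arrival_times) / t_syn)) / t_syn
    assert s == pytest.approx(closed, rel=1e-12)


def test_total_conductance_scaling_and_linearity():
    pw = reference_pathways()["ET"]
    s = np.zeros(10)
    C = np.ones(10)
    assert total_conductance(pw, s, C) == 0.0
    # single active connection at its moment of arrival: G = g/(sqrt(K) t_syn)
    s[3] = 1.0 / pw.t_syn
    G1 = total_conductance(pw, s, C)
    assert G1 == pytest.approx(0.15 / (np.sqrt(50) * 2.0), rel=1e-12)
    assert G1 == pytest.approx(0.0106, abs=2e-4)
    pw2 = replace(pw, g=2 * pw.g)
    assert total_conductance(pw2, s, C) == pytest.approx(2 * G1, rel=1e-12)
    with pytest.raises(ValueError):
        total_conductance(pw, -s, C)


# -------------------------------------------------------------- halorhodopsin

def test_halo_assignment_counts_and_ranges():
    cfg = HalorhodopsinConfig(f_halo=0.5)
    halo = assign_halorhodopsin(150, cfg, seed=3)
    assert halo.is_hr.sum() == 75
    hr_currents = halo.I_halo[halo.is_hr]
    assert np.all((hr_currents >= -3.0) & (hr_currents <= -1.0))
    # reversal shift is depolarizing and proportional to the pump current
    assert np.allclose(halo.dV_gaba, -4.0 * halo.I_halo)
    assert np.all(halo.dV_gaba[halo.is_hr] >= 4.0)
    # non-expressing neurons unaffected
    assert np.all(halo.I_halo[~halo.is_hr] == 0.0)


def test_halo_none_expressing():
    halo = assign_halorhodopsin(150, HalorhodopsinConfig(f_halo=0.0), seed=0)
    assert not halo.is_hr.any() and not halo.I_halo.any()


def test_halo_mean_current_converges():
    halo = assign_halorhodopsin(20000, HalorhodopsinConfig(f_halo=1.0), seed=1)
    assert halo.I_halo.mean() == pytest.approx(-2.0, abs=0.02)


def test_halo_rejects_bad_fraction():
    with pytest.raises(ValueError):
        HalorhodopsinConfig(f_halo=1.2)


# ----------------------------------------------------------------- unitary PSP

def test_unitary_psps_match_reference_amplitudes():
    """All six single-connection PSPs agree with calibration values (10%)."""
    for name, pw in reference_pathways().items():
        post = (
            NeuronParameters.excitatory()
            if pw.post == "E"
            else NeuronParameters.inhibitory()
        )
        v = measure_unitary_psp(pw, post)
        target = REFERENCE_PSP_MV[name]
        assert v == pytest.approx(target, rel=0.10), name
        assert np.sign(v) == np.sign(target)


def test_unitary_psp_passive_oracle():
    """On a leak-only membrane the PSP follows the double-exponential
    closed form.  The closed form linearizes the synaptic driving force at
    rest, which overestimates IPSPs (the true driving force shrinks toward
    the GABA_A reversal), so agreement is ~10%, tightest for EPSPs."""
    for name, tol in (("ET", 0.03), ("EI", 0.10)):
        pw = reference_pathways()[name]
        post = NeuronParameters.excitatory().passive()
        v = measure_unitary_psp(pw, post)
        assert v == pytest.approx(passive_psp_peak(pw, post), rel=tol), name


def test_unitary_psp_rejects_spiking_neuron():
    pw = replace(reference_pathways()["ET"], g=50.0)  # absurdly strong
    with pytest.raises(RuntimeError):
        measure_unitary_psp(pw, NeuronParameters.excitatory())


def test_reference_pathway_table_integrity():
    pws = reference_pathways()
    assert pws["EI"].tau_delay == 0.85 and pws["II"].tau_delay == 0.5
    assert pws["ET"].t_syn == 2.0 and pws["EI"].t_syn == 3.0
    assert pws["EI"].V_rev == -85.0 and pws["ET"].V_rev == 0.0
    assert {p.K for p in pws.values()} == {50, 75, 200, 400, 25}
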