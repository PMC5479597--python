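"""Shared fixtures.

The heavy network simulations are session-scoped and shared across the
acceptance tests so that each condition is simulated once.  Durations and
realization counts per condition are chosen so the whole suite stays at
desk scale; they are stated in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from barrelsim import (
    CircuitSpec,
    SimulationProtocol,
    ThalamicDrive,
    reference_circuit,
    run_simulation,
)
from barrelsim.circuit import reference_pathways
from barrelsim.experiments import simulate_condition


def small_circuit(**overrides) -> CircuitSpec:
    """A scaled-down circuit for fast structural tests (not calibrated)."""
    pws = {
        name: replace(pw, K=min(pw.K, 10))
        for name, pw in reference_pathways().items()
    }
    return CircuitSpec(N_E=40, N_I=10, N_T=20, pathways=pws, **overrides)


@pytest.fixture(scope="session")
def touch_table():
    """Reference circuit, whisking+touch drive: 3 realizations x 5.5 s."""
    return simulate_condition(
        reference_circuit(), ThalamicDrive.whisking_touch(),
        seeds=(101, 102, 103), duration=5500.0,
    )


@pytest.fixture(scope="session")
def zero_delay_table():
    """Same drive with the I-to-E synaptic delay removed: 2 x 3.5 s."""
    circ = reference_circuit().with_pathway("EI", tau_delay=0.0)
    return simulate_condition(
        circ, ThalamicDrive.whisking_touch(), seeds=(101, 102), duration=3500.0,
    )


@pytest.fixture(scope="session")
def whisking_rate_curve():
    """nu_E / nu_I during whisking (no touch) at A_T = 8, 14, 20 spikes/s."""
    out = {}
    for A_T in (8.0, 14.0, 20.0):
        df = simulate_condition(
            reference_circuit(), ThalamicDrive.whisking(A_T=A_T),
            seeds=(111,), duration=3500.0,
        )
        out[A_T] = (float(df["nu_E"].mean()), float(df["nu_I"].mean()))
    return out


@pytest.fixture(scope="session")
def baseline_table():
    """Non-whisking drive (A_T=6, C_T=0): 2 realizations x 5.5 s."""
    return simulate_condition(
        reference_circuit(), ThalamicDrive.non_whisking(),
        seeds=(121, 122), duration=5500.0,
    )
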