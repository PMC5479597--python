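"""Config-driven experiments: reference runs, parameter sweeps, optogenetics.

An :class:`ExperimentConfig` bundles a circuit, a thalamic drive state and
an integration protocol, optionally with a sweep descriptor (a dotted
parameter path and a list of values) and a realization count.  A master
seed deterministically generates one integer seed per realization; the
same per-realization seeds are reused at every sweep value, so sweeping a
parameter changes nothing else about the randomness (paired comparisons).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .circuit import (
    CircuitSpec,
    HalorhodopsinConfig,
    SynapticPathway,
    reference_circuit,
)
from .drive import ThalamicDrive, touch_onsets
from .engine import SimulationProtocol, SimulationResult, run_simulation
from .metrics import detect_runaway, population_rate, touch_response
from .neurons import NeuronParameters

__all__ = [
    "ExperimentConfig",
    "generate_reference_config",
    "run_experiment",
    "simulate_condition",
    "realization_seeds",
]


@dataclass
class ExperimentConfig:
    """One experiment: base configuration plus an optional sweep."""

    circuit: CircuitSpec = field(default_factory=reference_circuit)
    drive: ThalamicDrive = field(default_factory=ThalamicDrive.whisking)
    protocol: SimulationProtocol = field(default_factory=SimulationProtocol)
    sweep_parameter: str | None = None   # dotted path, e.g. "circuit.pathways.EI.tau_delay"
    sweep_values: tuple = ()
    realizations: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")
        if self.sweep_parameter is not None and len(self.sweep_values) == 0:
            raise ValueError("sweep requires at least one value")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"]["record_voltages"] = list(self.protocol.record_voltages)
        d["sweep_values"] = list(self.sweep_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        circ = dict(d["circuit"])
        circ["pathways"] = {
            k: SynapticPathway(**v) for k, v in circ["pathways"].items()
        }
        circ["params_E"] = NeuronParameters(**circ["params_E"])
        circ["params_I"] = NeuronParameters(**circ["params_I"])
        circ["halo"] = HalorhodopsinConfig(**circ["halo"])
        d["circuit"] = CircuitSpec(**circ)
        d["drive"] = ThalamicDrive(**d["drive"])
        proto = dict(d["protocol"])
        proto["record_voltages"] = tuple(proto.get("record_voltages", ()))
        d["protocol"] = SimulationProtocol(**proto)
        d["sweep_values"] = tuple(d.get("sweep_values", ()))
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def generate_reference_config(
    state: str = "whisking",
    duration: float = 6000.0,
    realizations: int = 10,
    master_seed: int = 0,
) -> ExperimentConfig:
    """The reference parameter set packaged as a runnable configuration."""
    drive = {
        "quiet": ThalamicDrive.non_whisking,
        "whisking": ThalamicDrive.whisking,
        "touch": ThalamicDrive.whisking_touch,
    }[state]()
    return ExperimentConfig(
        circuit=reference_circuit(),
        drive=drive,
        protocol=SimulationProtocol(duration=duration),
        realizations=realizations,
        master_seed=master_seed,
    )


def realization_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-realization integer seeds derived from a master seed."""
    return [int(s) for s in
            np.random.SeedSequence(master_seed).generate_state(n) % (2**31)]


def _apply_override(config: ExperimentConfig, path: str, value) -> ExperimentConfig:
    """Return a copy of ``config`` with the dotted-path parameter replaced."""
    parts = path.split(".")
    if parts[0] == "circuit" and parts[1] == "pathways":
        # circuit.pathways.<NAME>.<field>
        _, _, name, fld = parts
        return replace(config, circuit=config.circuit.with_pathway(name, **{fld: value}))
    if parts[0] == "circuit" and parts[1] == "halo":
        halo = replace(config.circuit.halo, **{parts[2]: value})
        return replace(config, circuit=replace(config.circuit, halo=halo))
    if parts[0] in ("circuit", "drive", "protocol") and len(parts) == 2:
        obj = getattr(config, parts[0])
        if not hasattr(obj, parts[1]):
            raise ValueError(f"unknown parameter {path!r}")
        return replace(config, **{parts[0]: replace(obj, **{parts[1]: value})})
    raise ValueError(f"unknown parameter path {path!r}")


def _condition_row(result: SimulationResult, drive: ThalamicDrive) -> dict:
    """Summary metrics of one realization."""
    proto = result.protocol
    window = (proto.transient, proto.duration)
    row = {
        "nu_T": population_rate(result.spikes["T"], window),
        "nu_E": population_rate(result.spikes["E"], window),
        "nu_I": population_rate(result.spikes["I"], window),
        "runaway": detect_runaway(result.spikes["E"], window),
        "seed": proto.seed,
    }
    if drive.touch_enabled:
        onsets = touch_onsets(drive, proto.duration)
        onsets = onsets[onsets >= proto.transient]
        for pop in ("T", "E", "I"):
            row[f"R_{pop}"] = touch_response(result.spikes[pop], onsets)
    if result.halo.is_hr.any() and not result.halo.is_hr.all():
        hr, non = result.split_inhibitory()
        row["nu_I_hr"] = population_rate(hr, window)
        row["nu_I_nonhr"] = population_rate(non, window)
    elif result.halo.is_hr.all():
        row["nu_I_hr"] = row["nu_I"]
    return row


def simulate_condition(
    circuit: CircuitSpec,
    drive: ThalamicDrive,
    seeds: Sequence[int],
    duration: float = 6000.0,
    transient: float = 500.0,
    dt: float = 0.05,
    round_delays: bool = False,
) -> pd.DataFrame:
    """Run one condition over several realizations; one metrics row each."""
    rows = []
    for seed in seeds:
        proto = SimulationProtocol(
            duration=duration, dt=dt, transient=transient, seed=int(seed),
            round_delays=round_delays,
        )
        result = run_simulation(circuit, drive, proto)
        rows.append(_condition_row(result, drive))
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Execute an experiment (sweep x realizations) and return a tidy table.

    Each row is one realization at one sweep value, with population rates,
    touch responses where applicable, and a runaway flag.  If ``out_dir``
    is given, writes ``metrics.csv`` and the resolved config there.
    """
    seeds = realization_seeds(config.master_seed, config.realizations)
    values = list(config.sweep_values) if config.sweep_parameter else [None]
    frames = []
    for value in values:
        cfg = config if value is None else _apply_override(
            config, config.sweep_parameter, value
        )
        df = simulate_condition(
            cfg.circuit, cfg.drive, seeds,
            duration=cfg.protocol.duration,
            transient=cfg.protocol.transient,
            dt=cfg.protocol.dt,
            round_delays=cfg.protocol.round_delays,
        )
        if value is not None:
            df.insert(0, config.sweep_parameter, value)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        config.to_yaml(out / "config.yaml")
    return table
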