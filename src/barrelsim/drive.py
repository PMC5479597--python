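"""Thalamic (VPM) drive: inhomogeneous-Poisson spike trains.

All thalamic relay neurons share one generating function

    F_T(t) = A_T * [1 + B_T sin(2*pi*t/tau_w + phi_w)]
             + (C_T/tau_c) * rect(t mod tau_w in [t_c, t_c + tau_c))

with A_T the cycle-averaged rate (spikes/s), B_T the sinusoidal modulation
depth of whisking, and C_T the number of spikes added per touch, delivered
as a rectangle of duration tau_c at phase t_c of every whisking cycle.
Spike trains of distinct neurons are statistically independent realizations
of an inhomogeneous Poisson process with this common intensity, so any
cross-neuron correlation comes solely from the shared rate modulation.

Behavioral states differ only in (A_T, C_T): (6, 0) at rest, (14, 0)
during free whisking, (14, 0.6) during whisking with touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThalamicDrive",
    "SpikeTrainSet",
    "evaluate_generating_function",
    "sample_thalamic_spikes",
    "touch_onsets",
]


@dataclass(frozen=True)
class ThalamicDrive:
    """Parameters of the thalamic generating function for one state."""

    A_T: float = 14.0        # cycle-averaged rate, spikes/s
    B_T: float = 0.25        # modulation depth (dimensionless)
    C_T: float = 0.0         # spikes added per touch
    tau_w: float = 100.0     # whisking period, ms
    t_c: float = 50.0        # touch onset within the cycle, ms
    tau_c: float = 3.0       # touch duration, ms
    phi_w: float = np.pi / 2  # preferred phase, rad
    touch_enabled: bool = False
    label: str = "whisking"

    def __post_init__(self) -> None:
        if self.A_T < 0:
            raise ValueError("A_T must be non-negative")
        if self.B_T > 1:
            raise ValueError("B_T > 1 would allow negative rates")
        if not (0 <= self.t_c and self.t_c + self.tau_c <= self.tau_w):
            raise ValueError("touch window must lie within the whisking cycle")

    @classmethod
    def non_whisking(cls) -> "ThalamicDrive":
        return cls(A_T=6.0, C_T=0.0, touch_enabled=False, label="non-whisking")

    @classmethod
    def whisking(cls, A_T: float = 14.0) -> "ThalamicDrive":
        return cls(A_T=A_T, C_T=0.0, touch_enabled=False, label="whisking")

    @classmethod
    def whisking_touch(cls, A_T: float = 14.0, C_T: float = 0.6) -> "ThalamicDrive":
        return cls(A_T=A_T, C_T=C_T, touch_enabled=True, label="whisking+touch")


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted spike times (ms) for one population."""

    population: str
    trains: list  # list of 1-D float arrays, sorted ascending
    duration: float  # ms
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains))

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns neuron_id, time_ms."""
        ids = np.concatenate(
            [np.full(len(t), i, dtype=int) for i, t in enumerate(self.trains)]
        ) if self.trains else np.array([], dtype=int)
        times = np.concatenate(self.trains) if self.trains else np.array([])
        return pd.DataFrame({"neuron_id": ids, "time_ms": times})

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, population: str, n_neurons: int, duration: float
    ) -> "SpikeTrainSet":
        trains = [
            np.sort(frame.loc[frame["neuron_id"] == i, "time_ms"].to_numpy(float))
            for i in range(n_neurons)
        ]
        return cls(population=population, trains=trains, duration=duration)


def evaluate_generating_function(t, drive: ThalamicDrive):
    """Instantaneous thalamic rate F_T(t) in spikes/s; t in ms (scalar or array)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    rate = drive.A_T * (
        1.0 + drive.B_T * np.sin(2.0 * np.pi * t / drive.tau_w + drive.phi_w)
    )
    if drive.touch_enabled and drive.C_T > 0:
        phase = np.mod(t, drive.tau_w)
        in_touch = (phase >= drive.t_c) & (phase < drive.t_c + drive.tau_c)
        # C_T spikes spread over tau_c ms -> rate increment in spikes/s
        rate = rate + in_touch * (drive.C_T / drive.tau_c * 1000.0)
    return rate if rate.ndim else float(rate)


def touch_onsets(drive: ThalamicDrive, duration: float) -> np.ndarray:
    """Touch onset times (ms) within [0, duration): one per whisking cycle."""
    if not drive.touch_enabled:
        return np.array([])
    n_cycles = int(np.ceil(duration / drive.tau_w))
    onsets = drive.t_c + drive.tau_w * np.arange(n_cycles)
    return onsets[onsets < duration]


def sample_thalamic_spikes(
    drive: ThalamicDrive,
    N_T: int,
    duration: float,
    seed,
    dt: float = 0.05,
    method: str = "bernoulli",
) -> SpikeTrainSet:
    """Sample N_T independent inhomogeneous-Poisson trains with intensity F_T.

    method="bernoulli" draws at most one spike per time bin of width ``dt``
    (ms) with probability ``F_T(t) dt``, keeping the drive aligned to the
    integrator grid; at the reference parameters the bin probability stays
    ~1e-2 even at the touch peak, so the binomial correction is negligible.
    method="thinning" is an exact grid-free sampler retained for
    cross-validation of the default.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if method == "bernoulli":
        n_steps = int(round(duration / dt))
        t_grid = np.arange(n_steps) * dt
        p = evaluate_generating_function(t_grid, drive) * dt / 1000.0
        trains = []
        for _ in range(N_T):
            hits = rng.random(n_steps) < p
            trains.append(t_grid[hits] + dt)  # spike assigned to bin end
    elif method == "thinning":
        peak = drive.A_T * (1.0 + max(drive.B_T, 0.0))
        if drive.touch_enabled:
            peak += drive.C_T / drive.tau_c * 1000.0
        lam = peak / 1000.0  # spikes/ms
        trains = []
        for _ in range(N_T):
            n_cand = rng.poisson(lam * duration)
            cand = np.sort(rng.uniform(0.0, duration, n_cand))
            keep = rng.random(n_cand) * peak < evaluate_generating_function(cand, drive)
            trains.append(cand[keep])
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    seed_echo = seed if isinstance(seed, (int, np.integer)) else None
    return SpikeTrainSet(population="T", trains=trains, duration=duration, seed=seed_echo)
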