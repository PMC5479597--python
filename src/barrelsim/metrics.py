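"""Summary statistics: population rates, touch responses, PSTHs, runaway.

The two headline quantities are

* ``nu`` (spikes/s): the population- and time-averaged spike rate of a
  population over an analysis window, and
* ``R`` (spikes/touch): the touch response, defined as the number of
  spikes a neuron fires in the 25 ms after touch onset minus the number
  in the 25 ms before, averaged over touches and neurons.

With the touch onset placed at the minimum of the whisking-modulated
thalamic rate, the sinusoidal contribution to the two 25 ms windows
cancels exactly, so for the thalamic population E[R_T] equals C_T, the
spikes added per touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .drive import SpikeTrainSet

__all__ = [
    "PopulationMetrics",
    "population_rate",
    "touch_response",
    "compute_psth",
    "detect_runaway",
    "TOUCH_WINDOW_MS",
]

TOUCH_WINDOW_MS = 25.0
RUNAWAY_RATE_HZ = 20.0      # nu_E above this in any 500 ms window -> runaway
RUNAWAY_WINDOW_MS = 500.0


@dataclass
class PopulationMetrics:
    """Aggregated statistics of one population under one condition."""

    population: str
    nu: float                       # spikes/s
    R: float | None = None          # spikes/touch (None without touch events)
    R_sd: float | None = None       # across-realization SD of R
    psth_edges: np.ndarray | None = None
    psth_rate: np.ndarray | None = None
    window: tuple | None = None     # analysis window (ms)
    runaway: bool = False


def population_rate(spikes: SpikeTrainSet, window: tuple[float, float]) -> float:
    """Population- and time-averaged rate (spikes/s) over ``window`` (ms)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    count = sum(
        int(np.searchsorted(t, t1) - np.searchsorted(t, t0)) for t in spikes.trains
    )
    return count / (spikes.n_neurons * (t1 - t0) / 1000.0)


def touch_response(
    spikes: SpikeTrainSet,
    touch_onsets: Sequence[float],
    window: float = TOUCH_WINDOW_MS,
) -> float:
    """Mean spikes/touch: post-onset window count minus pre-onset count.

    Touches without full +/- ``window`` ms of data coverage are excluded.
    """
    onsets = np.asarray(touch_onsets, dtype=float)
    onsets = onsets[(onsets >= window) & (onsets + window <= spikes.duration)]
    if len(onsets) == 0:
        raise ValueError("no touch onsets with full window coverage")
    diff = 0.0
    for t in spikes.trains:
        post = np.searchsorted(t, onsets + window) - np.searchsorted(t, onsets)
        pre = np.searchsorted(t, onsets) - np.searchsorted(t, onsets - window)
        diff += float(np.sum(post - pre))
    return diff / (len(onsets) * spikes.n_neurons)


def compute_psth(
    spikes: SpikeTrainSet,
    events: Sequence[float],
    bin_ms: float = 1.0,
    range_ms: tuple[float, float] = (-TOUCH_WINDOW_MS, TOUCH_WINDOW_MS),
) -> tuple[np.ndarray, np.ndarray]:
    """Event-aligned histogram normalized to spikes/s per neuron.

    Returns ``(edges, rate)``; ``rate[i]`` is the population-average rate in
    ``[edges[i], edges[i+1])`` relative to the event times.
    """
    events = np.asarray(events, dtype=float)
    if len(events) == 0:
        raise ValueError("no events")
    lo, hi = range_ms
    n_bins = (hi - lo) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide the range")
    edges = lo + bin_ms * np.arange(int(round(n_bins)) + 1)
    counts = np.zeros(len(edges) - 1)
    for t in spikes.trains:
        for ev in events:
            rel = t[(t >= ev + lo) & (t < ev + hi)] - ev
            counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(events) * spikes.n_neurons * bin_ms / 1000.0)
    return edges, rate


def detect_runaway(
    spikes_E: SpikeTrainSet,
    window: tuple[float, float],
    rate_threshold: float = RUNAWAY_RATE_HZ,
    sliding_ms: float = RUNAWAY_WINDOW_MS,
) -> bool:
    """True iff nu_E exceeds ``rate_threshold`` in any sliding 500 ms window.

    The threshold sits an order of magnitude above the excitatory rates the
    stable circuit produces, so the flag separates runaway excitation from
    ordinary fluctuations.
    """
    t0, t1 = window
    if t1 - t0 < sliding_ms:
        return population_rate(spikes_E, window) > rate_threshold
    all_times = np.sort(np.concatenate([t for t in spikes_E.trains])) if \
        spikes_E.trains else np.array([])
    all_times = all_times[(all_times >= t0) & (all_times <= t1)]
    if len(all_times) == 0:
        return False
    starts = np.arange(t0, t1 - sliding_ms + 1e-9, sliding_ms / 2.0)
    max_count = rate_threshold * spikes_E.n_neurons * sliding_ms / 1000.0
    for s in starts:
        cnt = np.searchsorted(all_times, s + sliding_ms) - np.searchsorted(all_times, s)
        if cnt > max_count:
            return True
    return False
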