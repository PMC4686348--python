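"""Raw-trace preprocessing: artifact removal, spike detection, evoked counts.

The analysis pipeline normally starts from evoked counts (the simulator
emits them directly); this module covers the path from a 25 kHz
extracellular voltage trace to those counts.  Spikes are negative valleys
below -5 sigma of the per-second trace statistics, deduplicated within a
0.25 ms refractory window; the evoked response to an event is the number of
spikes in the [10, 30) ms post-stimulus latency window (earlier deflections
are direct electrical responses, not synaptic ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SpikeTrain",
    "EvokedCounts",
    "remove_artifacts",
    "detect_spikes",
    "count_evoked",
]


@dataclass
class SpikeTrain:
    """Spike times (ms) of one electrode, strictly increasing."""

    electrode: int
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        self.times_ms = t


@dataclass
class EvokedCounts:
    """Evoked spike counts, shape ``(n_elec, n_trials, n_events)``.

    ``window_ms`` records the post-stimulus latency window the counts were
    taken from; ``interval_s`` the inter-stimulus interval.
    """

    counts: np.ndarray
    window_ms: tuple[float, float] = (10.0, 30.0)
    interval_s: float = 1.0
    condition: str = "trn"
    trials: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be (n_elec, n_trials, n_events)")
        if np.nanmin(c) < 0:
            raise ValueError("counts must be non-negative")
        self.counts = c
        if self.trials is None:
            self.trials = np.arange(1, c.shape[1] + 1)

    @property
    def n_elec(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_events(self) -> int:
        return self.counts.shape[2]


def remove_artifacts(
    trace,
    sat_level: float = 1000.0,
    band: tuple[float, float] = (500.0, 2000.0),
    order: int = 4,
):
    """Zero saturated regions, band-pass, and re-zero the flagged regions.

    Saturation is detected as ``|v| >= sat_level``.  The band-pass is a
    zero-phase Butterworth design (``order`` refers to the underlying
    filter; zero-phase application doubles the effective order); the band
    edges default to the 500-2000 Hz recording band.
    """
    from .simulate import VoltageTrace

    v = np.atleast_2d(np.asarray(trace.samples, dtype=float)).copy()
    mask = np.abs(v) >= sat_level
    v[mask] = 0.0
    sos = signal.butter(order, band, btype="bandpass", fs=trace.fs, output="sos")
    v = signal.sosfiltfilt(sos, v, axis=-1)
    v[mask] = 0.0
    out = v if np.asarray(trace.samples).ndim > 1 else v[0]
    return VoltageTrace(
        samples=out,
        stim_times=trace.stim_times,
        fs=trace.fs,
        artifact_window=trace.artifact_window,
    )


def detect_spikes(
    trace,
    electrode: int = 0,
    threshold_sd: float = 5.0,
    refractory_ms: float = 0.25,
) -> SpikeTrain:
    """Detect spikes as sub-threshold valleys of an artifact-free trace.

    The mean and standard deviation are computed per non-overlapping
    one-second block (a trace shorter than one second uses its full span).
    A candidate is a local minimum ``v[k] < v[k-1] and v[k] <= v[k+1]``
    with ``v - mu < -threshold_sd * sigma``; within any ``refractory_ms``
    interval only the lowest valley is kept.
    """
    v = np.asarray(trace.samples, dtype=float)
    if v.ndim == 2:
        v = v[electrode]
    n = v.size
    fs = trace.fs
    block = int(fs)  # one second of samples

    mu = np.empty(n)
    sd = np.empty(n)
    for a in range(0, n, block):
        b = min(a + block, n)
        mu[a:b] = v[a:b].mean()
        sd[a:b] = v[a:b].std()

    interior = np.zeros(n, dtype=bool)
    interior[1:-1] = (v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:])
    cand = np.flatnonzero(interior & (v - mu < -threshold_sd * sd))
    if cand.size == 0:
        return SpikeTrain(electrode=electrode, times_ms=np.empty(0))

    # Keep the deepest valley within any refractory window: greedily accept
    # candidates from deepest to shallowest, suppressing neighbours.
    min_gap = refractory_ms * fs / 1000.0
    order = cand[np.argsort(v[cand], kind="stable")]
    kept: list[int] = []
    for k in order:
        if all(abs(k - j) >= min_gap for j in kept):
            kept.append(k)
    kept_arr = np.sort(np.asarray(kept))
    return SpikeTrain(electrode=electrode, times_ms=kept_arr * 1000.0 / fs)


def count_evoked(
    spikes: SpikeTrain,
    stim_times_ms: np.ndarray,
    window_ms: tuple[float, float] = (10.0, 30.0),
) -> np.ndarray:
    """Count spikes with latency in ``[window[0], window[1])`` per event.

    Raises if consecutive stimuli are closer than the window end (the
    windows would overlap; at the 1 Hz design this cannot happen).
    """
    stim = np.sort(np.asarray(stim_times_ms, dtype=float))
    lo, hi = window_ms
    if stim.size > 1 and np.min(np.diff(stim)) < hi:
        raise ValueError("inter-stimulus interval shorter than the count window")
    t = spikes.times_ms
    return (
        np.searchsorted(t, stim + hi, side="left")
        - np.searchsorted(t, stim + lo, side="left")
    ).astype(np.int64)
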