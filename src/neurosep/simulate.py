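"""Synthetic neural-culture simulator with known ground truth.

The forward model mirrors the linear-rate population picture used by the
analysis: the two-dimensional population response to an event is
``x~ = W s~ + xi`` with ``s~`` the channel-group mean input, ``W`` a 2x2
connectivity (spike/event per event/event), and ``xi`` Gaussian background
noise.  Each electrode's expected evoked count adds a direct component from
its nearest stimulation channel and a spontaneous baseline, is rectified at
zero, and is emitted as a Poisson count.  Between trials the connectivity is
updated by a state-dependent Hebbian rule: the update is a weighted sum of
within-trial centered cross-products of population response and input, with
one efficacy for the single-source states (1,0)/(0,1) and another for the
joint state (1,1); the silent state (0,0) never contributes.

Plasticity operates on the *observed* count group means -- a culture's
synapses see its actual spiking activity, not a noiseless latent rate.

Evoked-response reliability improves with training: while plasticity is
active, the background-noise standard deviation decays by ``noise_decay``
per trial.  With plasticity disabled (``apv_mode``, the NMDA-blockade
analog) both the connectivity and the noise level stay frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._rng import substream
from .preprocess import EvokedCounts
from .stimulus import SOURCE_STATES, StimulusSchedule

__all__ = [
    "SimConfig",
    "SimGroundTruth",
    "VoltageTrace",
    "simulate_culture",
    "apply_plasticity",
    "synthesize_trace",
]

State = tuple[int, int]


def default_efficacies(beta1: float = 0.01, beta2: float = 0.00271) -> dict[State, float]:
    """State-dependent efficacy map; the silent state is always 0."""
    return {(0, 0): 0.0, (1, 0): beta1, (0, 1): beta1, (1, 1): beta2}


def _default_w0() -> np.ndarray:
    return np.array([[2.8, 0.8], [0.8, 2.8]])


def _default_noise_cov() -> np.ndarray:
    return 2.25 * np.eye(2)


@dataclass
class SimConfig:
    """Culture-simulation parameters.

    Defaults define the reference training condition: weakly selective
    initial connectivity whose population clusters overlap at trial 1, a
    ground-truth efficacy ratio ``beta2/beta1`` of 27.1 %, and background
    noise that shrinks as training consolidates responses.

    Attributes
    ----------
    W0 : (2, 2) array
        Initial population connectivity, spike/event.
    beta : mapping of source state to efficacy
        Plasticity efficacies; ``beta[(0, 0)]`` must be 0.
    eta : float
        Plasticity step scale multiplying the per-trial Hebbian statistic.
    noise_cov : (2, 2) array
        Background-noise covariance of the latent population rate at trial
        1, (spike/event)^2.  Must be symmetric positive semi-definite.
    noise_decay : float
        Per-trial multiplicative decay of the background-noise sd while
        plasticity is active (1.0 = constant reliability).
    baseline : float
        Spontaneous rate added to every electrode, spike/event.
    local_gain : float or (n_stim,) array
        Direct-response gain of each stimulated electrode to its own
        channel (identity mapping electrode i <-> channel i).
    bg_gain : float
        Coupling of non-stimulated electrodes to the mean population rate.
    d_d, d_s : float
        Direct and synaptic response latencies in ms; used only when
        synthesizing raw voltage traces.
    apv_mode : bool
        Disable plasticity (and reliability change) entirely.
    """

    W0: np.ndarray = field(default_factory=_default_w0)
    beta: Mapping[State, float] = field(default_factory=default_efficacies)
    eta: float = 0.05
    noise_cov: np.ndarray = field(default_factory=_default_noise_cov)
    noise_decay: float = 0.9975
    baseline: float = 0.5
    local_gain: float | np.ndarray = 2.0
    bg_gain: float = 0.15
    d_d: float = 2.0
    d_s: float = 12.0
    apv_mode: bool = False

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.W0.shape != (2, 2):
            raise ValueError("W0 must be 2x2")
        if self.noise_cov.shape != (2, 2):
            raise ValueError("noise_cov must be 2x2")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() < -1e-12:
            raise ValueError("noise_cov must be positive semi-definite")
        beta = dict(self.beta)
        if beta.get((0, 0), 0.0) != 0.0:
            raise ValueError("the (0, 0) efficacy is fixed at 0")
        beta.setdefault((0, 0), 0.0)
        self.beta = beta

    def efficacies(self) -> dict[State, float]:
        return {st: float(self.beta.get(st, 0.0)) for st in SOURCE_STATES}


@dataclass
class SimGroundTruth:
    """Truth record of a simulated culture, for recovery experiments."""

    W_trajectory: np.ndarray          # (n_trials, 2, 2), W at the start of each trial
    beta_true: dict[State, float]
    seed: int | None
    electrode_group: np.ndarray       # (n_elec,) in {1, 2, 0}: u1-driven, u2-driven, unstimulated


@dataclass
class VoltageTrace:
    """Raw extracellular voltage at 25 kHz with stimulation metadata."""

    samples: np.ndarray               # (n_samples,) or (n_elec, n_samples), microvolts
    stim_times: np.ndarray            # event onsets, ms
    fs: float = 25_000.0
    artifact_window: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        if self.fs != 25_000.0:
            raise ValueError("traces are defined at a 25 kHz sampling rate")


def apply_plasticity(
    W: np.ndarray,
    z_stats: Mapping[State, np.ndarray],
    efficacies: Mapping[State, float],
    eta: float = 1.0,
) -> np.ndarray:
    """One state-dependent Hebbian step: ``W + eta * sum_u beta_u z^u``.

    ``z_stats`` maps source states to 2x2 within-trial centered
    cross-product matrices.  The (0, 0) entry is ignored regardless of the
    efficacy map (its efficacy is 0 by assumption).
    """
    dW = np.zeros((2, 2))
    for st, z in z_stats.items():
        if st == (0, 0):
            continue
        eff = float(efficacies.get(st, 0.0))
        if eff:
            dW += eff * np.asarray(z)
    return np.asarray(W, dtype=float) + eta * dW


def hebbian_increments(
    x_obs: np.ndarray, s_tilde: np.ndarray, masks: Mapping[State, np.ndarray]
) -> dict[State, np.ndarray]:
    """Within-trial centered cross-products ``z^u`` from one trial's series."""
    xc = x_obs - x_obs.mean(axis=1, keepdims=True)
    sc = s_tilde - s_tilde.mean(axis=1, keepdims=True)
    return {st: xc[:, m] @ sc[:, m].T for st, m in masks.items()}


def simulate_culture(
    schedule: StimulusSchedule,
    config: SimConfig | None = None,
    seed: int | None = None,
    plastic_trials: np.ndarray | None = None,
) -> tuple[EvokedCounts, SimGroundTruth]:
    """Simulate evoked counts for one culture over a full training run.

    Parameters
    ----------
    schedule : StimulusSchedule
        The (trial-invariant) stimulation schedule.
    config : SimConfig
        Simulation parameters; defaults are the reference condition.
    seed : int
        Master seed; noise and counts use independent substreams.
    plastic_trials : bool array of length n_trials, optional
        Which trials are followed by a plasticity update.  Defaults to all
        (or none under ``apv_mode``).  Used e.g. for partial-training
        protocols where the culture rests between two training blocks.

    Returns
    -------
    (EvokedCounts, SimGroundTruth)
        Counts have shape ``(n_elec, n_trials, n_events)``.
    """
    config = config or SimConfig()
    p = schedule.params
    n_elec, n_stim = p.n_elec, p.n_stim
    n_trials, n_events = p.n_trials, p.n_events
    half = n_stim // 2

    rng_noise = substream(seed, "noise")
    rng_counts = substream(seed, "counts")

    s = schedule.s.astype(float)
    s_tilde = schedule.s_tilde()
    masks = schedule.state_masks()
    gain = np.broadcast_to(np.asarray(config.local_gain, float), (n_stim,))

    # Noise is drawn as L @ standard-normal with L scaled per trial.
    L = np.linalg.cholesky(config.noise_cov + 1e-15 * np.eye(2))

    plastic = np.ones(n_trials, dtype=bool) if plastic_trials is None else np.asarray(
        plastic_trials, dtype=bool
    )
    if plastic.shape != (n_trials,):
        raise ValueError("plastic_trials must have length n_trials")
    if config.apv_mode:
        plastic = np.zeros(n_trials, dtype=bool)

    group = np.zeros(n_elec, dtype=np.int8)
    group[:half] = 1
    group[half:n_stim] = 2

    W = config.W0.copy()
    eff = config.efficacies()
    scale = 1.0
    counts = np.empty((n_elec, n_trials, n_events), dtype=np.int64)
    W_traj = np.empty((n_trials, 2, 2))

    for l in range(n_trials):
        W_traj[l] = W
        xi = (scale * L) @ rng_noise.standard_normal((2, n_events))
        x_lat = W @ s_tilde + xi
        rate = np.empty((n_elec, n_events))
        rate[:half] = config.baseline + gain[:half, None] * s[:half] + x_lat[0]
        rate[half:n_stim] = (
            config.baseline + gain[half:, None] * s[half:] + x_lat[1]
        )
        rate[n_stim:] = config.baseline + config.bg_gain * 0.5 * (
            x_lat[0] + x_lat[1]
        )
        np.maximum(rate, 0.0, out=rate)
        counts[:, l] = rng_counts.poisson(rate)

        if plastic[l]:
            x_obs = np.stack(
                [counts[:half, l].mean(axis=0), counts[half:n_stim, l].mean(axis=0)]
            )
            z = hebbian_increments(x_obs, s_tilde, masks)
            W = apply_plasticity(W, z, eff, config.eta)
            scale *= config.noise_decay

    truth = SimGroundTruth(
        W_trajectory=W_traj,
        beta_true=eff,
        seed=seed,
        electrode_group=group,
    )
    return EvokedCounts(counts=counts), truth


def synthesize_trace(
    spike_times_ms: np.ndarray,
    stim_times_ms: np.ndarray,
    duration_ms: float | None = None,
    noise_sd: float = 10.0,
    spike_amplitude: float | None = None,
    sat_level: float = 1000.0,
    artifact_window: tuple[float, float] = (-3.0, 3.0),
    seed: int | None = None,
) -> VoltageTrace:
    """Synthesize a single-electrode voltage trace with planted spikes.

    Gaussian background noise plus a stereotyped negative-valley waveform at
    each spike time, plus a saturating artifact around each stimulation.
    Spikes falling inside an artifact window are dropped with a warning.
    Default spike amplitude is ``-8 * noise_sd`` (well below the -5 sigma
    detection threshold).
    """
    import warnings

    fs = 25_000.0
    spike_times_ms = np.sort(np.asarray(spike_times_ms, dtype=float))
    stim_times_ms = np.sort(np.asarray(stim_times_ms, dtype=float))
    if duration_ms is None:
        last = max(
            spike_times_ms[-1] if spike_times_ms.size else 0.0,
            stim_times_ms[-1] if stim_times_ms.size else 0.0,
        )
        duration_ms = last + 50.0
    n = int(round(duration_ms * fs / 1000.0))
    rng = substream(seed, "trace")
    v = rng.normal(0.0, noise_sd, n)

    if spike_amplitude is None:
        spike_amplitude = -8.0 * noise_sd

    # Stereotyped ~1.2 ms biphasic waveform: sharp negative valley, small
    # positive rebound.
    t_w = np.arange(-0.4e-3, 0.8e-3, 1.0 / fs)
    wave = np.exp(-0.5 * (t_w / 0.1e-3) ** 2) - 0.25 * np.exp(
        -0.5 * ((t_w - 0.35e-3) / 0.2e-3) ** 2
    )
    wave = spike_amplitude * wave / wave.max()
    k0 = int(np.argmin(np.abs(t_w)))

    lo, hi = artifact_window
    for ts in spike_times_ms:
        in_artifact = stim_times_ms.size and np.any(
            (ts >= stim_times_ms + lo) & (ts <= stim_times_ms + hi)
        )
        if in_artifact:
            warnings.warn(
                f"spike at {ts:.3f} ms falls inside a stimulation artifact "
                "window and was dropped",
                stacklevel=2,
            )
            continue
        k = int(round(ts * fs / 1000.0))
        a, b = k - k0, k - k0 + wave.size
        if a < 0 or b > n:
            continue
        v[a:b] += wave

    for ts in stim_times_ms:
        a = max(0, int(round((ts + lo) * fs / 1000.0)))
        b = min(n, int(round((ts + hi) * fs / 1000.0)))
        v[a:b] = sat_level

    return VoltageTrace(
        samples=v, stim_times=stim_times_ms, fs=fs, artifact_window=artifact_window
    )
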