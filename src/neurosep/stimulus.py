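"""Stimulation-schedule generation.

Two hidden binary sources ``u(t) = (u1, u2)`` drive 32 stimulation channels
``s(t)`` through a probabilistic mixing step: at each one-second event, every
channel in the first half of the array copies ``u1`` with probability *a*
(and ``u2`` otherwise), while every channel in the second half copies ``u2``
with probability *a*.  Equivalently the channel intensities are ``A @ u``
with a mixing matrix whose rows are ``(a, 1-a)`` for the first half and
``(1-a, a)`` for the second.  A trial is 256 such events; the same event
pattern is replayed on every trial of a 100-trial training run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = [
    "StimulusParams",
    "StimulusSchedule",
    "mixing_matrix",
    "generate_sources",
    "mix_inputs",
    "generate_schedule",
]

#: Source states in canonical order; used as the last axis of conditional
#: statistics throughout the package.
SOURCE_STATES: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))


@dataclass(frozen=True)
class StimulusParams:
    """Parameters of the generative stimulation process.

    Attributes
    ----------
    rho : float
        Per-event firing probability of each hidden source, in [0, 1].
    a : float
        Mixing balance, in [0, 1].  ``a = 1`` delivers each source unmixed
        to its own channel group; ``a = 1/2`` erases the group identity.
    n_events : int
        Stimulation events per trial (one per second).
    n_trials : int
        Training trials.
    n_stim : int
        Stimulation channels (first half biased to source 1, second half to
        source 2).  Must not exceed ``n_elec``.
    n_elec : int
        Recording electrodes.
    seed : int or None
        Master seed for schedule generation when used via
        :func:`generate_schedule` without an explicit seed.
    """

    rho: float = 0.5
    a: float = 0.75
    n_events: int = 256
    n_trials: int = 100
    n_stim: int = 32
    n_elec: int = 64
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [0, 1], got {self.a}")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_stim > self.n_elec:
            raise ValueError("n_stim cannot exceed n_elec")
        if self.n_stim < 2 or self.n_stim % 2:
            raise ValueError("n_stim must be an even number >= 2")


@dataclass(frozen=True)
class StimulusSchedule:
    """A realized stimulation schedule, common to all trials of a run.

    ``u`` has shape ``(2, n_events)`` and ``s`` shape ``(n_stim, n_events)``,
    both binary.  ``A`` is the ``(n_stim, 2)`` mixing matrix of the
    generative process (channel intensities are ``A @ u``).
    """

    u: np.ndarray
    s: np.ndarray
    A: np.ndarray
    params: StimulusParams = field(default_factory=StimulusParams)

    def __post_init__(self) -> None:
        u = np.asarray(self.u)
        s = np.asarray(self.s)
        if u.shape[0] != 2 or s.shape[1] != u.shape[1]:
            raise ValueError(
                f"inconsistent schedule shapes u{u.shape}, s{s.shape}"
            )
        for name, arr in (("u", u), ("s", s)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary")

    @property
    def n_events(self) -> int:
        return self.u.shape[1]

    def state_masks(self) -> dict[tuple[int, int], np.ndarray]:
        """Boolean event masks for the four source states."""
        return {
            st: (self.u[0] == st[0]) & (self.u[1] == st[1])
            for st in SOURCE_STATES
        }

    def s_tilde(self) -> np.ndarray:
        """Population input ``(2, n_events)``: channel-group means of s."""
        half = self.s.shape[0] // 2
        return np.stack([self.s[:half].mean(axis=0), self.s[half:].mean(axis=0)])


def mixing_matrix(params: StimulusParams) -> np.ndarray:
    """The ``(n_stim, 2)`` mixing matrix with rows (a, 1-a) then (1-a, a)."""
    half = params.n_stim // 2
    A = np.empty((params.n_stim, 2))
    A[:half] = (params.a, 1.0 - params.a)
    A[half:] = (1.0 - params.a, params.a)
    return A


def generate_sources(params: StimulusParams, seed=None) -> np.ndarray:
    """Draw the two hidden sources as i.i.d. Bernoulli(rho) event trains.

    Returns a ``(2, n_events)`` int8 array.  ``seed`` may be an int, a
    ``numpy.random.Generator``, or None (falls back to ``params.seed``).
    """
    rng = _resolve_rng(seed, params, "sources")
    omega = rng.random((2, params.n_events))
    return (omega < params.rho).astype(np.int8)


def mix_inputs(u: np.ndarray, params: StimulusParams, seed=None) -> np.ndarray:
    """Mix the sources into the binary channel inputs.

    Each channel independently copies its preferred source with probability
    ``a`` and the other source otherwise, so every ``s_i(t)`` is one of
    ``u1(t)`` or ``u2(t)``.

    Returns a ``(n_stim, n_events)`` int8 array.
    """
    u = np.asarray(u)
    if u.shape != (2, params.n_events):
        raise ValueError(
            f"u has shape {u.shape}, expected (2, {params.n_events})"
        )
    rng = _resolve_rng(seed, params, "mixing")
    half = params.n_stim // 2
    omega = rng.random((params.n_stim, params.n_events))
    takes_u1 = np.empty_like(omega, dtype=bool)
    takes_u1[:half] = omega[:half] < params.a
    takes_u1[half:] = omega[half:] < 1.0 - params.a
    return np.where(takes_u1, u[0], u[1]).astype(np.int8)


def generate_schedule(params: StimulusParams, seed=None) -> StimulusSchedule:
    """Generate sources, mix them, and bundle the result with its matrix."""
    base = params.seed if seed is None else seed
    u = generate_sources(params, substream(base, "sources"))
    s = mix_inputs(u, params, substream(base, "mixing"))
    return StimulusSchedule(u=u, s=s, A=mixing_matrix(params), params=params)


def _resolve_rng(seed, params: StimulusParams, stream: str) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        seed = params.seed
    return substream(seed, stream)
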