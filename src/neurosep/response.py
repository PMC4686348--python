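"""Per-electrode evoked-response statistics and source-preference analysis.

Responses are summarized per electrode by their conditional means given the
four source states.  An electrode is *available* when its state-averaged
response reaches 1 spike/event, and is labelled u1-preferring (G1) or
u2-preferring (G2) when the all-trial conditional means for the two pure
states differ by at least 0.5 spike/event.  The divergence between an
electrode's response distributions under the two pure states, assuming
Poisson conditionals, has the closed form

    D_KL(lam1 || lam2) = (ln lam1 - ln lam2) lam1 - lam1 + lam2  [nats]

which tracks how sharply the electrode discriminates the hidden sources.
A pure channel-follower under mixing balance a = 3/4 shows a conditional
mean ratio of exactly a/(1-a) = 3 between the pure states, so responses
whose ratio *exceeds* 3 are coding the source rather than their nearest
channel ("source coding").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import SOURCE_STATES

__all__ = [
    "ConditionalStats",
    "KLDTransition",
    "CodingDiagnostics",
    "conditional_stats",
    "kld_poisson",
    "kld_transition",
    "clip_delta",
    "source_coding_fraction",
    "coding_correlations",
]

# Preference labels
UNAVAILABLE, G0, G1, G2 = -1, 0, 1, 2


@dataclass
class ConditionalStats:
    """Conditional response means and preference labels.

    ``x_u`` has shape ``(n_elec, n_trials, 4)`` with the last axis ordered
    as ``SOURCE_STATES``; missing (trial, state) cells are NaN.  ``x_u_bar``
    is the all-trial average (NaN cells excluded, not zero-filled).
    ``label`` is -1 (unavailable), 0 (no preference), 1 (u1-preferring) or
    2 (u2-preferring).
    """

    x_u: np.ndarray
    x_u_bar: np.ndarray
    available: np.ndarray
    label: np.ndarray
    availability_threshold: float = 1.0
    preference_threshold: float = 0.5
    n_events: int = 256

    def group(self, which: int) -> np.ndarray:
        """Electrode indices with the given label."""
        return np.flatnonzero(self.label == which)


@dataclass
class KLDTransition:
    """Per-electrode, per-trial Poisson KLD (nats); NaN where undefined."""

    d_kl: np.ndarray
    available: np.ndarray

    def group_mean(self) -> np.ndarray:
        """Mean over available electrodes per trial."""
        return np.nanmean(self.d_kl[self.available], axis=0)


@dataclass
class CodingDiagnostics:
    """Correlation of each electrode with the sources and the error signals."""

    corr_u: np.ndarray        # (n_elec, 2)
    corr_e: np.ndarray        # (n_elec, 2)
    state_coding: np.ndarray  # bool per electrode
    error_coding: np.ndarray
    threshold: float = 0.4

    @property
    def state_fraction(self) -> float:
        ok = ~np.isnan(self.corr_u).all(axis=1)
        return float(self.state_coding[ok].mean()) if ok.any() else float("nan")

    @property
    def error_fraction(self) -> float:
        ok = ~np.isnan(self.corr_e).all(axis=1)
        return float(self.error_coding[ok].mean()) if ok.any() else float("nan")


def conditional_stats(
    counts,
    u: np.ndarray,
    availability_threshold: float = 1.0,
    preference_threshold: float = 0.5,
) -> ConditionalStats:
    """Per-trial conditional means, availability, and preference labels.

    ``counts`` is an :class:`~neurosep.preprocess.EvokedCounts` or a plain
    ``(n_elec, n_trials, n_events)`` array (NaN marks missing data);
    ``u`` is the ``(2, n_events)`` source schedule shared by all trials.
    """
    c = np.asarray(getattr(counts, "counts", counts), dtype=float)
    u = np.asarray(u)
    if u.shape != (2, c.shape[2]):
        raise ValueError("u must be (2, n_events) matching counts")

    x_u = np.full(c.shape[:2] + (4,), np.nan)
    for k, (a, b) in enumerate(SOURCE_STATES):
        m = (u[0] == a) & (u[1] == b)
        if m.any():
            with np.errstate(invalid="ignore"):
                x_u[:, :, k] = np.nanmean(c[:, :, m], axis=2)

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        x_u_bar = np.nanmean(x_u, axis=1)
    available = np.nanmean(x_u_bar, axis=1) >= availability_threshold
    diff = x_u_bar[:, 1] - x_u_bar[:, 2]  # (1,0) minus (0,1)

    label = np.full(c.shape[0], G0, dtype=np.int8)
    label[diff >= preference_threshold] = G1
    label[diff <= -preference_threshold] = G2
    label[~available] = UNAVAILABLE
    return ConditionalStats(
        x_u=x_u,
        x_u_bar=x_u_bar,
        available=available,
        label=label,
        availability_threshold=availability_threshold,
        preference_threshold=preference_threshold,
        n_events=c.shape[2],
    )


def kld_poisson(lam1, lam2, floor: float | None = None):
    """KLD between Poisson distributions with the given means, in nats.

    Limit conventions: ``lam1 = 0`` gives ``lam2``; ``lam2 = 0`` with
    ``lam1 > 0`` diverges and is either +inf (default) or evaluated with
    ``lam2`` floored at ``floor`` (a pseudo-count keeping trial curves
    finite while preserving their ordering).
    """
    l1 = np.asarray(lam1, dtype=float)
    l2 = np.asarray(lam2, dtype=float)
    if np.nanmin(l1, initial=0.0) < 0 or np.nanmin(l2, initial=0.0) < 0:
        raise ValueError("Poisson means must be non-negative")
    if floor is not None:
        l2 = np.maximum(l2, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (np.log(l1) - np.log(l2)) * l1 - l1 + l2
    out = np.where(l1 == 0, l2, out)        # lim lam1 -> 0
    out = np.where((l1 > 0) & (l2 == 0), np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def kld_transition(stats: ConditionalStats, floor: float | None = None) -> KLDTransition:
    """Per-electrode KLD between the (1,0)- and (0,1)-conditioned responses.

    ``floor`` defaults to one pseudo-count over all events of the run,
    ``1 / (n_trials * n_events)``, applied to the (0,1) mean so that trial
    curves stay finite while preserving their ordering.
    """
    x10 = stats.x_u[:, :, 1]
    x01 = stats.x_u[:, :, 2]
    if floor is None:
        floor = 1.0 / max(1, x10.shape[1] * stats.n_events)
    with np.errstate(invalid="ignore"):
        d = kld_poisson(np.nan_to_num(x10, nan=0.0), np.nan_to_num(x01, nan=0.0), floor=floor)
    d = np.where(np.isnan(x10) | np.isnan(x01), np.nan, d)
    d = np.where(stats.available[:, None], d, np.nan)
    return KLDTransition(d_kl=d, available=stats.available)


def clip_delta(trans: KLDTransition, limit: float = 10.0, ref_trial: int = 0) -> np.ndarray:
    """Change in KLD from a reference trial, clipped to ``[-limit, limit]``."""
    delta = trans.d_kl - trans.d_kl[:, [ref_trial]]
    return np.clip(delta, -limit, limit)


@dataclass
class SourceCodingFraction:
    """Fraction of preferring electrodes whose response ratio exceeds 3."""

    frac_g1: float
    frac_g2: float
    per_trial_g1: np.ndarray
    per_trial_g2: np.ndarray
    ratio_criterion: float = 3.0


def source_coding_fraction(
    stats: ConditionalStats, ratio: float = 3.0
) -> SourceCodingFraction:
    """Source-coding diagnostics from the conditional means.

    Among u1-preferring electrodes, the fraction whose all-trial mean
    response to (1,0) strictly exceeds ``ratio`` times the (0,1) response
    (and symmetrically for u2-preferring electrodes), plus per-trial
    versions of the same fractions.
    """
    g1 = stats.label == G1
    g2 = stats.label == G2

    def _frac(mask, hi, lo):
        if not mask.any():
            return float("nan")
        return float(np.mean(hi[mask] > ratio * lo[mask]))

    frac_g1 = _frac(g1, stats.x_u_bar[:, 1], stats.x_u_bar[:, 2])
    frac_g2 = _frac(g2, stats.x_u_bar[:, 2], stats.x_u_bar[:, 1])

    x10, x01 = stats.x_u[:, :, 1], stats.x_u[:, :, 2]
    with np.errstate(invalid="ignore"):
        pt_g1 = (
            np.nanmean(x10[g1] > ratio * x01[g1], axis=0)
            if g1.any()
            else np.full(stats.x_u.shape[1], np.nan)
        )
        pt_g2 = (
            np.nanmean(x01[g2] > ratio * x10[g2], axis=0)
            if g2.any()
            else np.full(stats.x_u.shape[1], np.nan)
        )
    return SourceCodingFraction(
        frac_g1=frac_g1,
        frac_g2=frac_g2,
        per_trial_g1=pt_g1,
        per_trial_g2=pt_g2,
        ratio_criterion=ratio,
    )


def coding_correlations(
    counts,
    u: np.ndarray,
    x_tilde: np.ndarray,
    threshold: float = 0.4,
) -> CodingDiagnostics:
    """State-coding vs error-coding classification of electrodes.

    Event series are concatenated over all trials.  The error signal of
    population component k is

        e_k(t) = x~_k(t) - (sum_t x~_k(t) / sum_t u_k(t)) u_k(t),

    i.e. the residual of the population response after removing its best
    scalar prediction from the matching source.  An electrode is
    state-coding when its correlation with either source exceeds
    ``threshold``, and error-coding when the absolute correlation with
    either error signal does.
    """
    c = np.asarray(getattr(counts, "counts", counts), dtype=float)
    n_elec, n_trials, n_events = c.shape
    series = c.reshape(n_elec, -1)
    u_full = np.tile(np.asarray(u, dtype=float), n_trials)
    x_arr = np.asarray(x_tilde, dtype=float)
    if x_arr.ndim == 3:  # (n_trials, 2, n_events)
        x_full = np.moveaxis(x_arr, 1, 0).reshape(2, -1)
    elif x_arr.ndim == 2 and x_arr.shape[0] == 2:  # already (2, total events)
        x_full = x_arr
    else:
        raise ValueError("x_tilde must be (n_trials, 2, n_events) or (2, T)")
    if x_full.shape[1] != series.shape[1]:
        raise ValueError("population series length does not match counts")

    e = np.empty_like(x_full)
    for k in range(2):
        tot_u = u_full[k].sum()
        gain = x_full[k].sum() / tot_u if tot_u > 0 else 0.0
        e[k] = x_full[k] - gain * u_full[k]

    corr_u = _corr_columns(series, u_full)
    corr_e = _corr_columns(series, e)
    with np.errstate(invalid="ignore"):
        state = np.nan_to_num(corr_u, nan=-np.inf).max(axis=1) > threshold
        error = np.nan_to_num(np.abs(corr_e), nan=-np.inf).max(axis=1) > threshold
    return CodingDiagnostics(
        corr_u=corr_u,
        corr_e=corr_e,
        state_coding=state,
        error_coding=error,
        threshold=threshold,
    )


def _corr_columns(series: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson correlation of each series row with each target row.

    Zero-variance rows (either side) yield NaN, flagging the electrode.
    """
    s = series - series.mean(axis=1, keepdims=True)
    t = targets - targets.mean(axis=1, keepdims=True)
    s_sd = np.sqrt((s**2).sum(axis=1))
    t_sd = np.sqrt((t**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (s @ t.T) / np.outer(s_sd, t_sd)
    out[s_sd == 0] = np.nan
    out[:, t_sd == 0] = np.nan
    return out
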