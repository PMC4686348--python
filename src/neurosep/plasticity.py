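"""Learning-rule inference: Hebbian (alpha) vs state-dependent (beta) models.

Both models explain the per-trial connectivity change as a weighted sum of
the Hebbian statistics

    z_ij^u(l) = sum_{t : u(t) = u} (x~_i(t) - <x~_i>) (s~_j(t) - <s~_j>),

centered by within-trial means, with the silent state (0,0) contributing
nothing.  The alpha-model uses one efficacy for all active states,

    dW_ij(l) = alpha (z_ij^{10} + z_ij^{01} + z_ij^{11}) + noise,

while the beta-model splits the single-source and joint states,

    dW_ij(l) = beta1 (z_ij^{10} + z_ij^{01}) + beta2 z_ij^{11} + noise.

Because the raw trial-to-trial connectivity differences are noisy and
saturate late in training, the response variable is the constant average
change dW_ij = (W_ij(last) - W_ij(first)) / n_trials for every trial.  Both
estimators are Gaussian maximum-likelihood closed forms (a shared residual
variance across the four matrix entries), and the models are compared by
the Schwarz Bayesian information criterion on the same residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PopulationSeries

__all__ = [
    "HebbStats",
    "EfficacyFit",
    "hebbian_statistics",
    "estimate_alpha",
    "estimate_beta",
    "model_bic",
    "predict_connectivity_change",
]

# Active source states entering the estimators, in storage order.
ACTIVE_STATES = ((1, 0), (0, 1), (1, 1))


@dataclass
class HebbStats:
    """Hebbian statistics of one culture.

    ``z`` has shape ``(n_trials, 3, 2, 2)`` with the state axis ordered as
    ``ACTIVE_STATES`` ((0,0) is excluded once and for all); ``dW`` is the
    2x2 constant per-trial change.
    """

    z: np.ndarray
    dW: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    @property
    def z_single(self) -> np.ndarray:
        """(n_trials, 2, 2) sum of the two single-source statistics."""
        return self.z[:, 0] + self.z[:, 1]

    @property
    def z_joint(self) -> np.ndarray:
        return self.z[:, 2]

    @property
    def z_total(self) -> np.ndarray:
        return self.z.sum(axis=1)


@dataclass
class EfficacyFit:
    """Fitted learning efficacies of one culture with model-fit summaries."""

    model: str                       # "alpha" or "beta"
    mu_alpha: float | None = None
    mu_beta1: float | None = None
    mu_beta2: float | None = None
    residual_variance: float = np.nan
    nll: float = np.nan
    bic: float = np.nan
    n_params: int = 0
    n_residuals: int = 0

    @property
    def efficacy_ratio(self) -> float:
        """beta2 / beta1 (beta-model only)."""
        if self.model != "beta":
            raise ValueError("efficacy ratio is defined for the beta-model")
        return self.mu_beta2 / self.mu_beta1


def hebbian_statistics(
    pop: PopulationSeries,
    W_trajectory: np.ndarray,
    centering: str = "trial",
) -> HebbStats:
    """Centered cross-product statistics and average connectivity change.

    ``W_trajectory`` is ``(n_trials, 2, 2)`` (typically the per-trial ML
    connectivity estimates).  ``centering`` selects the means used to
    center x~ and s~: ``"trial"`` (within-trial empirical means, default)
    or ``"all"`` (means over all trials pooled).  A state absent from a
    trial contributes an empty (zero) statistic.
    """
    W_trajectory = np.asarray(W_trajectory, dtype=float)
    n_trials = pop.n_trials
    if W_trajectory.shape != (n_trials, 2, 2):
        raise ValueError("W_trajectory must be (n_trials, 2, 2)")
    if centering not in ("trial", "all"):
        raise ValueError("centering must be 'trial' or 'all'")

    masks = [
        (pop.u[0] == a) & (pop.u[1] == b) for a, b in ACTIVE_STATES
    ]
    s = pop.s
    if centering == "all":
        x_mean_all = pop.x.mean(axis=(0, 2), keepdims=False)  # (2,)
        s_mean = s.mean(axis=1, keepdims=True)

    z = np.zeros((n_trials, 3, 2, 2))
    for l in range(n_trials):
        X = pop.x[l]
        if centering == "trial":
            xc = X - X.mean(axis=1, keepdims=True)
            sc = s - s.mean(axis=1, keepdims=True)
        else:
            xc = X - x_mean_all[:, None]
            sc = s - s_mean
        for k, m in enumerate(masks):
            if m.any():
                z[l, k] = xc[:, m] @ sc[:, m].T

    dW = (W_trajectory[-1] - W_trajectory[0]) / n_trials
    return HebbStats(z=z, dW=dW)


def _residual_fit(d: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """ML residual variance and negative log likelihood at the optimum."""
    r = d - pred
    n = r.size
    var = float(r @ r / n)
    # floor at a scale-relative epsilon so that exact fits (residuals at
    # machine precision) compare as equally good rather than by rounding noise
    floor = 1e-20 * float(d @ d / n) + np.finfo(float).tiny
    var = max(var, floor)
    nll = 0.5 * n * (1.0 + np.log(2.0 * np.pi * var))
    return var, nll


def model_bic(nll: float, n_params: int, n_residuals: int) -> float:
    """Schwarz criterion ``k ln n + 2 NLL`` (lower is better)."""
    if n_residuals <= n_params:
        raise ValueError("need more residuals than parameters")
    return n_params * np.log(n_residuals) + 2.0 * nll


def estimate_alpha(stats: HebbStats) -> EfficacyFit:
    """Closed-form ML estimate of the single Hebbian efficacy.

    ``mu_alpha = sum dW_ij z_ij^tot(l) / sum (z_ij^tot(l))^2`` over all
    trials and matrix entries.  The fit counts two parameters (efficacy and
    residual variance) in its BIC.
    """
    c = stats.z_total.reshape(stats.n_trials, -1).ravel()
    d = np.broadcast_to(stats.dW.ravel(), (stats.n_trials, 4)).ravel()
    denom = float(c @ c)
    if denom == 0.0:
        raise ZeroDivisionError(
            "all Hebbian statistics are zero; the efficacy is unidentifiable"
        )
    mu = float(c @ d) / denom
    var, nll = _residual_fit(d, mu * c)
    n = d.size
    return EfficacyFit(
        model="alpha",
        mu_alpha=mu,
        residual_variance=var,
        nll=nll,
        bic=model_bic(nll, 2, n),
        n_params=2,
        n_residuals=n,
    )


def estimate_beta(stats: HebbStats) -> EfficacyFit:
    """Closed-form ML estimate of the state-dependent efficacies.

    Solves the 2x2 normal equations for (beta1, beta2) where beta1 weights
    the single-source statistics and beta2 the joint-state statistic.  The
    fit counts three parameters in its BIC.
    """
    a = stats.z_single.reshape(stats.n_trials, -1).ravel()
    b = stats.z_joint.reshape(stats.n_trials, -1).ravel()
    d = np.broadcast_to(stats.dW.ravel(), (stats.n_trials, 4)).ravel()
    M = np.array([[a @ a, a @ b], [b @ a, b @ b]])
    if np.linalg.cond(M) > 1e12:
        raise np.linalg.LinAlgError(
            "singular normal matrix; beta efficacies are unidentifiable "
            "(e.g. the joint-state statistic vanishes)"
        )
    b1, b2 = np.linalg.solve(M, np.array([a @ d, b @ d]))
    var, nll = _residual_fit(d, b1 * a + b2 * b)
    n = d.size
    return EfficacyFit(
        model="beta",
        mu_beta1=float(b1),
        mu_beta2=float(b2),
        residual_variance=var,
        nll=nll,
        bic=model_bic(nll, 3, n),
        n_params=3,
        n_residuals=n,
    )


def predict_connectivity_change(fit: EfficacyFit, stats: HebbStats) -> np.ndarray:
    """Model-implied total connectivity change over the whole run.

    Sums the fitted per-trial changes, entrywise; used to contrast how the
    two plasticity rules extrapolate the off-diagonal (between-group)
    connections.
    """
    if fit.model == "alpha":
        per_trial = fit.mu_alpha * stats.z_total
    elif fit.model == "beta":
        per_trial = fit.mu_beta1 * stats.z_single + fit.mu_beta2 * stats.z_joint
    else:
        raise ValueError(f"unknown model {fit.model!r}")
    return per_trial.sum(axis=0)
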