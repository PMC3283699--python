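"""Empirical-Bayes shrinkage for exchangeable effect panels.

Prior (mu, tau^2) estimation by the method of moments, posterior
means/variances, prediction and confidence intervals, and the
efficiency diagnostics that compare the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DataError, DegeneratePriorWarning, SmallPanelWarning
from .panel import EffectPanel

__all__ = [
    "PriorEstimate",
    "PosteriorPanel",
    "IntervalSet",
    "estimate_prior",
    "compute_posterior",
    "prediction_intervals",
    "confidence_intervals",
    "efficiency_gain",
    "expected_coverage_count",
    "minimum_panel_size",
]


@dataclass(frozen=True)
class PriorEstimate:
    """Hyperparameters of the exchangeable prior, estimated or supplied.

    ``truncated`` records that the raw moment estimate of the prior
    variance was negative and was clipped to zero.
    """

    mu_hat: float
    tau2_hat: float
    k: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.tau2_hat < 0:
            raise DataError("tau2_hat must be nonnegative")
        if self.k < 2:
            raise DataError("a prior needs a panel of at least 2 factors")


@dataclass
class PosteriorPanel:
    """Per-factor posterior means and variances under the estimated prior."""

    post_mean: np.ndarray
    post_var: np.ndarray
    prior: PriorEstimate
    labels: list[str]


@dataclass
class IntervalSet:
    """Per-factor interval bounds at a stated level.

    ``kind`` is "CI" (classical Wald) or "PI" (empirical-Bayes
    prediction).  ``significant`` flags intervals that exclude zero
    (open intervals: lower > 0 or upper < 0).
    """

    lower: np.ndarray
    upper: np.ndarray
    level: float
    kind: str
    labels: list[str]

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise DataError(f"level must be in (0, 1), got {self.level}")
        if self.kind not in ("CI", "PI"):
            raise DataError(f"kind must be 'CI' or 'PI', got {self.kind!r}")
        if np.any(self.lower > self.upper):
            raise DataError("interval lower bounds exceed upper bounds")

    @property
    def significant(self) -> np.ndarray:
        return (self.lower > 0) | (self.upper < 0)

    @property
    def length(self) -> np.ndarray:
        return self.upper - self.lower


def estimate_prior(panel: EffectPanel, warn: bool = True) -> PriorEstimate:
    """Method-of-moments prior from the panel itself.

    mu_hat is the unweighted average of the estimates.  tau2_hat is

        max(0, S^2 - mean(se^2) + (2 / (K (K-1))) * sum_{i<j} cov_ij)

    where S^2 is the sample variance of the estimates; the covariance
    term corrects for correlated estimates and vanishes when the panel
    has no covariance matrix (independence) or a diagonal one.
    """
    k = panel.k
    if k < 2:
        raise DataError("prior estimation requires at least 2 factors")
    mu_hat = float(panel.beta.mean())
    s2 = float(panel.beta.var(ddof=1))
    mean_var = float(panel.var.mean())
    cov_term = 0.0
    if panel.cov is not None:
        off_sum = float((panel.cov.sum() - np.trace(panel.cov)) / 2.0)
        cov_term = 2.0 * off_sum / (k * (k - 1))
    raw = s2 - mean_var + cov_term
    tau2_hat = max(0.0, raw)
    prior = PriorEstimate(
        mu_hat=mu_hat, tau2_hat=tau2_hat, k=k, truncated=raw < 0
    )
    if warn:
        if prior.truncated:
            warnings.warn(
                "prior variance estimate truncated at 0; prediction intervals "
                "will have zero width",
                DegeneratePriorWarning,
                stacklevel=2,
            )
        elif tau2_hat > 0:
            needed = minimum_panel_size(mean_var / tau2_hat)
            if k < needed:
                warnings.warn(
                    f"panel size {k} is below the recommended minimum of "
                    f"{needed} for mean(se^2)/tau2 = {mean_var / tau2_hat:.3g}; "
                    "prediction intervals may under-cover",
                    SmallPanelWarning,
                    stacklevel=2,
                )
    return prior


def compute_posterior(panel: EffectPanel, prior: PriorEstimate) -> PosteriorPanel:
    """Precision-weighted shrinkage of each estimate toward the prior mean.

    post_var_i = (1/tau2 + 1/se_i^2)^-1 and
    post_mean_i = post_var_i * (mu/tau2 + beta_i/se_i^2).

    The tau2 = 0 limit gives complete shrinkage (post_mean = mu,
    post_var = 0); tau2 -> inf leaves the estimates untouched.
    """
    var = panel.var
    tau2 = prior.tau2_hat
    if tau2 == 0.0:
        post_mean = np.full(panel.k, prior.mu_hat)
        post_var = np.zeros(panel.k)
    else:
        post_var = 1.0 / (1.0 / tau2 + 1.0 / var)
        post_mean = post_var * (prior.mu_hat / tau2 + panel.beta / var)
    return PosteriorPanel(
        post_mean=post_mean, post_var=post_var, prior=prior, labels=panel.labels
    )


def _z(level: float) -> float:
    if not (0 < level < 1):
        raise DataError(f"level must be in (0, 1), got {level}")
    return float(norm.ppf((1 + level) / 2))


def prediction_intervals(post: PosteriorPanel, level: float = 0.95) -> IntervalSet:
    """Empirical-Bayes prediction intervals post_mean +/- z * sqrt(post_var)."""
    z = _z(level)
    half = z * np.sqrt(post.post_var)
    return IntervalSet(
        lower=post.post_mean - half,
        upper=post.post_mean + half,
        level=level,
        kind="PI",
        labels=post.labels,
    )


def confidence_intervals(panel: EffectPanel, level: float = 0.95) -> IntervalSet:
    """Classical Wald intervals beta_i +/- z * se_i."""
    z = _z(level)
    half = z * panel.se
    return IntervalSet(
        lower=panel.beta - half,
        upper=panel.beta + half,
        level=level,
        kind="CI",
        labels=panel.labels,
    )


def efficiency_gain(
    panel: EffectPanel, prior: PriorEstimate
) -> tuple[np.ndarray, float]:
    """Per-factor and average variance reduction of PIs relative to CIs.

    gain_i = se_i^2 / tau2, so that se_i^2 / post_var_i = 1 + gain_i.
    Returned as ratios (multiply by 100 for percent).
    """
    if prior.tau2_hat == 0.0:
        warnings.warn(
            "tau2_hat is 0: efficiency gain is unbounded",
            DegeneratePriorWarning,
            stacklevel=2,
        )
        gains = np.full(panel.k, np.inf)
        return gains, float("inf")
    gains = panel.var / prior.tau2_hat
    return gains, float(gains.mean())


def expected_coverage_count(intervals: IntervalSet, subset=None) -> float:
    """Expected number of true values inside a set of prediction intervals.

    ``level x (subset size)``; ``subset`` is a boolean mask or index
    array, defaulting to the whole set.  Only meaningful for PIs.
    """
    if intervals.kind != "PI":
        raise DataError("expected coverage counts apply to prediction intervals")
    if subset is None:
        n = intervals.lower.size
    else:
        subset = np.asarray(subset)
        n = int(subset.sum()) if subset.dtype == bool else subset.size
    return intervals.level * n


def minimum_panel_size(ratio: float) -> int:
    """Smallest panel size for nominal PI coverage, given mean(se^2)/tau2.

    Conservative step function over the grid {0.125, 0.25, 0.5}: larger
    noise-to-signal ratios need larger panels, 100+ beyond ratio 0.5.
    """
    if ratio <= 0:
        raise DataError(f"variance ratio must be positive, got {ratio}")
    if ratio <= 0.125:
        return 20
    if ratio <= 0.25:
        return 30
    if ratio <= 0.5:
        return 50
    return 100
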