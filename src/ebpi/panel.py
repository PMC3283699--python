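"""Effect panels: point estimates, standard errors and their covariance.

An :class:`EffectPanel` is the common currency between the estimation
front end (2x2 tables, per-variant logistic fits) and the shrinkage
machinery.  Everything is on the log odds ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

_COV_DIAG_TOL = 1e-10


@dataclass
class EffectPanel:
    """A panel of K exchangeable effect estimates.

    Parameters
    ----------
    labels
        Opaque per-factor identifiers; order is preserved everywhere.
    beta
        Point estimates (log odds ratios), shape (K,).
    se
        Standard errors of ``beta``, strictly positive, shape (K,).
    cov
        Optional K x K covariance matrix of the estimates.  Must be
        symmetric with diagonal equal to ``se**2`` (tolerance 1e-10).
        Absent covariance means independence is assumed downstream.
    """

    labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.beta.ndim != 1 or self.se.shape != self.beta.shape:
            raise DataError("beta and se must be 1-d arrays of equal length")
        if len(self.labels) != self.beta.size:
            raise DataError(
                f"{len(self.labels)} labels for {self.beta.size} estimates"
            )
        if not np.all(np.isfinite(self.beta)) or not np.all(np.isfinite(self.se)):
            raise DataError("beta and se must be finite")
        if np.any(self.se <= 0):
            bad = [self.labels[i] for i in np.flatnonzero(self.se <= 0)]
            raise DataError(f"non-positive standard errors for: {bad}")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            k = self.beta.size
            if self.cov.shape != (k, k):
                raise DataError(
                    f"covariance shape {self.cov.shape} does not match panel size {k}"
                )
            if not np.allclose(self.cov, self.cov.T, atol=_COV_DIAG_TOL):
                raise DataError("covariance matrix is not symmetric")
            if not np.allclose(np.diag(self.cov), self.se**2, atol=_COV_DIAG_TOL):
                raise DataError("covariance diagonal does not equal se**2")

    @property
    def k(self) -> int:
        return self.beta.size

    @property
    def var(self) -> np.ndarray:
        """Sampling variances se**2."""
        return self.se**2
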