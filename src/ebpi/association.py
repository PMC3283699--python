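"""Effect estimation from raw data: 2x2 tables, genotype panels, LD.

Produces :class:`~ebpi.panel.EffectPanel` inputs for the shrinkage
machinery.  Includes the variant filters (control minor allele frequency
and Hardy-Weinberg exact test) used when screening SNP panels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import DataError, EBPIWarning, EstimationError, ZeroCellError
from .panel import EffectPanel

__all__ = [
    "TwoByTwoTable",
    "GenotypePanel",
    "crude_logor",
    "fit_variant_logor",
    "fit_panel",
    "pairwise_pearson",
    "approx_covariance",
    "filter_variants",
    "hwe_exact_test",
]

# IRLS contract for the per-variant logistic fits
_IRLS_TOL = 1e-10
_IRLS_MAXITER = 100
_SEPARATION_BETA = 15.0  # |beta| beyond this flags (quasi-)separation


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of a dichotomous exposure-disease cross-classification.

    a: exposed cases, b: exposed controls, c: unexposed cases,
    d: unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DataError(f"cell {name} must be a nonnegative integer, got {v}")


def crude_logor(table: TwoByTwoTable, continuity: bool = False) -> tuple[float, float]:
    """Crude log odds ratio and its large-sample standard error.

    Returns ``ln(ad/bc)`` and ``sqrt(1/a + 1/b + 1/c + 1/d)``.

    Any zero cell is a :class:`ZeroCellError` unless ``continuity`` is
    set, in which case the Haldane-Anscombe correction (add 0.5 to every
    cell of a table containing a zero) is applied.
    """
    cells = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    zeros = [name for name, v in cells.items() if v == 0]
    if zeros:
        if not continuity:
            raise ZeroCellError(
                f"zero cell(s) {zeros} make the crude logOR undefined; "
                "pass continuity=True for the Haldane-Anscombe correction"
            )
        cells = {name: v + 0.5 for name, v in cells.items()}
    a, b, c, d = cells["a"], cells["b"], cells["c"], cells["d"]
    beta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return beta, se


@dataclass
class GenotypePanel:
    """Individuals x variants allele-count matrix with a binary phenotype.

    Genotypes are copies of the coded allele (0, 1 or 2); NaN marks a
    missing call.  Phenotype is 1 for cases and 0 for controls.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    labels: list[str]
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        if self.genotypes.ndim != 2:
            raise DataError("genotype matrix must be 2-d (individuals x variants)")
        n, k = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise DataError("phenotype length does not match number of individuals")
        if len(self.labels) != k:
            raise DataError("variant labels do not match number of columns")
        if not np.isin(self.phenotype, [0, 1]).all():
            raise DataError("phenotype must be coded 0 (control) / 1 (case)")
        if self.phenotype.sum() == 0 or self.phenotype.sum() == n:
            raise DataError("phenotype needs at least one case and one control")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if not np.isin(obs, [0.0, 1.0, 2.0]).all():
            raise DataError("genotypes must be 0, 1, 2 or missing (NaN)")
        self.phenotype = self.phenotype.astype(int)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]


def _logistic_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), written stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_variant_logor(panel: GenotypePanel, variant_index: int) -> tuple[float, float]:
    """Single-covariate logistic regression slope for one variant.

    Fits ``logit P(case) = b0 + b1 * allele_count`` by iteratively
    reweighted least squares (Newton scoring) to a relative
    log-likelihood change below 1e-10 or 100 iterations.  Individuals
    with a missing call at this variant are dropped.

    Raises
    ------
    EstimationError
        If the genotype column carries no information (constant), the
        fit does not converge, or |slope| > 15 (separation flag).
    """
    g = panel.genotypes[:, variant_index]
    mask = ~np.isnan(g)
    g = g[mask]
    y = panel.phenotype[mask].astype(float)
    label = panel.labels[variant_index]
    if np.unique(g).size < 2:
        raise EstimationError(f"variant {label!r}: genotype column is constant")
    if np.unique(y).size < 2:
        raise EstimationError(f"variant {label!r}: no case/control contrast left")

    X = np.column_stack([np.ones_like(g), g])
    beta = np.zeros(2)
    ll_old = _logistic_loglik(y, X @ beta)
    converged = False
    for _ in range(_IRLS_MAXITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        # Newton step: (X' W X)^-1 X' (y - p)
        xtwx = X.T @ (X * w[:, None])
        score = X.T @ (y - p)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"variant {label!r}: singular information") from exc
        beta = beta + step
        ll_new = _logistic_loglik(y, X @ beta)
        if abs(ll_new - ll_old) < _IRLS_TOL * (abs(ll_old) + _IRLS_TOL):
            converged = True
            break
        ll_old = ll_new
    if not converged:
        raise EstimationError(f"variant {label!r}: IRLS did not converge")
    if abs(beta[1]) > _SEPARATION_BETA:
        raise EstimationError(
            f"variant {label!r}: |slope| > {_SEPARATION_BETA}, likely separation"
        )
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return float(beta[1]), float(math.sqrt(cov[1, 1]))


def fit_panel(panel: GenotypePanel) -> EffectPanel:
    """Fit every variant; failed fits are excluded with a warning."""
    labels, betas, ses = [], [], []
    for j, label in enumerate(panel.labels):
        try:
            b, s = fit_variant_logor(panel, j)
        except EstimationError as exc:
            warnings.warn(f"excluding {label!r}: {exc}", EBPIWarning, stacklevel=2)
            continue
        labels.append(label)
        betas.append(b)
        ses.append(s)
    if not labels:
        raise DataError("no variant produced a usable estimate")
    return EffectPanel(labels=labels, beta=np.array(betas), se=np.array(ses))


def pairwise_pearson(panel: GenotypePanel) -> np.ndarray:
    """Pairwise Pearson correlations between allele counts (LD matrix).

    Complete-case per pair; a pair with fewer than 3 complete
    observations or zero variance gets correlation 0 with a warning.
    """
    G = panel.genotypes
    k = panel.n_variants
    if k < 2:
        raise DataError("need at least two variants for a correlation matrix")
    r = np.eye(k)
    if not np.isnan(G).any():
        sd = G.std(axis=0)
        ok = sd > 0
        if not ok.all():
            bad = [panel.labels[i] for i in np.flatnonzero(~ok)]
            warnings.warn(
                f"zero-variance variants set to r=0: {bad}", EBPIWarning, stacklevel=2
            )
        if ok.any():
            sub = np.corrcoef(G[:, ok], rowvar=False)
            idx = np.flatnonzero(ok)
            r[np.ix_(idx, idx)] = sub
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            mask = ~np.isnan(G[:, i]) & ~np.isnan(G[:, j])
            if mask.sum() < 3:
                warnings.warn(
                    f"pair ({panel.labels[i]}, {panel.labels[j]}): "
                    "<3 complete observations, r set to 0",
                    EBPIWarning,
                    stacklevel=2,
                )
                continue
            x, yv = G[mask, i], G[mask, j]
            if x.std() == 0 or yv.std() == 0:
                warnings.warn(
                    f"pair ({panel.labels[i]}, {panel.labels[j]}): "
                    "zero variance, r set to 0",
                    EBPIWarning,
                    stacklevel=2,
                )
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(x, yv)[0, 1])
    return np.clip(r, -1.0, 1.0)


def approx_covariance(corr: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Covariance approximation cov_ij = r_ij * se_i * se_j."""
    corr = np.asarray(corr, dtype=float)
    se = np.asarray(se, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise DataError("correlation matrix must be square")
    if se.shape != (corr.shape[0],):
        raise DataError(
            f"se length {se.shape} does not match correlation dimension {corr.shape}"
        )
    if np.any(se <= 0):
        raise DataError("standard errors must be strictly positive")
    if not np.allclose(corr, corr.T, atol=1e-8) or not np.allclose(
        np.diag(corr), 1.0, atol=1e-8
    ):
        raise DataError("correlation matrix must be symmetric with unit diagonal")
    cov = corr * np.outer(se, se)
    # exact diagonal regardless of float noise in corr's diagonal
    np.fill_diagonal(cov, se**2)
    return cov


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count and sums the probabilities of all configurations
    no more probable than the observed one.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise DataError(f"genotype counts must be nonnegative integers, got {counts}")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("total genotype count must be positive")
    n_a = 2 * n_aa + n_Aa  # copies of the a allele
    rare = min(n_a, 2 * n - n_a)

    hets = np.arange(rare % 2, rare + 1, 2)
    # P(het | n, allele counts) up to a constant:
    #   n! 2^het / (hom_r! het! hom_c!) with hom_r = (rare-het)/2
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = hets * math.log(2.0) - (
        gammaln(hom_r + 1) + gammaln(hets + 1) + gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_Aa
    p_obs = probs[hets == obs][0]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


@dataclass
class FilterReport:
    """Per-variant exclusion reasons keyed by label ('maf' or 'hwe')."""

    excluded: dict[str, str] = field(default_factory=dict)


def filter_variants(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    hwe_p_min: float = 0.05,
) -> tuple[GenotypePanel, FilterReport]:
    """Keep variants with control MAF >= maf_min and HWE exact p >= hwe_p_min.

    Both criteria are evaluated in controls only, complete-case per
    variant.  Returns the filtered panel and a report of exclusions.
    """
    if not (0 <= maf_min < 0.5):
        raise DataError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if not (0 <= hwe_p_min <= 1):
        raise DataError(f"hwe_p_min must be in [0, 1], got {hwe_p_min}")
    controls = panel.genotypes[panel.phenotype == 0]
    report = FilterReport()
    keep = []
    for j, label in enumerate(panel.labels):
        g = controls[:, j]
        g = g[~np.isnan(g)]
        if g.size == 0:
            report.excluded[label] = "maf"
            continue
        n2 = int((g == 2).sum())
        n1 = int((g == 1).sum())
        n0 = int((g == 0).sum())
        freq = (2 * n2 + n1) / (2 * g.size)
        maf = min(freq, 1 - freq)
        if maf < maf_min:
            report.excluded[label] = "maf"
            continue
        if hwe_exact_test(n0, n1, n2) < hwe_p_min:
            report.excluded[label] = "hwe"
            continue
        keep.append(j)
    if not keep:
        raise DataError("no variants survive the MAF/HWE filters")
    filtered = GenotypePanel(
        genotypes=panel.genotypes[:, keep],
        phenotype=panel.phenotype,
        labels=[panel.labels[j] for j in keep],
        individual_ids=panel.individual_ids,
    )
    return filtered, report
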