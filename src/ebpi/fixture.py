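"""Synthetic genotype/phenotype fixtures.

Stand-in data for exercising the fit -> estimate workflow at arbitrary
dimensions: genotypes drawn under Hardy-Weinberg equilibrium at random
per-variant minor allele frequencies, optional block-correlated (LD-like)
structure via a Gaussian copula on haplotypes, and case/control status
from an additive logistic model.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .association import GenotypePanel
from .errors import DataError
from .simulate import draw_true_effects

__all__ = ["make_fixture"]


def _block_correlation(k: int, block_size: int, rho: float) -> np.ndarray:
    """Block-diagonal exchangeable correlation (rho within blocks)."""
    r = np.eye(k)
    for start in range(0, k, block_size):
        stop = min(start + block_size, k)
        r[start:stop, start:stop] = rho
    np.fill_diagonal(r, 1.0)
    return r


def make_fixture(
    n_cases: int,
    n_controls: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    effect_dist: str = "normal",
    tau2: float = 0.0,
    block_size: int = 1,
    block_corr: float = 0.0,
    seed: int = 0,
) -> GenotypePanel:
    """Generate a case/control genotype panel.

    Each individual receives two haplotypes; within a haplotype, latent
    standard normals with the block correlation structure are
    thresholded at the per-variant MAF quantile, so marginal genotype
    frequencies follow HWE at the requested MAFs.  Disease status comes
    from ``logit P(case) = b0 + sum_j beta_j (g_j - 2 maf_j)`` with
    effects drawn as in the simulation study (``tau2 = 0`` means no
    association), and individuals are sampled until the case and
    control quotas are both filled.
    """
    if min(n_cases, n_controls, n_variants) < 1:
        raise DataError("fixture dimensions must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise DataError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    beta = draw_true_effects(n_variants, tau2, effect_dist, rng)
    thresh = norm.ppf(mafs)
    if block_size > 1 and block_corr != 0.0:
        chol = np.linalg.cholesky(
            _block_correlation(n_variants, block_size, block_corr)
        )
    else:
        chol = None
    b0 = np.log(n_cases / n_controls)  # target prevalence in the sampling pool

    n_total = n_cases + n_controls
    geno = np.empty((n_total, n_variants))
    pheno = np.empty(n_total, dtype=int)
    filled_cases = filled_controls = 0
    batch = max(256, n_total)
    while filled_cases < n_cases or filled_controls < n_controls:
        z = rng.standard_normal((2 * batch, n_variants))
        if chol is not None:
            z = z @ chol.T
        alleles = (z < thresh).astype(float)
        g = alleles[:batch] + alleles[batch:]
        eta = b0 + (g - 2 * mafs) @ beta
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        for i in range(batch):
            if y[i] and filled_cases < n_cases:
                geno[filled_cases + filled_controls] = g[i]
                pheno[filled_cases + filled_controls] = 1
                filled_cases += 1
            elif not y[i] and filled_controls < n_controls:
                geno[filled_cases + filled_controls] = g[i]
                pheno[filled_cases + filled_controls] = 0
                filled_controls += 1
            if filled_cases == n_cases and filled_controls == n_controls:
                break
    order = rng.permutation(n_total)
    return GenotypePanel(
        genotypes=geno[order],
        phenotype=pheno[order],
        labels=[f"snp{j + 1}" for j in range(n_variants)],
        individual_ids=[f"ind{i + 1}" for i in range(n_total)],
    )
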