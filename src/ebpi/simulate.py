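"""Coverage simulation study for the EB prediction-interval procedure.

Generates panels of true log odds ratios, adds (possibly correlated)
estimation noise, runs the full estimate-prior / posterior / interval
pipeline per replicate, and tabulates coverage and efficiency over a
grid of scenarios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eb import (
    PriorEstimate,
    compute_posterior,
    confidence_intervals,
    estimate_prior,
    prediction_intervals,
)
from .errors import DataError
from .panel import EffectPanel

__all__ = [
    "ScenarioConfig",
    "CoverageResult",
    "draw_true_effects",
    "draw_correlation_matrix",
    "simulate_panel",
    "run_scenario",
    "scenario_grid",
    "plot_grid",
]

CORRELATION_REGIMES = ("independent", "moderate", "strong")
EFFECT_DISTS = ("normal", "mixture")

# pairwise-correlation blocks: (share drawn negative, negative lower
# bound, positive upper bound); the negative bound mirrors the positive
# one since the printed lower limit is ambiguous in the source material.
_REGIME_BOUNDS = {"moderate": (1 / 3, -0.4, 0.4), "strong": (1 / 3, -0.8, 0.8)}

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    sigma2_mean m is realized per factor as sigma_i^2 ~ U[0.5 m, 1.5 m]
    (the same +/-50% relative spread for every m).
    """

    k: int
    tau2: float
    sigma2_mean: float
    correlation: str = "independent"
    effect_dist: str = "normal"
    reps: int = 10_000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DataError(f"panel size must be >= 2, got {self.k}")
        if self.reps < 1:
            raise DataError(f"reps must be >= 1, got {self.reps}")
        if not (0 < self.level < 1):
            raise DataError(f"level must be in (0, 1), got {self.level}")
        if self.tau2 < 0 or self.sigma2_mean < 0:
            raise DataError("variances must be nonnegative")
        if self.correlation not in CORRELATION_REGIMES:
            raise DataError(
                f"correlation must be one of {CORRELATION_REGIMES}, "
                f"got {self.correlation!r}"
            )
        if self.effect_dist not in EFFECT_DISTS:
            raise DataError(
                f"effect_dist must be one of {EFFECT_DISTS}, got {self.effect_dist!r}"
            )


@dataclass(frozen=True)
class CoverageResult:
    """Monte-Carlo summary of one scenario."""

    config: ScenarioConfig
    coverage_pi: float
    coverage_pi_se: float
    coverage_ci: float
    coverage_ci_se: float
    coverage_pi_sig: float
    coverage_pi_sig_se: float
    coverage_ci_sig: float
    coverage_ci_sig_se: float
    avg_len_pi: float
    avg_len_ci: float
    avg_gain: float
    n_sig_pi: int
    n_sig_ci: int
    n_truncated: int


# --- draws -----------------------------------------------------------------

# beta(2, 5) moments, used to standardize the mixture component
_BETA_A, _BETA_B = 2.0, 5.0
_BETA_MEAN = _BETA_A / (_BETA_A + _BETA_B)
_BETA_SD = math.sqrt(
    _BETA_A * _BETA_B / ((_BETA_A + _BETA_B) ** 2 * (_BETA_A + _BETA_B + 1))
)
_UNIF_SD = math.sqrt(1.0 / 12.0)
_MIX_WEIGHTS = (0.4, 0.2, 0.4)  # beta / uniform / normal


def draw_true_effects(
    k: int, tau2: float, effect_dist: str, rng: np.random.Generator
) -> np.ndarray:
    """True log odds ratios: mean 0, variance tau2.

    "normal" is N(0, tau2).  "mixture" draws 40% from a beta(2,5), 20%
    from a uniform and 40% from a normal, each component standardized to
    mean 0 and unit variance before scaling by sqrt(tau2); the mixture
    is deliberately far from normal while matching the first two
    moments.
    """
    if effect_dist not in EFFECT_DISTS:
        raise DataError(f"unknown effect_dist {effect_dist!r}")
    if tau2 == 0:
        return np.zeros(k)
    if effect_dist == "normal":
        return rng.normal(0.0, math.sqrt(tau2), size=k)
    comp = rng.choice(3, size=k, p=_MIX_WEIGHTS)
    out = np.empty(k)
    nb = int((comp == 0).sum())
    nu = int((comp == 1).sum())
    nn = k - nb - nu
    out[comp == 0] = (rng.beta(_BETA_A, _BETA_B, size=nb) - _BETA_MEAN) / _BETA_SD
    out[comp == 1] = (rng.uniform(0.0, 1.0, size=nu) - 0.5) / _UNIF_SD
    out[comp == 2] = rng.normal(0.0, 1.0, size=nn)
    return out * math.sqrt(tau2)


def _proj_psd(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(a)
    return (v * np.clip(w, 0.0, None)) @ v.T


def nearest_correlation(
    r: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the nearest
    (Frobenius) positive semidefinite correlation matrix.

    Higham-style alternating projections (PSD cone vs unit diagonal)
    with Dykstra's correction; a matrix that is already PSD is returned
    unchanged.  The final iterate is re-projected onto the PSD cone and
    diagonally rescaled, so the output is PSD to machine precision with
    an exactly unit diagonal.
    """
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() >= -_PSD_TOL:
        return r
    y = r.copy()
    ds = np.zeros_like(r)
    for _ in range(max_iter):
        r_k = y - ds
        x = _proj_psd(r_k)
        ds = x - r_k
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        if np.abs(y_new - y).max() < tol:
            y = y_new
            break
        y = y_new
    x = _proj_psd((y + y.T) / 2.0)
    d = np.sqrt(np.clip(np.diag(x), 1e-12, None))
    x = x / np.outer(d, d)  # PSD-preserving renormalization to unit diagonal
    np.fill_diagonal(x, 1.0)
    return (x + x.T) / 2.0


def draw_correlation_matrix(
    k: int, regime: str, rng: np.random.Generator
) -> np.ndarray:
    """Random correlation matrix for a given regime.

    "independent" is the identity.  Otherwise each pairwise entry is
    drawn from U[neg_lo, 0] with probability 1/3 and from U[0, pos_hi]
    otherwise, then the matrix is repaired to the nearest PSD
    correlation matrix.
    """
    if regime == "independent":
        return np.eye(k)
    try:
        p_neg, neg_lo, pos_hi = _REGIME_BOUNDS[regime]
    except KeyError:
        raise DataError(
            f"correlation regime must be one of {CORRELATION_REGIMES}, got {regime!r}"
        ) from None
    n_pairs = k * (k - 1) // 2
    neg = rng.random(n_pairs) < p_neg
    vals = np.where(
        neg,
        rng.uniform(neg_lo, 0.0, size=n_pairs),
        rng.uniform(0.0, pos_hi, size=n_pairs),
    )
    r = np.eye(k)
    iu = np.triu_indices(k, 1)
    r[iu] = vals
    r[(iu[1], iu[0])] = vals
    return nearest_correlation(r)


def _noise_factor(r: np.ndarray) -> np.ndarray:
    """Matrix square root of a (possibly semidefinite) correlation matrix."""
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(r)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_panel(
    config: ScenarioConfig,
    rng: np.random.Generator,
    correlation: np.ndarray | None = None,
    sigma2: np.ndarray | None = None,
) -> tuple[np.ndarray, EffectPanel]:
    """One synthetic panel: true effects and their noisy estimates.

    sigma_i^2 ~ U[0.5 m, 1.5 m]; noise is multivariate normal with
    covariance D R D (D = diag(sigma_i)); the panel carries the true
    covariance.  ``correlation`` and ``sigma2`` may be supplied to pin
    them across replicates (used by diagnostics/tests).
    """
    k = config.k
    beta_true = draw_true_effects(k, config.tau2, config.effect_dist, rng)
    if sigma2 is None:
        m = config.sigma2_mean
        sigma2 = rng.uniform(0.5 * m, 1.5 * m, size=k)
    sigma = np.sqrt(sigma2)
    corr_supplied = correlation is not None
    if not corr_supplied:
        correlation = draw_correlation_matrix(k, config.correlation, rng)
    z = rng.standard_normal(k)
    if config.correlation == "independent" and not corr_supplied:
        e = sigma * z
        cov = np.diag(sigma2)
    else:
        L = _noise_factor(correlation)
        e = sigma * (L @ z)
        cov = correlation * np.outer(sigma, sigma)
        np.fill_diagonal(cov, sigma2)
    beta_hat = beta_true + e
    panel = EffectPanel(
        labels=[f"f{i + 1}" for i in range(k)],
        beta=beta_hat,
        se=sigma,
        cov=cov,
    )
    return beta_true, panel


def _ratio_se(x: np.ndarray, n: np.ndarray) -> float:
    """Monte-Carlo standard error of sum(x)/sum(n) over replicates."""
    total = n.sum()
    if total == 0:
        return float("nan")
    r = x.sum() / total
    return float(math.sqrt(np.sum((x - r * n) ** 2)) / total)


def run_scenario(config: ScenarioConfig, oracle: bool = False) -> CoverageResult:
    """Monte-Carlo coverage of PIs and CIs under one scenario.

    Per replicate: simulate a panel, estimate the prior (or, in
    ``oracle`` mode, use the true mu = 0 and tau2), build posterior
    PIs and Wald CIs, and record whether each true effect falls in its
    interval — overall and within the significant (zero-excluding)
    subsets.  Replicates whose prior variance estimate truncates to zero
    are retained; their zero-width PIs count as non-covering unless the
    true value equals the prior mean exactly.
    """
    reps, k = config.reps, config.k
    streams = np.random.SeedSequence(config.seed).spawn(reps)

    pi_cover = np.empty(reps)
    ci_cover = np.empty(reps)
    pi_sig_n = np.zeros(reps)
    pi_sig_cov = np.zeros(reps)
    ci_sig_n = np.zeros(reps)
    ci_sig_cov = np.zeros(reps)
    len_pi = np.empty(reps)
    len_ci = np.empty(reps)
    gains = []
    n_truncated = 0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(reps):
            rng = np.random.default_rng(streams[r])
            beta_true, panel = simulate_panel(config, rng)
            if oracle:
                prior = PriorEstimate(mu_hat=0.0, tau2_hat=config.tau2, k=k)
            else:
                prior = estimate_prior(panel, warn=False)
            if prior.tau2_hat == 0.0 and not oracle:
                n_truncated += 1
            post = compute_posterior(panel, prior)
            pis = prediction_intervals(post, config.level)
            cis = confidence_intervals(panel, config.level)

            in_pi = (pis.lower <= beta_true) & (beta_true <= pis.upper)
            in_ci = (cis.lower <= beta_true) & (beta_true <= cis.upper)
            pi_cover[r] = in_pi.mean()
            ci_cover[r] = in_ci.mean()
            sig_pi = pis.significant
            sig_ci = cis.significant
            pi_sig_n[r] = sig_pi.sum()
            pi_sig_cov[r] = in_pi[sig_pi].sum()
            ci_sig_n[r] = sig_ci.sum()
            ci_sig_cov[r] = in_ci[sig_ci].sum()
            len_pi[r] = pis.length.mean()
            len_ci[r] = cis.length.mean()
            if prior.tau2_hat > 0:
                gains.append(panel.var.mean() / prior.tau2_hat)

    sqrt_reps = math.sqrt(reps)
    return CoverageResult(
        config=config,
        coverage_pi=float(pi_cover.mean()),
        coverage_pi_se=float(pi_cover.std(ddof=1) / sqrt_reps) if reps > 1 else 0.0,
        coverage_ci=float(ci_cover.mean()),
        coverage_ci_se=float(ci_cover.std(ddof=1) / sqrt_reps) if reps > 1 else 0.0,
        coverage_pi_sig=float(pi_sig_cov.sum() / pi_sig_n.sum())
        if pi_sig_n.sum() > 0
        else float("nan"),
        coverage_pi_sig_se=_ratio_se(pi_sig_cov, pi_sig_n),
        coverage_ci_sig=float(ci_sig_cov.sum() / ci_sig_n.sum())
        if ci_sig_n.sum() > 0
        else float("nan"),
        coverage_ci_sig_se=_ratio_se(ci_sig_cov, ci_sig_n),
        avg_len_pi=float(len_pi.mean()),
        avg_len_ci=float(len_ci.mean()),
        avg_gain=float(np.mean(gains)) if gains else float("inf"),
        n_sig_pi=int(pi_sig_n.sum()),
        n_sig_ci=int(ci_sig_n.sum()),
        n_truncated=n_truncated,
    )


TAU2_GRID = (1.0, 0.5, 0.25)
SIGMA2_GRID = (0.5, 0.25, 0.125)


def scenario_grid(
    base: ScenarioConfig,
    k_values: tuple[int, ...] = (10, 20, 30, 50, 100),
    tau2_values: tuple[float, ...] = TAU2_GRID,
    sigma2_values: tuple[float, ...] = SIGMA2_GRID,
    regimes: tuple[str, ...] = CORRELATION_REGIMES,
) -> pd.DataFrame:
    """Coverage table over the (tau2, sigma2_mean) grid x regimes x K.

    Long format, one row per scenario; deterministic given the base
    seed (each cell gets a distinct sub-seed derived from it).
    """
    rows = []
    cell = 0
    for tau2 in tau2_values:
        for s2 in sigma2_values:
            for regime in regimes:
                for k in k_values:
                    cfg = replace(
                        base,
                        k=k,
                        tau2=tau2,
                        sigma2_mean=s2,
                        correlation=regime,
                        seed=base.seed * 1_000_003 + cell,
                    )
                    cell += 1
                    res = run_scenario(cfg)
                    rows.append(
                        {
                            "tau2": tau2,
                            "sigma2_mean": s2,
                            "correlation": regime,
                            "effect_dist": cfg.effect_dist,
                            "K": k,
                            "coverage_pi": res.coverage_pi,
                            "coverage_pi_sig": res.coverage_pi_sig,
                            "coverage_ci_sig": res.coverage_ci_sig,
                            "avg_len_pi": res.avg_len_pi,
                            "avg_len_ci": res.avg_len_ci,
                            "gain": res.avg_gain,
                            "mc_se": res.coverage_pi_se,
                        }
                    )
    return pd.DataFrame(rows)


def plot_grid(table: pd.DataFrame, path: str, level: float = 0.95) -> None:
    """Basic 3x3 panel plot of coverage against K, one line per regime."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tau2s = sorted(table["tau2"].unique(), reverse=True)
    s2s = sorted(table["sigma2_mean"].unique(), reverse=True)
    fig, axes = plt.subplots(
        len(tau2s), len(s2s), figsize=(4 * len(s2s), 3 * len(tau2s)), squeeze=False
    )
    styles = {"independent": "-", "moderate": "--", "strong": ":"}
    for i, tau2 in enumerate(tau2s):
        for j, s2 in enumerate(s2s):
            ax = axes[i][j]
            sub = table[(table["tau2"] == tau2) & (table["sigma2_mean"] == s2)]
            for regime, grp in sub.groupby("correlation"):
                grp = grp.sort_values("K")
                ax.plot(
                    grp["K"],
                    grp["coverage_pi"],
                    styles.get(regime, "-"),
                    label=regime,
                )
            ax.axhline(level, color="grey", lw=0.8)
            ax.set_title(f"tau2={tau2}, mean sigma2={s2}", fontsize=9)
            ax.set_xlabel("K")
            ax.set_ylabel("coverage")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
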