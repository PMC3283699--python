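"""TSV readers/writers, scenario config parsing and run manifests.

All tabular formats are UTF-8, tab-separated, headered, '.' decimal.
Floats in result tables are written at 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import GenotypePanel, TwoByTwoTable, crude_logor
from .eb import IntervalSet, PosteriorPanel
from .errors import DataError
from .panel import EffectPanel
from .simulate import CoverageResult, ScenarioConfig

_FLOAT_FMT = "%.6g"


def read_panel(path: str | Path, continuity: bool = False) -> EffectPanel:
    """Read an effect panel: columns ``id, beta, se`` or ``id, a, b, c, d``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse {path}: {exc}") from exc
    cols = list(df.columns)
    if {"id", "beta", "se"}.issubset(cols):
        return EffectPanel(
            labels=[str(x) for x in df["id"]],
            beta=df["beta"].to_numpy(dtype=float),
            se=df["se"].to_numpy(dtype=float),
        )
    if {"id", "a", "b", "c", "d"}.issubset(cols):
        betas, ses = [], []
        for i, row in df.iterrows():
            try:
                t = TwoByTwoTable(int(row.a), int(row.b), int(row.c), int(row.d))
                b, s = crude_logor(t, continuity=continuity)
            except DataError as exc:
                raise DataError(f"{path}, line {i + 2}: {exc}") from exc
            betas.append(b)
            ses.append(s)
        return EffectPanel(
            labels=[str(x) for x in df["id"]],
            beta=np.array(betas),
            se=np.array(ses),
        )
    raise DataError(
        f"{path}: need columns (id, beta, se) or (id, a, b, c, d); got {cols}"
    )


def read_matrix(path: str | Path, labels: list[str] | None = None) -> np.ndarray:
    """Read a square labelled matrix (first row/column are labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise DataError(f"{path}: matrix is not square ({df.shape})")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise DataError(f"{path}: row and column labels differ")
    if labels is not None:
        got = list(df.index.astype(str))
        if got != list(labels):
            raise DataError(
                f"{path}: matrix labels do not match the panel "
                f"(first mismatch at position "
                f"{next(i for i, (x, y) in enumerate(zip(got, labels)) if x != y)})"
            )
    return df.to_numpy(dtype=float)


def write_matrix(m: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(m, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )


def read_genotypes(path: str | Path) -> GenotypePanel:
    """Read a genotype matrix TSV.

    First column: individual ID; second: phenotype (0/1); remaining
    columns: variants with values 0/1/2 or NA.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if df.shape[1] < 3:
        raise DataError(f"{path}: need id, phenotype and >=1 variant column")
    ids = [str(x) for x in df.iloc[:, 0]]
    pheno = df.iloc[:, 1].to_numpy()
    if not np.isin(pheno, [0, 1]).all():
        bad = int(np.flatnonzero(~np.isin(pheno, [0, 1]))[0])
        raise DataError(
            f"{path}, line {bad + 2}: phenotype must be 0 or 1, got {pheno[bad]!r}"
        )
    geno = df.iloc[:, 2:].to_numpy(dtype=float)
    obs = geno[~np.isnan(geno)]
    if not np.isin(obs, [0.0, 1.0, 2.0]).all():
        rows = np.where(~(np.isnan(geno) | np.isin(geno, [0.0, 1.0, 2.0])))[0]
        raise DataError(
            f"{path}, line {int(rows[0]) + 2}: genotypes must be 0/1/2/NA"
        )
    return GenotypePanel(
        genotypes=geno,
        phenotype=pheno.astype(int),
        labels=[str(c) for c in df.columns[2:]],
        individual_ids=ids,
    )


def write_genotypes(panel: GenotypePanel, path: str | Path) -> None:
    ids = panel.individual_ids or [f"ind{i + 1}" for i in range(panel.n_individuals)]
    df = pd.DataFrame(panel.genotypes, columns=panel.labels)
    df = df.astype("Int64")  # keeps 0/1/2 integral, NaN -> <NA>
    df.insert(0, "phenotype", panel.phenotype)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_results(
    panel: EffectPanel,
    post: PosteriorPanel,
    cis: IntervalSet,
    pis: IntervalSet,
    gains: np.ndarray,
    path: str | Path,
    or_scale: bool = False,
) -> None:
    """Per-factor results table (logOR scale; OR columns optional)."""
    df = pd.DataFrame(
        {
            "id": panel.labels,
            "beta": panel.beta,
            "se": panel.se,
            "ci_low": cis.lower,
            "ci_high": cis.upper,
            "post_mean": post.post_mean,
            "post_var": post.post_var,
            "pi_low": pis.lower,
            "pi_high": pis.upper,
            "gain": gains,
            "significant": pis.significant,
        }
    )
    if or_scale:
        df["or"] = np.exp(panel.beta)
        df["pi_low_or"] = np.exp(pis.lower)
        df["pi_high_or"] = np.exp(pis.upper)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_coverage_table(results: list[CoverageResult], path: str | Path) -> None:
    rows = [
        {
            "tau2": r.config.tau2,
            "sigma2_mean": r.config.sigma2_mean,
            "correlation": r.config.correlation,
            "effect_dist": r.config.effect_dist,
            "K": r.config.k,
            "coverage_pi": r.coverage_pi,
            "coverage_pi_sig": r.coverage_pi_sig,
            "coverage_ci_sig": r.coverage_ci_sig,
            "avg_len_pi": r.avg_len_pi,
            "avg_len_ci": r.avg_len_ci,
            "gain": r.avg_gain,
            "mc_se": r.coverage_pi_se,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_scenario_config(path: str | Path) -> ScenarioConfig:
    """Parse a flat TOML scenario file into a ScenarioConfig."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    known = {
        "K": "k",
        "k": "k",
        "tau2": "tau2",
        "sigma2_mean": "sigma2_mean",
        "correlation": "correlation",
        "effect_dist": "effect_dist",
        "reps": "reps",
        "level": "level",
        "seed": "seed",
    }
    kwargs = {}
    for key, val in raw.items():
        if key not in known:
            raise DataError(
                f"{path}: unknown scenario key {key!r}; allowed: "
                f"{sorted(set(known))}"
            )
        kwargs[known[key]] = val
    if "k" not in kwargs:
        raise DataError(f"{path}: scenario must set K")
    return ScenarioConfig(**kwargs)


# --- manifest ---------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    version: str
    inputs: dict[str, str]
    timestamp: str
    warnings: list[str]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None = None,
    inputs: list[str | Path] = (),
    warning_messages: list[str] = (),
) -> Path:
    """Write the single run manifest for an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config=config,
        seed=seed,
        version=__version__,
        inputs={str(p): _sha256(Path(p)) for p in inputs},
        timestamp=datetime.now(timezone.utc).isoformat(),
        warnings=list(warning_messages),
    )
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2)
        fh.write("\n")
    return path
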