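"""Genome-wide gene x exposure interaction scan.

Orchestrates the per-gene mixed-effects test over a set of expression
weight models and exposures, applying per-exposure eligibility and
complete-case rules, per-exposure Benjamini-Hochberg FDR adjustment,
a genes-x-exposures Bonferroni threshold, and genomic-inflation
diagnostics (lambda_GC and QQ coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateInputError,
    EmptyInputError,
    EmptyOverlapError,
    MistiError,
    ParameterError,
)
from .gxe import DEFAULT_GRID, misti_gene_test
from .io_formats import (
    GenotypeMatrix,
    GxEResult,
    PhenotypeTable,
    harmonize_alleles,
    results_to_frame,
)

DEFAULT_COVARIATES = ("age", "pc1", "pc2", "pc3", "pc4", "pc5")


@dataclass(frozen=True)
class ExposureSpec:
    """Analysis-side description of one exposure column."""

    name: str
    kind: str = "continuous"  # continuous | binary | ordinal
    scale: float = 1.0
    eligibility: str = "all"
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError(f"exposure {self.name}: scale must be > 0")


@dataclass(frozen=True)
class ScanConfig:
    alpha: float = 0.05
    fdr: float = 0.2
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    grid: tuple[float, ...] = DEFAULT_GRID
    seed: int = 0


@dataclass
class ResultsTable:
    """Scan output: one row per tested gene x exposure, plus metadata."""

    df: pd.DataFrame
    metadata: dict
    warnings: list[str] = field(default_factory=list)


def bonferroni_threshold(n_genes: int, n_exposures: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_genes * n_exposures)."""
    if n_genes < 1 or n_exposures < 1:
        raise ParameterError("n_genes and n_exposures must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    return alpha / (n_genes * n_exposures)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value list")
    if (p <= 0).any() or (p > 1).any() or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class InflationResult:
    lambda_gc: float
    qq: pd.DataFrame  # columns: expected_neglog10, observed_neglog10


def genomic_inflation(pvalues: Sequence[float]) -> InflationResult:
    """Genomic inflation factor and QQ coordinates.

    lambda_GC = median of the chi^2_1 quantile transform of the
    p-values divided by the chi^2_1 median (0.4549...)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 10:
        raise DegenerateInputError("need at least 10 p-values for inflation diagnostics")
    if (p <= 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    order = np.sort(p)
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(order)
    qq = pd.DataFrame({"expected_neglog10": expected, "observed_neglog10": observed})
    return InflationResult(lambda_gc=lam, qq=qq)


def _design_for_exposure(
    pheno: pd.DataFrame, covariates: Sequence[str], extra: Sequence[str]
) -> np.ndarray:
    """Intercept + study dummies (reference level dropped) + numeric
    covariates + any exposure-specific extra covariates."""
    n = len(pheno)
    cols = [np.ones(n)]
    studies = sorted(pheno["study"].astype(str).unique())
    for s in studies[1:]:
        cols.append((pheno["study"].astype(str) == s).to_numpy(dtype=float))
    for c in list(covariates) + list(extra):
        if c not in pheno.columns:
            raise ParameterError(f"covariate column '{c}' missing from phenotype table")
        cols.append(pheno[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _eligible_mask(pheno: pd.DataFrame, spec: ExposureSpec) -> np.ndarray:
    if spec.eligibility == "all":
        mask = np.ones(len(pheno), dtype=bool)
    elif spec.eligibility == "parous_only":
        mask = pheno["parous"].to_numpy() == 1
    elif spec.eligibility == "premenopausal_only":
        mask = pheno["postmenopausal"].to_numpy() == 0
    elif spec.eligibility == "postmenopausal_only":
        mask = pheno["postmenopausal"].to_numpy() == 1
    else:
        raise ParameterError(f"unknown eligibility rule '{spec.eligibility}'")
    return mask & pheno[spec.name].notna().to_numpy()


def run_scan(
    models: Sequence,
    cohort_genos: GenotypeMatrix,
    pheno: PhenotypeTable,
    exposures: Sequence[ExposureSpec],
    config: ScanConfig = ScanConfig(),
) -> ResultsTable:
    """Scan every weight model against every exposure.

    Per exposure: restrict to eligible samples with a non-missing
    exposure value, assemble the covariate design, harmonize each
    gene's weights to the cohort genotypes (genes without any surviving
    nonzero-weight variant are skipped), run the mixed-effects test and
    attach per-exposure BH-adjusted p-values.  Bonferroni calls use the
    genes x exposures family.
    """
    if not models or not exposures:
        raise ParameterError("need at least one model and one exposure")
    results: list[GxEResult] = []
    warnings: list[str] = []
    df_pheno = pheno.df
    for spec in exposures:
        if spec.name not in df_pheno.columns:
            warnings.append(f"exposure '{spec.name}' missing from phenotype table; skipped")
            continue
        mask = _eligible_mask(df_pheno, spec)
        if mask.sum() == 0:
            warnings.append(f"exposure '{spec.name}': empty eligible stratum; skipped")
            continue
        sub = df_pheno.loc[mask].reset_index(drop=True)
        X = _design_for_exposure(sub, config.covariates, spec.extra_covariates)
        E = sub[spec.name].to_numpy(dtype=float)
        y = sub["case_status"].to_numpy(dtype=float)
        sample_idx = np.flatnonzero(mask)
        exposure_results: list[GxEResult] = []
        for model in models:
            gene_weights = model.to_gene_weights() if hasattr(model, "to_gene_weights") else model
            try:
                w, aligned, _rep = harmonize_alleles(gene_weights, cohort_genos)
            except EmptyOverlapError:
                warnings.append(f"gene '{gene_weights.gene_id}': no overlapping variants; skipped")
                continue
            nz = np.flatnonzero(w != 0)
            if nz.size == 0:
                warnings.append(f"gene '{gene_weights.gene_id}': no nonzero-weight variant survives; skipped")
                continue
            G = aligned.dosages[sample_idx][:, nz]
            try:
                rec = misti_gene_test(
                    _ModelView(gene_weights.gene_id, gene_weights.chrom, w[nz]),
                    G, E, X, y, grid=config.grid,
                )
            except MistiError as exc:
                warnings.append(f"gene '{gene_weights.gene_id}' x '{spec.name}': {exc}")
                continue
            rec.exposure = spec.name
            exposure_results.append(rec)
        if exposure_results:
            adj = bh_adjust([r.p_amisti for r in exposure_results])
            for r, a in zip(exposure_results, adj):
                r.fdr_adjusted = float(a)
        results.extend(exposure_results)
    if not results:
        raise EmptyInputError("scan produced no results")
    df = results_to_frame(results)
    threshold = bonferroni_threshold(len(models), len(exposures), config.alpha)
    df["significant_bonferroni"] = df["p_amisti"] < threshold
    df["suggestive_fdr"] = df["fdr_adjusted"] < config.fdr
    metadata = {
        "n_genes": len(models),
        "n_exposures": len(exposures),
        "n_tests": int(len(df)),
        "alpha": config.alpha,
        "bonferroni_threshold": threshold,
        "fdr_flag_threshold": config.fdr,
        "seed": int(config.seed),
        "grid": [float(g) for g in config.grid],
    }
    return ResultsTable(df=df, metadata=metadata, warnings=warnings)


@dataclass
class _ModelView:
    gene_id: str
    chrom: str
    weights: np.ndarray


def write_scan_output(table: ResultsTable, outdir: str | Path) -> None:
    """Write results.tsv, per-exposure qq_<exposure>.tsv and scan_meta.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(outdir / "results.tsv", sep="\t", index=False, float_format="%.10e")
    lambdas = {}
    for exposure, sub in table.df.groupby("exposure"):
        p = sub["p_amisti"].dropna()
        if len(p) >= 10:
            infl = genomic_inflation(p)
            lambdas[str(exposure)] = infl.lambda_gc
            infl.qq.to_csv(outdir / f"qq_{exposure}.tsv", sep="\t", index=False,
                           float_format="%.6f")
    meta = dict(table.metadata)
    meta["lambda_gc"] = lambdas
    meta["warnings"] = table.warnings
    (outdir / "scan_meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
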