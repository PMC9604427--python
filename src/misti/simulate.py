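"""Synthetic reference panels and case-control cohorts.

The generator mirrors the statistical structure the analysis assumes:
an LD-structured genotype panel (latent-Gaussian AR(1) haplotype blocks
thresholded at MAF-matched quantiles), expression with a sparse,
heritable cis component, and an ascertained case-control cohort whose
disease model carries a fixed expression-by-exposure interaction and
per-variant random interaction effects:

    logit P(Y=1) = a0 + X g + bE*E + bT*T + bTE*(T*E) + sum_j b_j G_j E,
    b_j ~ N(0, tau^2),  T = G w.

Cases and controls are drawn without replacement from a simulated
population (default 20x the target size), so downstream tests are
exercised under outcome-dependent sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .exceptions import EmptyInputError, ParameterError
from .io_formats import GenotypeMatrix, PhenotypeTable, VariantRecord

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass(frozen=True)
class LDSpec:
    """Block-structured LD specification for the latent-Gaussian model."""

    n_blocks: int = 10
    block_size: int = 10
    within_block_rho: float = 0.6
    maf_low: float = 0.05
    maf_high: float = 0.5
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 2_000

    def __post_init__(self) -> None:
        if self.block_size < 1 or self.n_blocks < 1:
            raise ParameterError("n_blocks and block_size must be >= 1")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ParameterError("within_block_rho must lie in [0, 1)")
        if not (0.005 <= self.maf_low <= self.maf_high <= 0.5):
            raise ParameterError("require 0.005 <= maf_low <= maf_high <= 0.5")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size


@dataclass(frozen=True)
class ExpressionTruth:
    """Generative truth for one gene's expression."""

    causal_indices: tuple[int, ...]
    causal_effects: tuple[float, ...]
    target_h2: float

    def __post_init__(self) -> None:
        if len(self.causal_indices) != len(self.causal_effects):
            raise ParameterError("causal_indices and causal_effects lengths differ")
        if not 0.0 <= self.target_h2 < 1.0:
            raise ParameterError("target_h2 must lie in [0, 1)")


@dataclass(frozen=True)
class CohortTruth:
    """Generative truth for the case-control disease model."""

    beta_E: float = 0.0
    beta_T: float = 0.0
    beta_TE: float = 0.0
    tau: float = 0.0
    intercept: float = -2.2
    study_effect: float = 0.1
    age_effect: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ParameterError("tau must be >= 0")


@dataclass(frozen=True)
class ExposureSim:
    """Distributional recipe for one simulated exposure variable."""

    name: str = "exposure"
    kind: str = "continuous"  # continuous | binary | ordinal
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    levels: tuple[int, ...] = (1, 2, 3, 4)
    level_probs: tuple[float, ...] = (0.17, 0.42, 0.245, 0.165)
    scale: float = 1.0
    eligibility: str = "all"  # all | parous_only | premenopausal_only | postmenopausal_only
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError(f"exposure {self.name}: scale must be > 0")
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ParameterError(f"exposure {self.name}: unknown kind '{self.kind}'")


def simulate_ld_genotypes(n: int, spec: LDSpec, sample_seed: int | None = None) -> GenotypeMatrix:
    """Simulate ``n`` diploid dosage vectors under block-AR(1) LD.

    Within a block the latent haplotype correlation is rho^|i-j|; blocks
    are independent.  Each haplotype allele is the indicator that a
    standard-normal latent variable falls below the MAF quantile, and
    the dosage is the sum over two independent haplotypes.  Variant
    properties (MAFs, positions) are fixed by ``spec.seed``; the
    optional ``sample_seed`` draws an independent sample on the same
    variant set (defaults to ``spec.seed``).
    """
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng_var = np.random.default_rng(spec.seed)
    p = spec.n_variants
    mafs = rng_var.uniform(spec.maf_low, spec.maf_high, size=p)
    thresholds = norm.ppf(mafs)

    rng = np.random.default_rng(spec.seed if sample_seed is None else sample_seed)
    rho = spec.within_block_rho
    innov_sd = np.float32(np.sqrt(1.0 - rho * rho))
    thr32 = thresholds.astype(np.float32)

    def _haplotypes() -> np.ndarray:
        # AR(1) recursion vectorised across blocks
        z = rng.standard_normal((n, spec.n_blocks, spec.block_size), dtype=np.float32)
        for j in range(1, spec.block_size):
            z[:, :, j] = np.float32(rho) * z[:, :, j - 1] + innov_sd * z[:, :, j]
        return z.reshape(n, p) < thr32

    dosages = np.add(_haplotypes(), _haplotypes(), dtype=np.float64)

    variants = [
        VariantRecord(
            id=f"snp{j:05d}",
            chrom=spec.chrom,
            pos=spec.pos_start + j * spec.pos_step,
            ref_allele=_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0],
            alt_allele=_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][1],
            maf=float(min(mafs[j], 1 - mafs[j])),
        )
        for j in range(p)
    ]
    sample_ids = [f"s{i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def simulate_expression_panel(
    genos: GenotypeMatrix, truth: ExpressionTruth, seed: int = 0
) -> np.ndarray:
    """Expression y = G_c b_c + e with the noise scaled (and orthogonalised
    against the genetic value) so the realised variance ratio equals
    ``target_h2`` exactly on the panel."""
    idx = np.asarray(truth.causal_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= genos.n_variants):
        raise ParameterError("causal index outside variant range")
    rng = np.random.default_rng(seed)
    n = genos.n_samples
    eps = rng.standard_normal(n)
    if truth.target_h2 == 0.0 or idx.size == 0:
        return eps
    g = genos.dosages[:, idx] @ np.asarray(truth.causal_effects, dtype=float)
    g = g - g.mean()
    var_g = float(g @ g) / n
    if var_g <= 0:
        raise ParameterError("causal genotypes carry no variance")
    eps = eps - eps.mean()
    eps = eps - (eps @ g) / (g @ g) * g  # exact orthogonality -> exact ratio
    target_var_e = var_g * (1.0 - truth.target_h2) / truth.target_h2
    eps *= np.sqrt(target_var_e / (float(eps @ eps) / n))
    return g + eps


def _compute_pcs(dosages: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k left singular vectors of the centred dosage matrix
    (orthonormal over samples)."""
    centred = dosages - dosages.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    return u[:, :k]


def simulate_cohort(
    genos: GenotypeMatrix,
    weights: np.ndarray,
    exposure: ExposureSim,
    truth: CohortTruth,
    n_cases: int,
    n_controls: int,
    n_studies: int = 2,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Ascertain a case-control cohort from a simulated population.

    ``genos`` is the population genotype matrix; cases and controls are
    sampled without replacement until the quotas are met.  The returned
    phenotype table carries case status, age, study, five genotype PCs
    of the sampled cohort, the exposure column and eligibility flags.
    """
    n_pop = genos.n_samples
    if n_cases + n_controls > n_pop:
        raise ParameterError("n_cases + n_controls exceeds the simulated population size")
    rng = np.random.default_rng(truth.seed)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != genos.n_variants:
        raise ParameterError("weight vector length does not match variant count")
    G = genos.dosages
    T = G @ w

    if exposure.kind == "binary":
        E = rng.binomial(1, exposure.prevalence, size=n_pop).astype(float)
    elif exposure.kind == "ordinal":
        E = rng.choice(np.asarray(exposure.levels, dtype=float), size=n_pop,
                       p=np.asarray(exposure.level_probs) / np.sum(exposure.level_probs))
    else:
        E = rng.normal(exposure.mean, exposure.sd, size=n_pop)
        if exposure.nonnegative:
            E = np.clip(E, 0.0, None)
    E_coded = E / exposure.scale

    study = rng.integers(0, n_studies, size=n_pop)
    age = rng.normal(55.0, 8.0, size=n_pop)
    b = rng.normal(0.0, truth.tau, size=genos.n_variants) if truth.tau > 0 else np.zeros(genos.n_variants)

    eta = (
        truth.intercept
        + truth.study_effect * (study % 2)
        + truth.age_effect * (age - 55.0)
        + truth.beta_E * E_coded
        + truth.beta_T * T
        + truth.beta_TE * T * E_coded
        + (G @ b) * E_coded
    )
    y = rng.binomial(1, expit(eta))

    case_pool = np.flatnonzero(y == 1)
    control_pool = np.flatnonzero(y == 0)
    if case_pool.size < n_cases or control_pool.size < n_controls:
        raise EmptyInputError(
            f"population yielded {case_pool.size} cases / {control_pool.size} controls; "
            "quotas unreachable - adjust the intercept or enlarge the population"
        )
    cases = rng.permutation(case_pool)[:n_cases]
    controls = rng.permutation(control_pool)[:n_controls]
    index = np.concatenate([cases, controls])
    index = index[rng.permutation(index.size)]

    cohort = genos.subset_samples(index.tolist())
    pcs = _compute_pcs(cohort.dosages, k=5)
    df = pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "case_status": y[index].astype(int),
        "age": age[index],
        "study": [f"study{int(s)}" for s in study[index]],
    })
    for k in range(5):
        df[f"pc{k+1}"] = pcs[:, k]
    df["parous"] = rng.binomial(1, 0.87, size=index.size)
    df["postmenopausal"] = rng.binomial(1, 0.67, size=index.size)
    df["former_mht_e"] = rng.binomial(1, 0.12, size=index.size)
    df["former_mht_ep"] = rng.binomial(1, 0.09, size=index.size)
    exposure_col = E_coded[index]
    elig = _eligibility_mask(df, exposure.eligibility)
    exposure_col = np.where(elig, exposure_col, np.nan)
    df[exposure.name] = exposure_col
    return cohort, PhenotypeTable(df)


def _eligibility_mask(df: pd.DataFrame, eligibility: str) -> np.ndarray:
    if eligibility == "all":
        return np.ones(len(df), dtype=bool)
    if eligibility == "parous_only":
        return df["parous"].to_numpy() == 1
    if eligibility == "premenopausal_only":
        return df["postmenopausal"].to_numpy() == 0
    if eligibility == "postmenopausal_only":
        return df["postmenopausal"].to_numpy() == 1
    raise ParameterError(f"unknown eligibility rule '{eligibility}'")


def make_exposures(
    table: PhenotypeTable, specs: Sequence[ExposureSim], seed: int = 0
) -> PhenotypeTable:
    """Add simulated exposure columns (coded on their analysis scale) and
    eligibility flags to a phenotype table.

    Continuous exposures are normal (optionally truncated at zero),
    binary ones Bernoulli, ordinal ones categorical on their level set.
    The stored column is raw / scale; rows failing the eligibility rule
    get a missing exposure so restricted analyses are complete-case."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ParameterError("exposure specs must name distinct columns")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    n = len(df)
    if "parous" not in df.columns:
        df["parous"] = rng.binomial(1, 0.87, size=n)
    if "postmenopausal" not in df.columns:
        df["postmenopausal"] = rng.binomial(1, 0.67, size=n)
    if "former_mht_e" not in df.columns:
        df["former_mht_e"] = rng.binomial(1, 0.12, size=n)
    if "former_mht_ep" not in df.columns:
        df["former_mht_ep"] = rng.binomial(1, 0.09, size=n)
    for spec in specs:
        if spec.kind == "binary":
            raw = rng.binomial(1, spec.prevalence, size=n).astype(float)
        elif spec.kind == "ordinal":
            raw = rng.choice(np.asarray(spec.levels, dtype=float), size=n,
                             p=np.asarray(spec.level_probs) / np.sum(spec.level_probs))
        else:
            raw = rng.normal(spec.mean, spec.sd, size=n)
            if spec.nonnegative:
                raw = np.clip(raw, 0.0, None)
        coded = raw / spec.scale
        elig = _eligibility_mask(df, spec.eligibility)
        df[spec.name] = np.where(elig, coded, np.nan)
    return PhenotypeTable(df)


def default_exposure_catalog() -> list[ExposureSim]:
    """Fourteen exposure recipes shaped like established breast-cancer
    risk factors (reproductive history, anthropometry, alcohol, smoking,
    oral contraceptive and menopausal hormone therapy use), with the
    standard per-unit codings and eligibility restrictions."""
    return [
        ExposureSim("age_first_birth", "continuous", mean=24.8, sd=4.6, scale=5, eligibility="parous_only"),
        ExposureSim("alcohol_gday", "continuous", mean=6.1, sd=11.4, scale=10, nonnegative=True),
        ExposureSim("age_menarche", "continuous", mean=12.95, sd=1.55, scale=2),
        ExposureSim("bmi_premenopausal", "continuous", mean=25.5, sd=5.3, scale=5, eligibility="premenopausal_only"),
        ExposureSim("bmi_postmenopausal", "continuous", mean=26.6, sd=5.2, scale=5, eligibility="postmenopausal_only"),
        ExposureSim("ever_breastfed", "binary", prevalence=0.78, eligibility="parous_only"),
        ExposureSim("breastfeeding_months", "continuous", mean=8.6, sd=11.2, scale=12, nonnegative=True, eligibility="parous_only"),
        ExposureSim("height_cm", "continuous", mean=163.8, sd=6.45, scale=5),
        ExposureSim("oc_ever", "binary", prevalence=0.59),
        ExposureSim("parous_exposure", "binary", prevalence=0.87),
        ExposureSim("n_full_term_births", "ordinal", eligibility="parous_only"),
        ExposureSim("smoking_current", "binary", prevalence=0.14),
        ExposureSim("mht_e_current", "binary", prevalence=0.16, eligibility="postmenopausal_only"),
        ExposureSim("mht_ep_current", "binary", prevalence=0.15, eligibility="postmenopausal_only"),
    ]
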