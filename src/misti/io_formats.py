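"""Standard-format I/O and allele harmonisation.

Genotypes are read from VCF (DS dosage field when present, otherwise
alt-allele counts from GT) into an alt-allele dosage matrix in [0, 2].
Phenotypes, per-gene expression weight files and scan results travel as
tab-separated text with headers so that every artefact round-trips
through plain files.

Coordinates are 1-based and region queries are fully closed intervals,
following VCF convention.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    EmptyOverlapError,
    ParameterError,
    ParseError,
    SchemaError,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: required phenotype columns beyond the sample identifier
REQUIRED_PHENO_COLUMNS = ("case_status", "age", "study", "pc1", "pc2", "pc3", "pc4", "pc5")

#: eligibility flag columns used by restricted analyses
ELIGIBILITY_COLUMNS = ("parous", "postmenopausal", "former_mht_e", "former_mht_ep")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with the metadata the pipeline filters on."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float
    info_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ParameterError(f"variant {self.id}: ref and alt alleles are identical")
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ParameterError(f"variant {self.id}: MAF {self.maf} outside [0, 0.5]")

    @property
    def is_strand_ambiguous(self) -> bool:
        pair = {self.ref_allele, self.alt_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with variant metadata."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.sample_ids):
            raise ParameterError("dosage row count does not match sample count")
        if p != len(self.variants):
            raise ParameterError("dosage column count does not match variant count")
        if self.dosages.size and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ParameterError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency from the column means."""
        m = self.dosages.mean(axis=0) / 2.0
        return np.minimum(m, 1.0 - m)

    def subset_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in index],
            dosages=self.dosages[:, index].copy(),
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=list(self.variants),
            dosages=self.dosages[index, :].copy(),
        )


class PhenotypeTable:
    """Typed phenotype/covariate/exposure table backed by a DataFrame.

    Exposure cells may be missing (NaN); they are never imputed here —
    each exposure is analysed complete-case downstream.
    """

    def __init__(self, df: pd.DataFrame):
        for col in ("sample_id",) + REQUIRED_PHENO_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"phenotype table missing required column '{col}'")
        if df["sample_id"].duplicated().any():
            raise SchemaError("sample_id values must be unique")
        status = df["case_status"].dropna()
        if not status.isin([0, 1]).all():
            bad = sorted(set(status) - {0, 1})
            raise SchemaError(f"case_status must be 0/1; found {bad}")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].astype(str).tolist()

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, col: str) -> pd.Series:
        return self.df[col]


@dataclass
class GeneWeights:
    """Per-gene expression weight entry (the TWAS weight unit)."""

    gene_id: str
    chrom: str
    window_start: int
    window_end: int
    scheme: str
    cv_r2: float
    h2: float
    h2_p: float
    variants: pd.DataFrame  # columns: variant_id, chrom, pos, ref, alt, weight

    def __post_init__(self) -> None:
        if self.scheme not in ("top1", "lasso", "enet"):
            raise ParameterError(f"unknown scheme '{self.scheme}'")
        w = np.asarray(self.variants["weight"], dtype=float)
        if not np.all(np.isfinite(w)):
            raise ParameterError(f"gene {self.gene_id}: non-finite weight")
        if self.scheme == "top1" and int(np.count_nonzero(w)) != 1:
            raise ParameterError(f"gene {self.gene_id}: top1 scheme must have exactly one nonzero weight")

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.variants["weight"], dtype=float)


@dataclass
class GxEResult:
    """One gene x exposure interaction test record (a results-table row)."""

    gene_id: str
    chrom: str
    n_snps: int
    p_fixed: float
    p_random: float
    p_fisher: float
    p_amisti: float
    exposure: str = ""
    fdr_adjusted: float = math.nan
    davies_fallback: bool = False
    converged: bool = True


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def _parse_region(region: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(region)
    if not m:
        raise ParameterError(f"malformed region '{region}'; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise ParameterError(f"malformed region '{region}'")
    return chrom, start, end


def read_genotypes(
    path: str | Path,
    region: str | None = None,
    maf_min: float = 0.0,
    info_min: float = 0.0,
) -> GenotypeMatrix:
    """Read dosages from a VCF, keeping variants with MAF >= ``maf_min``
    and (when an INFO score is present) INFO >= ``info_min``.

    Dosages come from the DS FORMAT field when available and otherwise
    from GT alt-allele counts.  Region queries are 1-based, closed on
    both ends.  Missing genotypes are filled with the variant mean.
    """
    import cyvcf2

    path = str(path)
    if region is not None:
        chrom_q, start_q, end_q = _parse_region(region)
    try:
        vcf = cyvcf2.VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"cannot parse VCF '{path}': {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyInputError(f"VCF '{path}' contains no samples")

    has_index = region is not None and (
        Path(path + ".tbi").exists() or Path(path + ".csi").exists()
    )
    iterator = vcf(f"{chrom_q}:{start_q}-{end_q}") if has_index else vcf
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for v in iterator:
        if region is not None and not (start_q <= v.POS <= end_q and v.CHROM == chrom_q):
            continue
        if len(v.ALT) != 1:
            continue  # multi-allelic records are out of scope
        ds = None
        try:
            ds = v.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(v.gt_types)
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        if np.isnan(dos).any():
            fill = np.nanmean(dos) if np.isfinite(np.nanmean(dos)) else 0.0
            dos = np.where(np.isnan(dos), fill, dos)
        m = float(dos.mean()) / 2.0
        maf = min(m, 1.0 - m)
        info = v.INFO.get("INFO")
        if maf < maf_min:
            continue
        if info is not None and float(info) < info_min:
            continue
        variants.append(
            VariantRecord(
                id=v.ID or f"{v.CHROM}:{v.POS}",
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref_allele=str(v.REF),
                alt_allele=str(v.ALT[0]),
                maf=maf,
                info_score=float(info) if info is not None else None,
            )
        )
        columns.append(np.clip(dos, 0.0, 2.0))
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)


def write_genotypes_vcf(genos: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT and DS fields (plain text)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">',
    ]
    chroms = sorted({v.chrom for v in genos.variants})
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + list(
        genos.sample_ids
    )
    lines.append("\t".join(header))
    order = sorted(range(genos.n_variants), key=lambda j: (genos.variants[j].chrom, genos.variants[j].pos))
    for j in order:
        var = genos.variants[j]
        dos = genos.dosages[:, j]
        info = f"INFO={var.info_score:.4f}" if var.info_score is not None else "."
        fields = [var.chrom, str(var.pos), var.id, var.ref_allele, var.alt_allele, ".", "PASS", info, "GT:DS"]
        for d in dos:
            g = int(round(d))
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(g, 0), 2)]
            fields.append(f"{gt}:{d:.4f}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a tab-separated phenotype/covariate/exposure table."""
    df = pd.read_csv(path, sep="\t", dtype={"study": str, "sample_id": str})
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Weight files
# ---------------------------------------------------------------------------

_WEIGHT_COLUMNS = [
    "gene_id", "gene_chrom", "window_start", "window_end", "scheme", "cv_r2",
    "h2", "h2_p", "variant_id", "chrom", "pos", "ref", "alt", "weight",
]


def write_weights(genes: Iterable[GeneWeights], path: str | Path) -> None:
    """Write per-gene weight entries as a flat TSV (one row per variant)."""
    rows = []
    for g in genes:
        for _, v in g.variants.iterrows():
            rows.append(
                (g.gene_id, g.chrom, g.window_start, g.window_end, g.scheme,
                 g.cv_r2, g.h2, g.h2_p, v["variant_id"], v["chrom"], v["pos"],
                 v["ref"], v["alt"], v["weight"])
            )
    df = pd.DataFrame(rows, columns=_WEIGHT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10e")


def read_weights(path: str | Path) -> list[GeneWeights]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_chrom": str, "chrom": str})
    missing = [c for c in _WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"weight file missing columns {missing}")
    out: list[GeneWeights] = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        first = sub.iloc[0]
        if not (first["h2_p"] < 0.01):
            raise SchemaError(
                f"gene {gene_id}: stored h2 p-value {first['h2_p']} fails the P<0.01 gate"
            )
        variants = sub[["variant_id", "chrom", "pos", "ref", "alt", "weight"]].reset_index(drop=True)
        out.append(
            GeneWeights(
                gene_id=str(gene_id),
                chrom=str(first["gene_chrom"]),
                window_start=int(first["window_start"]),
                window_end=int(first["window_end"]),
                scheme=str(first["scheme"]),
                cv_r2=float(first["cv_r2"]),
                h2=float(first["h2"]),
                h2_p=float(first["h2_p"]),
                variants=variants,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Allele harmonisation
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationReport:
    n_exact: int = 0
    n_flipped: int = 0
    n_dropped_unmatched: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_exact + self.n_flipped


def harmonize_alleles(
    gene: GeneWeights, genos: GenotypeMatrix
) -> tuple[np.ndarray, GenotypeMatrix, HarmonizationReport]:
    """Align a gene's weight variants with cohort genotypes.

    Matching is on chrom:pos.  Exact ref/alt matches pass through;
    swapped ref/alt flips the dosage (d -> 2-d); strand-complement
    matches are treated as matches after complementing; strand-ambiguous
    variants (A/T, C/G) and unmatched variants are dropped.
    """
    lookup: dict[tuple[str, int], int] = {
        (v.chrom, v.pos): j for j, v in enumerate(genos.variants)
    }
    report = HarmonizationReport()
    weights: list[float] = []
    cols: list[np.ndarray] = []
    records: list[VariantRecord] = []
    for _, wv in gene.variants.iterrows():
        key = (str(wv["chrom"]), int(wv["pos"]))
        wref, walt = str(wv["ref"]), str(wv["alt"])
        if {wref, walt} in ({"A", "T"}, {"C", "G"}):
            report.n_dropped_ambiguous += 1
            continue
        j = lookup.get(key)
        if j is None:
            report.n_dropped_unmatched += 1
            continue
        cv = genos.variants[j]
        cref, calt = cv.ref_allele, cv.alt_allele
        wref_c = _COMPLEMENT.get(wref, "?")
        walt_c = _COMPLEMENT.get(walt, "?")
        if (wref, walt) == (cref, calt) or (wref_c, walt_c) == (cref, calt):
            flip = False
        elif (walt, wref) == (cref, calt) or (walt_c, wref_c) == (cref, calt):
            flip = True
        else:
            report.n_dropped_mismatch += 1
            continue
        dos = genos.dosages[:, j]
        if flip:
            report.n_flipped += 1
            dos = 2.0 - dos
        else:
            report.n_exact += 1
        weights.append(float(wv["weight"]))
        cols.append(dos)
        records.append(
            VariantRecord(
                id=cv.id, chrom=cv.chrom, pos=cv.pos,
                ref_allele=wref, alt_allele=walt,
                maf=cv.maf, info_score=cv.info_score,
            )
        )
    if not cols:
        raise EmptyOverlapError(
            f"gene {gene.gene_id}: no weight variants overlap the cohort genotypes"
        )
    aligned = GenotypeMatrix(
        sample_ids=list(genos.sample_ids),
        variants=records,
        dosages=np.column_stack(cols),
    )
    return np.asarray(weights), aligned, report


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "gene_id", "chrom", "exposure", "n_snps", "p_fixed", "p_random",
    "p_fisher", "p_amisti", "fdr_adjusted", "davies_fallback", "converged",
]


def results_to_frame(results: Sequence[GxEResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])[RESULT_COLUMNS]


def write_results(results: Sequence[GxEResult], path: str | Path) -> None:
    """Write interaction results as a TSV mirroring the familiar
    gene / chromosome / SNP-count / fixed / random / adaptive / FDR layout."""
    if not results:
        raise EmptyInputError("no results to write")
    df = results_to_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.10e")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results file missing columns {missing}")
    return df
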