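"""RNA-level annotation: expression outliers and per-variant RNA support.

Expression outliers are scored with a modified z-score against a reference
cohort (a TCGA-style panel of tumors of the same disease):

    z = (TPM_sample - median_ref) / MAD_ref

where MAD is the *raw* median absolute deviation, without the 1.4826
normal-consistency constant. Genes whose reference MAD is zero get an
undefined z (``None``), never an infinity, to avoid spurious outliers in
unexpressed genes.

Per-variant RNA support counts alternate and total reads over the variant
locus in RNA; a record is "sufficient" when total coverage is at least 5
reads, and only sufficient records enter the DNA-RNA VAF correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ingest import ExpressionTable

__all__ = [
    "ReferenceCohortStats",
    "ExpressionAnnotation",
    "RnaSupport",
    "PearsonResult",
    "modified_zscore",
    "build_reference_stats",
    "annotate_expression",
    "rna_variant_support",
    "dna_rna_vaf_correlation",
]

#: default |z| threshold used only to highlight outliers in reports
OUTLIER_Z = 2.0

#: minimum total RNA reads for a variant to count as covered
MIN_RNA_READS = 5


@dataclass
class ReferenceCohortStats:
    """Per-gene median and raw MAD of TPM over the reference cohort."""

    median_tpm: dict[str, float]
    mad_tpm: dict[str, float]
    cohort_n: int

    def genes(self) -> list[str]:
        return list(self.median_tpm)


@dataclass(frozen=True)
class ExpressionAnnotation:
    gene: str
    sample_id: str
    tpm: float
    z: float | None  # None when reference MAD is 0

    @property
    def is_outlier(self) -> bool:
        return self.z is not None and abs(self.z) >= OUTLIER_Z


@dataclass(frozen=True)
class RnaSupport:
    """RNA read support at a DNA variant locus."""

    variant_key: tuple
    rna_alt_reads: int
    rna_total_reads: int
    min_reads: int = MIN_RNA_READS

    def __post_init__(self) -> None:
        if self.rna_alt_reads < 0 or self.rna_total_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.rna_alt_reads > self.rna_total_reads:
            raise ValueError("alt reads exceed total reads")

    @property
    def rna_vaf(self) -> float | None:
        if self.rna_total_reads == 0:
            return None
        return self.rna_alt_reads / self.rna_total_reads

    @property
    def sufficient(self) -> bool:
        return self.rna_total_reads >= self.min_reads


@dataclass(frozen=True)
class PearsonResult:
    r: float | None
    n: int
    p_value: float | None = None  # reporting-only, never a gate

    @property
    def defined(self) -> bool:
        return self.r is not None


def modified_zscore(tpm: float, median_tpm: float, mad_tpm: float) -> float | None:
    """(tpm - median) / MAD; None when the reference MAD is zero."""
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    if mad_tpm < 0:
        raise ValueError("MAD must be non-negative")
    if mad_tpm == 0:
        return None
    return (tpm - median_tpm) / mad_tpm


def build_reference_stats(expression: ExpressionTable) -> ReferenceCohortStats:
    """Per-gene median and raw MAD of TPM across the reference cohort."""
    mat = expression.tpm
    n = mat.shape[1]
    if n < 2:
        raise ValueError("reference cohort needs >= 2 samples (MAD degenerate)")
    values = mat.values.astype(float)
    med = np.median(values, axis=1)
    mad = np.median(np.abs(values - med[:, None]), axis=1)
    genes = list(mat.index)
    return ReferenceCohortStats(
        median_tpm=dict(zip(genes, med.tolist())),
        mad_tpm=dict(zip(genes, mad.tolist())),
        cohort_n=n,
    )


def annotate_expression(
    expression: ExpressionTable, stats_ref: ReferenceCohortStats
) -> list[ExpressionAnnotation]:
    """Score every (gene, sample) cell of a tumor expression table."""
    out = []
    for gene in expression.genes:
        if gene not in stats_ref.median_tpm:
            continue
        med = stats_ref.median_tpm[gene]
        mad = stats_ref.mad_tpm[gene]
        for sample in expression.samples:
            tpm = float(expression.tpm.at[gene, sample])
            out.append(
                ExpressionAnnotation(
                    gene=gene, sample_id=sample, tpm=tpm, z=modified_zscore(tpm, med, mad)
                )
            )
    return out


def rna_variant_support(
    variant_key: tuple, rna_alt_reads: int, rna_total_reads: int, min_reads: int = MIN_RNA_READS
) -> RnaSupport:
    """Build the RNA support record for one variant locus."""
    return RnaSupport(variant_key, rna_alt_reads, rna_total_reads, min_reads)


def dna_rna_vaf_correlation(pairs: list[tuple[float, float]]) -> PearsonResult:
    """Pearson correlation of (DNA VAF, RNA VAF) pairs.

    Callers should pre-filter to sufficient RNA coverage. Fewer than three
    pairs, or zero variance in either coordinate, yields an undefined result.
    """
    n = len(pairs)
    if n < 3:
        return PearsonResult(r=None, n=n)
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        return PearsonResult(r=None, n=n)
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), n=n, p_value=float(res.pvalue))
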