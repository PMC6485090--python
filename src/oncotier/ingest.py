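"""Readers and writers for the pipeline's standard inputs.

Coordinate conventions, enforced at read time:

* VCF records, splice junctions, SV breakpoints: **1-based** positions
  (junction coordinates are the first/last intronic bases).
* Copy-number segments and exon models: **0-based half-open** intervals
  (BED convention).

Somatic VCFs carry gene and consequence in a SnpEff-style ``ANN`` INFO field
(``alt|term|impact|gene|...``) and, optionally, the protein-level change in a
``PSPEC`` INFO field. VAF is taken from an explicit ``AF`` FORMAT/INFO tag
when present, otherwise derived from ``AD`` (alt / (ref + alt)); records with
neither are skipped with a logged warning. Multiallelic sites are split into
one record per alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "SomaticVariant",
    "GermlineCallset",
    "CopyNumberSegment",
    "StructuralVariantRecord",
    "ExpressionTable",
    "JunctionTable",
    "GeneModel",
    "CONSEQUENCES",
    "map_consequence",
    "read_somatic_vcf",
    "write_somatic_vcf",
    "read_germline_vcf",
    "write_germline_vcf",
    "read_cnv_segments",
    "write_cnv_segments",
    "read_expression",
    "write_expression",
    "read_junctions",
    "write_junctions",
    "read_gene_model",
    "write_gene_model",
    "read_sv",
    "write_sv",
]

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "promoter",
    "synonymous",
    "other",
)

#: Consequence classes that count as exonic for candidate selection.
EXONIC_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "synonymous"}
)

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "fusion")


class CoordinateError(ValueError):
    """A record violates the stated coordinate convention."""


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic SNV/indel call for one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str
    vaf: float
    depth: int
    sample_id: str
    variant_spec: str = ""  # protein/cDNA change, e.g. "R132H"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.alt == self.ref:
            raise ValueError("alt equals ref")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GermlineCallset:
    """Germline variant keys (with VAF) for one sample."""

    sample_id: str
    calls: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.calls


@dataclass(frozen=True)
class CopyNumberSegment:
    """Genomic interval with observed total copy number (0-based half-open)."""

    chrom: str
    start: int
    end: int
    observed_cn: float
    sample_id: str
    allele_cn: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.observed_cn < 0:
            raise ValueError("observed_cn must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class StructuralVariantRecord:
    """Paired-breakpoint structural variant (positions 1-based)."""

    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    sv_type: str
    genes_hit: tuple[str, ...]
    sample_id: str
    caller: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.pos_a < 1 or self.pos_b < 1:
            raise CoordinateError("SV breakpoint positions are 1-based (>= 1)")


@dataclass
class ExpressionTable:
    """Gene x sample matrix of TPM values."""

    tpm: pd.DataFrame  # index=genes, columns=sample ids

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression table")
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass
class JunctionTable:
    """Splice-junction read counts; donor/acceptor are 1-based intron boundaries."""

    rows: pd.DataFrame  # chrom, donor_pos, acceptor_pos, read_count, sample_id

    REQUIRED = ("chrom", "donor_pos", "acceptor_pos", "read_count", "sample_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"junction table missing column(s) {missing}")
        bad = self.rows["donor_pos"] >= self.rows["acceptor_pos"]
        if bad.any():
            line = int(np.flatnonzero(bad.values)[0]) + 1
            raise CoordinateError(f"junction line {line}: donor_pos must be < acceptor_pos")
        if (self.rows["read_count"] < 0).any():
            raise ValueError("junction read_count must be >= 0")


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based half-open
    end: int
    number: int


@dataclass(frozen=True)
class GeneInfo:
    gene: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]  # ordered by exon number (1..n)

    def __post_init__(self) -> None:
        nums = [e.number for e in self.exons]
        if nums != list(range(1, len(nums) + 1)):
            raise ValueError(f"{self.gene}: exon numbers must be consecutive from 1")
        by_coord = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.gene}: exons overlap")

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def tss(self) -> int:
        """0-based transcription start position."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneModel:
    """Exon structures per gene, plus the promoter-window convention.

    ``promoter_window`` is the number of bases upstream of the annotated
    transcription start that count as promoter territory.
    """

    genes: dict[str, GeneInfo]
    promoter_window: int = 1000

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def promoter_interval(self, gene: str) -> tuple[str, int, int]:
        """0-based half-open promoter interval upstream of the TSS."""
        g = self.genes[gene]
        if g.strand == "+":
            return (g.chrom, max(0, g.start - self.promoter_window), g.start)
        return (g.chrom, g.end, g.end + self.promoter_window)


# ---------------------------------------------------------------------------
# consequence mapping


def _load_consequence_map() -> dict[str, str]:
    path = resources.files("oncotier").joinpath("data/consequence_map.tsv")
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df["snpeff_term"], df["consequence"]))


_CONSEQUENCE_MAP: dict[str, str] | None = None


def map_consequence(term: str) -> str:
    """Map a SnpEff-style annotation term to the pipeline's consequence enum.

    Unmapped terms fall through to ``"other"`` with a warning. Terms already
    in the enum pass through unchanged.
    """
    global _CONSEQUENCE_MAP
    if _CONSEQUENCE_MAP is None:
        _CONSEQUENCE_MAP = _load_consequence_map()
    if term in CONSEQUENCES:
        return term
    mapped = _CONSEQUENCE_MAP.get(term)
    if mapped is None:
        logger.warning("unmapped consequence term %r -> 'other'", term)
        return "other"
    return mapped


# ---------------------------------------------------------------------------
# VCF


def _ann_for_alt(ann_value: str, alt: str) -> tuple[str, str]:
    """Pick (term, gene) from a SnpEff-style ANN INFO value for one alt allele."""
    for entry in ann_value.split(","):
        parts = entry.split("|")
        if len(parts) >= 4 and parts[0] == alt:
            return parts[1], parts[3]
    # fall back to the first annotation
    parts = ann_value.split(",")[0].split("|")
    term = parts[1] if len(parts) > 1 else "other"
    gene = parts[3] if len(parts) > 3 else ""
    return term, gene


def read_somatic_vcf(path: Path | str, sample_id: str | None = None) -> list[SomaticVariant]:
    """Read somatic SNV/indel calls from a VCF 4.x file.

    One record is emitted per sample-allele; multiallelic sites are split.
    VAF precedence: explicit AF tag, then AD-derived; records lacking both
    (or lacking depth) are skipped with a warning.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    if sample_id is None:
        sample_id = samples[0] if samples else "sample"
    out: list[SomaticVariant] = []
    skipped = 0
    for rec in vcf:
        ann = rec.INFO.get("ANN")
        pspec = rec.INFO.get("PSPEC") or ""
        for ai, alt in enumerate(rec.ALT):
            if ann:
                term, gene = _ann_for_alt(ann, alt)
            else:
                term, gene = "other", ""
            consequence = map_consequence(term)
            vaf = None
            depth = None
            try:
                af = rec.format("AF")
                if af is not None:
                    vaf = float(af[0][ai])
            except (KeyError, TypeError):
                pass
            if vaf is None:
                info_af = rec.INFO.get("AF")
                if info_af is not None:
                    vaf = float(info_af[ai]) if isinstance(info_af, tuple) else float(info_af)
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is not None:
                ref_n = int(ad[0][0])
                alt_n = int(ad[0][ai + 1])
                depth = ref_n + sum(int(ad[0][j + 1]) for j in range(len(rec.ALT)))
                if vaf is None:
                    total = ref_n + alt_n
                    vaf = alt_n / total if total > 0 else None
            if depth is None:
                try:
                    dp = rec.format("DP")
                    if dp is not None:
                        depth = int(dp[0][0])
                except KeyError:
                    pass
            if vaf is None or depth is None:
                skipped += 1
                continue
            specs = [s.strip() for s in str(pspec).split(",")] if pspec else []
            spec = specs[ai] if ai < len(specs) else (specs[0] if specs else "")
            out.append(
                SomaticVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=gene.upper(),
                    consequence=consequence,
                    vaf=min(1.0, max(0.0, vaf)),
                    depth=depth,
                    sample_id=sample_id,
                    variant_spec=spec,
                )
            )
    if skipped:
        logger.warning("%s: skipped %d record(s) without a VAF/depth source", path, skipped)
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele|Annotation|Putative_impact|Gene_Name'">
##INFO=<ID=PSPEC,Number=.,Type=String,Description="Protein or cDNA level change per alt allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_somatic_vcf(variants: list[SomaticVariant], path: Path | str) -> Path:
    """Write somatic calls as a plain-text single-sample VCF 4.2."""
    path = Path(path)
    sample = variants[0].sample_id if variants else "sample"
    lines = [_VCF_HEADER.format(sample=sample)]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        alt_n = int(round(v.vaf * v.depth))
        ref_n = v.depth - alt_n
        ann = f"{v.alt}|{_reverse_consequence(v.consequence)}|MODERATE|{v.gene}"
        info = f"ANN={ann}"
        if v.variant_spec:
            info += f";PSPEC={v.variant_spec}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}"
            f"\tGT:AD:DP\t0/1:{ref_n},{alt_n}:{v.depth}\n"
        )
    path.write_text("".join(lines))
    return path


_REVERSE_CONSEQUENCE = {
    "missense": "missense_variant",
    "nonsense": "stop_gained",
    "frameshift": "frameshift_variant",
    "inframe_indel": "inframe_deletion",
    "splice_site": "splice_donor_variant",
    "promoter": "upstream_gene_variant",
    "synonymous": "synonymous_variant",
    "other": "intron_variant",
}


def _reverse_consequence(consequence: str) -> str:
    return _REVERSE_CONSEQUENCE[consequence]


def read_germline_vcf(path: Path | str, sample_id: str | None = None) -> GermlineCallset:
    """Read a germline callset; keys are (chrom, pos, ref, alt), values VAF."""
    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else "sample"
    calls: dict[tuple[str, int, str, str], float] = {}
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT):
            vaf = 0.5
            try:
                ad = rec.format("AD")
                if ad is not None:
                    ref_n = int(ad[0][0])
                    alt_n = int(ad[0][ai + 1])
                    if ref_n + alt_n > 0:
                        vaf = alt_n / (ref_n + alt_n)
            except KeyError:
                pass
            calls[(rec.CHROM, rec.POS, rec.REF, alt)] = vaf
    return GermlineCallset(sample_id=sample_id, calls=calls)


def write_germline_vcf(callset: GermlineCallset, path: Path | str, depth: int = 40) -> Path:
    path = Path(path)
    lines = [_VCF_HEADER.format(sample=callset.sample_id)]
    for (chrom, pos, ref, alt), vaf in sorted(callset.calls.items()):
        alt_n = int(round(vaf * depth))
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t."
            f"\tGT:AD:DP\t0/1:{depth - alt_n},{alt_n}:{depth}\n"
        )
    path.write_text("".join(lines))
    return path


# ---------------------------------------------------------------------------
# TSV-backed formats


def read_cnv_segments(path: Path | str) -> list[CopyNumberSegment]:
    """Read SEG-like TSV: sample, chrom, start, end, observed_cn[, allele_cn]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        allele = None
        raw = str(getattr(row, "allele_cn", "") or "")
        if raw:
            a, b = raw.split("|")
            allele = (float(a), float(b))
        try:
            out.append(
                CopyNumberSegment(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    observed_cn=float(row.observed_cn),
                    sample_id=str(row.sample),
                    allele_cn=allele,
                )
            )
        except CoordinateError as err:
            raise CoordinateError(f"{path} line {i + 2}: {err}") from err
    return out


def write_cnv_segments(segments: list[CopyNumberSegment], path: Path | str) -> Path:
    df = pd.DataFrame(
        [
            (
                s.sample_id,
                s.chrom,
                s.start,
                s.end,
                s.observed_cn,
                "|".join(map(str, s.allele_cn)) if s.allele_cn else "",
            )
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "observed_cn", "allele_cn"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_expression(path: Path | str) -> ExpressionTable:
    """Read a TPM TSV with a ``gene`` column and one column per sample."""
    df = pd.read_csv(path, sep="\t").set_index("gene")
    df.index.name = None
    return ExpressionTable(tpm=df)


def write_expression(table: ExpressionTable, path: Path | str) -> Path:
    table.tpm.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)
    return Path(path)


def read_junctions(path: Path | str) -> JunctionTable:
    """Read STAR-SJ-style junction TSV: chrom, donor_pos, acceptor_pos, read_count, sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return JunctionTable(rows=df)


def write_junctions(table: JunctionTable, path: Path | str) -> Path:
    table.rows.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_gene_model(path: Path | str, promoter_window: int = 1000) -> GeneModel:
    """Read a BED-like exon table: gene, chrom, strand, exon_number, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes: dict[str, GeneInfo] = {}
    for gene, group in df.groupby("gene", sort=False):
        group = group.sort_values("exon_number")
        exons = tuple(
            Exon(chrom=str(r.chrom), start=int(r.start), end=int(r.end), number=int(r.exon_number))
            for r in group.itertuples(index=False)
        )
        genes[str(gene)] = GeneInfo(
            gene=str(gene),
            chrom=str(group["chrom"].iloc[0]),
            strand=str(group["strand"].iloc[0]),
            exons=exons,
        )
    return GeneModel(genes=genes, promoter_window=promoter_window)


def write_gene_model(model: GeneModel, path: Path | str) -> Path:
    rows = [
        (g.gene, g.chrom, g.strand, e.number, e.start, e.end)
        for g in model.genes.values()
        for e in g.exons
    ]
    pd.DataFrame(
        rows, columns=["gene", "chrom", "strand", "exon_number", "start", "end"]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_sv(path: Path | str) -> list[StructuralVariantRecord]:
    """Read BEDPE-like SV TSV with 1-based breakpoints."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        genes = tuple(g for g in str(row.genes_hit).split(",") if g)
        out.append(
            StructuralVariantRecord(
                chrom_a=str(row.chrom_a),
                pos_a=int(row.pos_a),
                strand_a=str(row.strand_a),
                chrom_b=str(row.chrom_b),
                pos_b=int(row.pos_b),
                strand_b=str(row.strand_b),
                sv_type=str(row.sv_type),
                genes_hit=genes,
                sample_id=str(row.sample),
                caller=str(getattr(row, "caller", "")),
            )
        )
    return out


def write_sv(records: list[StructuralVariantRecord], path: Path | str) -> Path:
    df = pd.DataFrame(
        [
            (
                r.sample_id,
                r.chrom_a,
                r.pos_a,
                r.strand_a,
                r.chrom_b,
                r.pos_b,
                r.strand_b,
                r.sv_type,
                ",".join(r.genes_hit),
                r.caller,
            )
            for r in records
        ],
        columns=[
            "sample",
            "chrom_a",
            "pos_a",
            "strand_a",
            "chrom_b",
            "pos_b",
            "strand_b",
            "sv_type",
            "genes_hit",
            "caller",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
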