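"""Copy-number and structural-variant prioritization.

Observed copy number in an impure tumor sample is a mixture of tumor and
normal cells:

    observed = purity * tumor_cn + (1 - purity) * normal_cn

Purity correction inverts this mixture (floored at zero). Corrected copy
numbers are then classified relative to integer states with a +/-0.5
tolerance band, except the copy-neutral band, which is anchored at the
sample ploidy so hyperploid genomes are not called gained genome-wide:

* homozygous loss: cn < 0.5
* heterozygous loss: 0.5 <= cn < 1.5
* neutral: |cn - ploidy| <= 0.5
* focal amplification: cn >= 5
* gain: everything above the neutral band below 5 copies

Focality is arm-level when a segment covers at least half of its arm.
Priority ranks follow the clinical convention of reporting unambiguous
two-copy losses and high-copy focal amplifications first:

* rank 1: homozygous loss, focal amplification, and actionable-gene SVs
* rank 2: focal gain / focal heterozygous loss
* rank 3: arm-level gain / arm-level heterozygous loss
* neutral: unranked
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ingest import CopyNumberSegment, GeneModel, StructuralVariantRecord

__all__ = [
    "ClassifiedCnv",
    "ArmTable",
    "correct_copy_number",
    "classify_segment",
    "genes_in_segment",
    "prioritize_findings",
    "FOCAL_AMP_CN",
]

COPY_CLASSES = (
    "focal_amplification",
    "gain",
    "neutral",
    "heterozygous_loss",
    "homozygous_loss",
)

#: corrected copies at or above this are amplifications (below: second-class gains)
FOCAL_AMP_CN = 5.0

#: fraction of arm length at or above which a segment is arm-level
ARM_FRACTION = 0.5


@dataclass(frozen=True)
class Arm:
    chrom: str
    start: int  # 0-based half-open
    end: int
    label: str  # "p" or "q"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ArmTable:
    """Chromosome-arm intervals; arms must tile each chromosome without overlap."""

    arms: list[Arm]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Arm]] = {}
        for arm in self.arms:
            by_chrom.setdefault(arm.chrom, []).append(arm)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            for a, b in zip(arms, arms[1:]):
                if a.end != b.start:
                    raise ValueError(f"arms of {chrom} do not tile: {a} vs {b}")

    def arm_of(self, chrom: str, start: int, end: int) -> Arm:
        """The arm holding the larger share of the interval."""
        best, best_overlap = None, -1
        for arm in self.arms:
            if arm.chrom != chrom:
                continue
            overlap = min(end, arm.end) - max(start, arm.start)
            if overlap > best_overlap:
                best, best_overlap = arm, overlap
        if best is None or best_overlap <= 0:
            raise KeyError(f"no arm covers {chrom}:{start}-{end}")
        return best

    @classmethod
    def read(cls, path) -> "ArmTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            arms=[
                Arm(str(r.chrom), int(r.start), int(r.end), str(r.arm))
                for r in df.itertuples(index=False)
            ]
        )

    def write(self, path) -> None:
        pd.DataFrame(
            [(a.chrom, a.start, a.end, a.label) for a in self.arms],
            columns=["chrom", "start", "end", "arm"],
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ClassifiedCnv:
    """A segment with purity-corrected copy number, class, focality and rank."""

    segment: CopyNumberSegment
    corrected_cn: float
    copy_class: str
    focality: str  # "focal" | "arm_level"
    genes_hit: tuple[str, ...] = ()
    priority_rank: int | None = None  # 1 highest; None = unranked (neutral)

    def __post_init__(self) -> None:
        if self.copy_class not in COPY_CLASSES:
            raise ValueError(f"unknown copy_class {self.copy_class!r}")


def correct_copy_number(observed_cn: float, purity: float, normal_cn: float = 2.0) -> float:
    """Invert the tumor/normal mixture; result floored at 0."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    corrected = (observed_cn - normal_cn * (1.0 - purity)) / purity
    return max(0.0, corrected)


def _copy_class(corrected_cn: float, ploidy: float) -> str:
    if corrected_cn < 0.5:
        return "homozygous_loss"
    if corrected_cn < 1.5:
        return "heterozygous_loss"
    if corrected_cn >= FOCAL_AMP_CN:
        return "focal_amplification"
    if abs(corrected_cn - ploidy) <= 0.5:
        return "neutral"
    if corrected_cn > ploidy:
        return "gain"
    # below the neutral band but above 1.5: relative loss in a hyperploid genome
    return "heterozygous_loss"


def _rank(copy_class: str, focality: str) -> int | None:
    if copy_class == "neutral":
        return None
    if copy_class in ("homozygous_loss", "focal_amplification"):
        return 1
    if focality == "focal":
        return 2
    return 3


def classify_segment(
    segment: CopyNumberSegment,
    purity: float,
    ploidy: float,
    arms: ArmTable,
    model: GeneModel | None = None,
) -> ClassifiedCnv:
    """Purity-correct, classify and rank one copy-number segment."""
    corrected = correct_copy_number(segment.observed_cn, purity)
    copy_class = _copy_class(corrected, ploidy)
    arm = arms.arm_of(segment.chrom, segment.start, segment.end)
    covered = min(segment.end, arm.end) - max(segment.start, arm.start)
    focality = "arm_level" if covered >= ARM_FRACTION * arm.length else "focal"
    # amplification is by definition focal territory; an arm-level high gain
    # stays classified as amplification but keeps its arm-level focality tag
    genes = tuple(genes_in_segment(segment, model)) if model is not None else ()
    return ClassifiedCnv(
        segment=segment,
        corrected_cn=corrected,
        copy_class=copy_class,
        focality=focality,
        genes_hit=genes,
        priority_rank=_rank(copy_class, focality),
    )


def genes_in_segment(segment: CopyNumberSegment, model: GeneModel) -> list[str]:
    """Genes overlapping the segment by >= 1 bp (half-open intervals)."""
    out = []
    for g in model.genes.values():
        if g.chrom == segment.chrom and g.start < segment.end and segment.start < g.end:
            out.append(g.gene)
    return out


def prioritize_findings(
    classified: list[ClassifiedCnv], include_low_priority: bool = True
) -> list[ClassifiedCnv]:
    """Stable sort by rank, then by distance of corrected CN from diploid.

    Rank-3 findings (arm-level gains, heterozygous losses) are reported only
    when ``include_low_priority`` is set (the default, matching manual
    curation practice; disabling it emulates stricter automated scopes that
    skip sub-5-copy gains and het losses). Neutral segments are never
    reported.
    """
    eligible = [
        c
        for c in classified
        if c.priority_rank is not None and (include_low_priority or c.priority_rank < 3)
    ]
    return sorted(
        eligible, key=lambda c: (c.priority_rank, -abs(c.corrected_cn - 2.0))
    )


def sv_findings_rank1(
    sv_records: list[StructuralVariantRecord], actionable_genes
) -> list[StructuralVariantRecord]:
    """SVs disrupting/activating an actionable gene (attached as rank-1 findings)."""
    return [
        sv for sv in sv_records if any(g.upper() in actionable_genes for g in sv.genes_hit)
    ]
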