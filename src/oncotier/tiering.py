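"""Candidate-variant selection and actionability tiering.

Somatic SNVs/indels are classified into four tiers against the knowledge
base, with strict precedence (a variant gets exactly one tier):

* **Tier 1** -- exact-variant evidence of clinical significance in the study
  disease (default glioblastoma).
* **Tier 2** -- exact-variant evidence of clinical significance in another
  tumor type.
* **Tier 3** -- variant of unknown significance (VUS) in an actionable gene
  that carries at least one drug association.
* **Tier 4** -- VUS in a cancer-census gene.

Candidate selection keeps exonic and splice-site consequences plus variants
falling in the promoter window of promoter-listed genes (TERT by default);
synonymous variants are excluded by default.

Low-VAF rescue retains sub-threshold calls (VAF < 15%) in known cancer genes
when total read depth is at least 40, mirroring manual review of likely
subclonal events in impure tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Container

from .ingest import EXONIC_CONSEQUENCES, GeneModel, SomaticVariant
from .kb import KnowledgeBase, query_drugs, query_evidence

__all__ = [
    "TieredFinding",
    "select_candidates",
    "tier_for",
    "assign_tier",
    "rescue_low_vaf",
    "tier_sample",
]

TIERS = (1, 2, 3, 4)
CANDIDATE_CLASSES = ("exonic", "splice_site", "promoter")


@dataclass(frozen=True)
class TieredFinding:
    """A somatic variant with its assigned tier and supporting evidence."""

    variant: SomaticVariant
    tier: int | None  # 1..4 or None
    candidate_class: str = "exonic"
    evidence_refs: tuple[str, ...] = ()
    rescue_flag: bool = False

    def __post_init__(self) -> None:
        if self.tier is not None and self.tier not in TIERS:
            raise ValueError(f"tier must be in {TIERS} or None")
        if self.candidate_class not in CANDIDATE_CLASSES:
            raise ValueError(f"unknown candidate_class {self.candidate_class!r}")


def candidate_class_of(
    variant: SomaticVariant,
    model: GeneModel | None,
    promoter_genes: frozenset[str] = frozenset({"TERT"}),
    include_synonymous: bool = False,
) -> str | None:
    """Return the candidate class of a variant, or None if not a candidate."""
    if variant.consequence == "synonymous" and not include_synonymous:
        return None
    if variant.consequence in EXONIC_CONSEQUENCES:
        return "exonic"
    if variant.consequence == "splice_site":
        return "splice_site"
    # promoter: either annotated as promoter, or positionally inside the
    # promoter window of a promoter-listed gene
    if variant.gene in promoter_genes and model is not None and variant.gene in model:
        chrom, start, end = model.promoter_interval(variant.gene)
        if variant.chrom == chrom and start < variant.pos <= end:  # pos is 1-based
            return "promoter"
    if variant.consequence == "promoter" and variant.gene in promoter_genes:
        return "promoter"
    return None


def select_candidates(
    variants: list[SomaticVariant],
    model: GeneModel | None = None,
    promoter_genes: frozenset[str] = frozenset({"TERT"}),
    include_synonymous: bool = False,
) -> list[SomaticVariant]:
    """Keep exonic, splice-site and promoter-window candidate variants."""
    return [
        v
        for v in variants
        if candidate_class_of(v, model, promoter_genes, include_synonymous) is not None
    ]


def tier_for(
    gene: str, variant_spec: str, kb: KnowledgeBase, study_disease: str = "glioblastoma"
) -> tuple[int | None, tuple[str, ...]]:
    """Tier kernel on (gene, variant_spec): returns (tier, evidence refs).

    Precedence Tier1 > Tier2 > Tier3 > Tier4 > none; pure function.
    """
    ev = query_evidence(kb, gene, variant_spec, study_disease)
    same_sig = [e for e in ev.same_disease if e.significance == "clinically_significant"]
    other_sig = [e for e in ev.other_disease if e.significance == "clinically_significant"]
    if same_sig:
        return 1, tuple(e.source_id for e in ev.all)
    if other_sig:
        return 2, tuple(e.source_id for e in ev.all)
    actionable = kb.gene_sets.get("actionable_genes")
    # the gene qualifies with *any* drug association (a gain-directed drug
    # still marks the gene actionable for a VUS), not only scope-compatible ones
    if (
        actionable is not None
        and gene.upper() in actionable
        and gene.upper() in kb.genes_with_drugs()
    ):
        drugs = query_drugs(kb, gene, "snv", variant_spec)
        refs = tuple(f"{d.gene}:{d.drug}" for d in drugs)
        return 3, refs
    census = kb.gene_sets.get("cancer_census")
    if census is not None and gene.upper() in census:
        return 4, ()
    return None, ()


def assign_tier(
    variant: SomaticVariant,
    kb: KnowledgeBase,
    study_disease: str = "glioblastoma",
    candidate_class: str = "exonic",
    rescue_flag: bool = False,
) -> TieredFinding:
    """Assign a single tier with precedence Tier1 > Tier2 > Tier3 > Tier4 > none.

    Pure function of its inputs: no randomness, no state.
    """
    spec = variant.variant_spec or f"{variant.ref}>{variant.alt}"
    tier, refs = tier_for(variant.gene, spec, kb, study_disease)
    return TieredFinding(variant, tier, candidate_class, refs, rescue_flag)


@dataclass
class VafPartition:
    """Partition of variants by the low-VAF rescue rule."""

    pass_main: list[SomaticVariant] = field(default_factory=list)
    rescued: list[SomaticVariant] = field(default_factory=list)
    dropped: list[SomaticVariant] = field(default_factory=list)

    @property
    def kept(self) -> list[SomaticVariant]:
        return self.pass_main + self.rescued


def rescue_low_vaf(
    variants: list[SomaticVariant],
    cancer_gene_set: Container[str],
    vaf_threshold: float = 0.15,
    min_depth: int = 40,
) -> VafPartition:
    """Partition variants by the VAF threshold with cancer-gene rescue.

    Variants at or above the threshold pass. Below-threshold variants in a
    known cancer gene with depth >= ``min_depth`` are rescued; the rest are
    dropped.
    """
    part = VafPartition()
    for v in variants:
        if v.vaf >= vaf_threshold:
            part.pass_main.append(v)
        elif v.gene in cancer_gene_set and v.depth >= min_depth:
            part.rescued.append(v)
        else:
            part.dropped.append(v)
    return part


def tier_sample(
    variants: list[SomaticVariant],
    kb: KnowledgeBase,
    model: GeneModel | None = None,
    study_disease: str = "glioblastoma",
    apply_vaf_filter: bool = True,
) -> list[TieredFinding]:
    """Full per-sample tiering: select candidates, apply VAF rescue, tier each.

    Convenience wrapper chaining :func:`select_candidates`,
    :func:`rescue_low_vaf` (against the cancer-census set) and
    :func:`assign_tier`.
    """
    promoter_genes = frozenset(
        kb.gene_sets["promoter_genes"].genes if "promoter_genes" in kb.gene_sets else {"TERT"}
    )
    candidates = select_candidates(variants, model, promoter_genes)
    rescued_keys: set = set()
    if apply_vaf_filter:
        census = kb.gene_sets.get("cancer_census")
        census_genes = census.genes if census else frozenset()
        part = rescue_low_vaf(candidates, census_genes)
        rescued_keys = {id(v) for v in part.rescued}
        candidates = part.kept
    findings = []
    for v in candidates:
        cls = candidate_class_of(v, model, promoter_genes) or "exonic"
        findings.append(
            assign_tier(v, kb, study_disease, cls, rescue_flag=id(v) in rescued_keys)
        )
    return findings
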