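"""Therapy matching: findings -> drug options, combinations, hypermutation rule.

Tiered SNVs/indels (tiers 1-3), prioritized CNVs and actionable SVs are
matched against the drug-gene knowledge base; Tier-4-only variants emit no
options. Combination options pair drugs whose targets lie in one pathway
(an upstream receptor gain plus a downstream suppressor loss, or two
parallel arms). Samples with hypermutated exomes and a disrupted
mismatch-repair gene receive checkpoint-inhibitor options through the
pseudo-gene key ``TMB_HIGH``, which keeps the matcher uniform: checkpoint
drugs are ordinary knowledge-base rows.

A configuration switch restricts output to molecularly targeted agents
(dropping chemo- and immunotherapies), emulating automated curation scopes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .cnv import ClassifiedCnv
from .ingest import SomaticVariant, StructuralVariantRecord
from .kb import EVIDENCE_LEVELS, KnowledgeBase, query_drugs
from .tiering import TieredFinding, tier_for

__all__ = [
    "Finding",
    "tier_finding",
    "TherapyOption",
    "MutationBurden",
    "match_therapies",
    "suggest_combinations",
    "apply_hypermutation_rule",
    "compute_burden",
    "rank_therapies",
    "summarize_association_types",
]

FINDING_TYPES = ("snv", "indel", "cnv_gain", "cnv_loss", "sv", "burden", "expression")

RATIONALES = (
    "direct_target",
    "pathway_downstream",
    "combination_same_pathway",
    "combination_parallel_arms",
    "hypermutation_checkpoint",
)

#: hypermutation calling defaults: count > max(floor, fold * cohort median)
HYPERMUTATION_FLOOR = 1000
HYPERMUTATION_FOLD = 5.0

#: normalized names of non-targeted (chemo/immuno/cell) therapies in the
#: bundled KB, used by the targeted-only scope switch
NON_TARGETED_DRUGS = frozenset(
    {"TEMOZOLOMIDE", "DOCETAXEL", "PACLITAXEL", "PEMBROLIZUMAB", "NIVOLUMAB", "CART"}
)

#: consequence classes that count as a mismatch-repair gene disruption
MMR_DISRUPTING = frozenset({"nonsense", "frameshift", "splice_site"})


@dataclass(frozen=True)
class Finding:
    """A typed, matchable finding: tiered SNV/indel, CNV class, SV or burden flag."""

    sample_id: str
    gene: str
    finding_type: str
    variant_spec: str = ""
    tier: int | None = None
    priority_rank: int | None = None

    def __post_init__(self) -> None:
        if self.finding_type not in FINDING_TYPES:
            raise ValueError(f"unknown finding_type {self.finding_type!r}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.sample_id, self.gene, self.finding_type, self.variant_spec)


def finding_from_tiered(tf: TieredFinding) -> Finding:
    v = tf.variant
    ftype = "indel" if v.is_indel else "snv"
    return Finding(
        sample_id=v.sample_id,
        gene=v.gene,
        finding_type=ftype,
        variant_spec=v.variant_spec or f"{v.ref}>{v.alt}",
        tier=tf.tier,
    )


def findings_from_cnv(classified: list[ClassifiedCnv]) -> list[Finding]:
    out = []
    for c in classified:
        if c.priority_rank is None:
            continue
        gaining = c.copy_class in ("gain", "focal_amplification")
        ftype = "cnv_gain" if gaining else "cnv_loss"
        spec = "amplification" if c.copy_class == "focal_amplification" else (
            "gain" if gaining else "loss"
        )
        for gene in c.genes_hit:
            out.append(
                Finding(
                    sample_id=c.segment.sample_id,
                    gene=gene,
                    finding_type=ftype,
                    variant_spec=spec,
                    priority_rank=c.priority_rank,
                )
            )
    return out


def tier_finding(
    finding: Finding, kb: KnowledgeBase, study_disease: str = "glioblastoma"
) -> Finding:
    """Return a copy of an SNV/indel finding with its tier assigned from the KB.

    Non-SNV findings pass through unchanged (CNV/SV/burden findings are
    ranked by priority, not tier).
    """
    if finding.finding_type not in ("snv", "indel") or finding.tier is not None:
        return finding
    tier, _refs = tier_for(finding.gene, finding.variant_spec, kb, study_disease)
    return Finding(
        sample_id=finding.sample_id,
        gene=finding.gene,
        finding_type=finding.finding_type,
        variant_spec=finding.variant_spec,
        tier=tier,
        priority_rank=finding.priority_rank,
    )


def finding_from_sv(sv: StructuralVariantRecord, gene: str, spec: str = "") -> Finding:
    return Finding(
        sample_id=sv.sample_id, gene=gene.upper(), finding_type="sv",
        variant_spec=spec, priority_rank=1,
    )


@dataclass(frozen=True)
class TherapyOption:
    """One therapy suggestion (monotherapy or combination) for a sample."""

    sample_id: str
    drugs: tuple[str, ...]  # normalized names; singleton = monotherapy
    targets: tuple[Finding, ...]
    evidence_level: str
    trial_ids: tuple[str, ...] = ()
    rationale: str = "direct_target"
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError("option must carry at least one drug")
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence_level {self.evidence_level!r}")
        if self.rationale not in RATIONALES:
            raise ValueError(f"unknown rationale {self.rationale!r}")
        if not self.targets:
            raise ValueError("option must reference at least one finding")

    @property
    def evidence_rank(self) -> int:
        return EVIDENCE_LEVELS.index(self.evidence_level)


@dataclass(frozen=True)
class MutationBurden:
    """Per-sample exonic SNV burden and MMR status."""

    sample_id: str
    exonic_snv_count: int
    hypermutant: bool
    mmr_hits: tuple[Finding, ...] = ()

    def __post_init__(self) -> None:
        if self.exonic_snv_count < 0:
            raise ValueError("exonic_snv_count must be >= 0")


_ALTERATION_CLASS = {
    "snv": "snv",
    "indel": "snv",
    "cnv_gain": "gain",
    "cnv_loss": "loss",
    "sv": "sv",
    "burden": "snv",  # TMB_HIGH rows are any_alteration, class is moot
    "expression": "expression",
}


def match_therapies(
    findings: list[Finding],
    kb: KnowledgeBase,
    targeted_only: bool = False,
) -> list[TherapyOption]:
    """Emit one TherapyOption per (sample, drug, target), deduplicated.

    SNVs/indels must carry tier 1-3; Tier-4-only and untiered variants are
    not matched. CNV, SV, expression and burden findings match regardless of
    tier. With ``targeted_only``, chemo/immunotherapy rows are suppressed.
    """
    options: list[TherapyOption] = []
    seen: set[tuple] = set()
    for f in findings:
        if f.finding_type in ("snv", "indel") and (f.tier is None or f.tier > 3):
            continue
        assocs = query_drugs(kb, f.gene, _ALTERATION_CLASS[f.finding_type], f.variant_spec)
        rationale = "hypermutation_checkpoint" if f.finding_type == "burden" else "direct_target"
        for assoc in assocs:
            if targeted_only and assoc.drug in NON_TARGETED_DRUGS:
                continue
            key = (f.sample_id, assoc.drug, f.key)
            if key in seen:
                continue
            seen.add(key)
            options.append(
                TherapyOption(
                    sample_id=f.sample_id,
                    drugs=(assoc.drug,),
                    targets=(f,),
                    evidence_level=assoc.evidence_level,
                    trial_ids=assoc.trial_ids,
                    rationale=rationale,
                )
            )
    return options


def suggest_combinations(
    options: list[TherapyOption],
    findings: list[Finding],
    pathways,
) -> list[TherapyOption]:
    """Propose same-pathway combination options.

    For every pathway hit by two or more distinct-gene findings that each
    already have at least one monotherapy option, one combination option is
    emitted pairing the best-evidence drug per finding. When the involved
    roles differ (upstream vs downstream) the rationale is
    ``combination_same_pathway``; when all findings hit same-role members
    (parallel arms) it is ``combination_parallel_arms``.
    """
    by_target: dict[tuple, list[TherapyOption]] = {}
    for opt in options:
        if len(opt.drugs) == 1:
            for t in opt.targets:
                by_target.setdefault(t.key, []).append(opt)

    combos: list[TherapyOption] = []
    samples = sorted({f.sample_id for f in findings})
    for sample in samples:
        sample_findings = [f for f in findings if f.sample_id == sample and f.key in by_target]
        for pathway, members in pathways.items():
            role_of = dict(members)
            hits: dict[str, Finding] = {}
            for f in sample_findings:
                if f.gene in role_of and f.gene not in hits:
                    hits[f.gene] = f
            if len(hits) < 2:
                continue
            chosen: list[tuple[Finding, TherapyOption]] = []
            for gene in sorted(hits):
                f = hits[gene]
                best = min(by_target[f.key], key=lambda o: (o.evidence_rank, o.drugs))
                chosen.append((f, best))
            drugs = tuple(dict.fromkeys(o.drugs[0] for _, o in chosen))
            if len(drugs) < 2:
                continue  # one drug covering both targets is not a combination
            roles = {role_of[f.gene] for f, _ in chosen}
            rationale = (
                "combination_parallel_arms" if len(roles) == 1 else "combination_same_pathway"
            )
            trial_ids = tuple(
                dict.fromkeys(t for _, o in chosen for t in o.trial_ids)
            )
            level = EVIDENCE_LEVELS[max(o.evidence_rank for _, o in chosen)]
            combos.append(
                TherapyOption(
                    sample_id=sample,
                    drugs=drugs,
                    targets=tuple(f for f, _ in chosen),
                    evidence_level=level,
                    trial_ids=trial_ids,
                    rationale=rationale,
                )
            )
    return combos


def compute_burden(
    variants: list[SomaticVariant],
    sample_id: str,
    cohort_median: float,
    mmr_genes,
    floor: int = HYPERMUTATION_FLOOR,
    fold: float = HYPERMUTATION_FOLD,
) -> MutationBurden:
    """Count exonic SNVs for one sample and flag hypermutation + MMR hits."""
    from .ingest import EXONIC_CONSEQUENCES

    sample_vars = [v for v in variants if v.sample_id == sample_id]
    count = sum(1 for v in sample_vars if v.consequence in EXONIC_CONSEQUENCES)
    threshold = max(floor, fold * cohort_median)
    mmr_hits = tuple(
        Finding(
            sample_id=sample_id,
            gene=v.gene,
            finding_type="indel" if v.is_indel else "snv",
            variant_spec=v.variant_spec or f"{v.ref}>{v.alt}",
        )
        for v in sample_vars
        if v.gene in mmr_genes and v.consequence in MMR_DISRUPTING
    )
    return MutationBurden(
        sample_id=sample_id,
        exonic_snv_count=count,
        hypermutant=count > threshold,
        mmr_hits=mmr_hits,
    )


def apply_hypermutation_rule(
    burden: MutationBurden, kb: KnowledgeBase
) -> TherapyOption | None:
    """Checkpoint-inhibitor option for hypermutant samples with an MMR hit.

    Both conditions are required: burden above threshold *and* at least one
    disrupted mismatch-repair gene. Drugs come from the knowledge base's
    ``TMB_HIGH`` rows.
    """
    if not (burden.hypermutant and burden.mmr_hits):
        return None
    assocs = query_drugs(kb, "TMB_HIGH", "snv")
    if not assocs:
        return None
    target = Finding(
        sample_id=burden.sample_id,
        gene="TMB_HIGH",
        finding_type="burden",
        variant_spec="High mutation burden",
    )
    drugs = tuple(dict.fromkeys(a.drug for a in assocs))
    trial_ids = tuple(dict.fromkeys(t for a in assocs for t in a.trial_ids))
    level = EVIDENCE_LEVELS[min(a.evidence_rank for a in assocs)]
    return TherapyOption(
        sample_id=burden.sample_id,
        drugs=drugs,
        targets=(target,) + burden.mmr_hits,
        evidence_level=level,
        trial_ids=trial_ids,
        rationale="hypermutation_checkpoint",
    )


def rank_therapies(options: list[TherapyOption]) -> list[TherapyOption]:
    """Stable sort: strongest evidence first, then best target tier, then drug name."""

    def best_tier(opt: TherapyOption) -> int:
        tiers = [t.tier for t in opt.targets if t.tier is not None]
        return min(tiers) if tiers else 5

    ranked = sorted(options, key=lambda o: (o.evidence_rank, best_tier(o), o.drugs))
    return [
        TherapyOption(
            sample_id=o.sample_id,
            drugs=o.drugs,
            targets=o.targets,
            evidence_level=o.evidence_level,
            trial_ids=o.trial_ids,
            rationale=o.rationale,
            rank=i + 1,
        )
        for i, o in enumerate(ranked)
    ]


_TYPE_BUCKET = {
    "snv": "SNV",
    "indel": "Indel",
    "cnv_gain": "CNV",
    "cnv_loss": "CNV",
    "sv": "SV",
}


def summarize_association_types(options: list[TherapyOption]) -> dict[str, float]:
    """Fraction of therapy associations attributable to SNV/CNV/Indel/SV targets.

    Each (option, typed target) pair counts as one association; burden and
    expression targets are untyped and excluded. Returns an all-zero
    distribution for empty input.
    """
    counts: Counter[str] = Counter()
    for opt in options:
        for t in opt.targets:
            bucket = _TYPE_BUCKET.get(t.finding_type)
            if bucket:
                counts[bucket] += 1
    total = sum(counts.values())
    dist = {k: 0.0 for k in ("SNV", "CNV", "Indel", "SV")}
    if total:
        for k in dist:
            dist[k] = counts.get(k, 0) / total
    return dist
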