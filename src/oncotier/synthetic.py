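"""Synthetic GBM-like cohorts with known ground truth, plus observer models.

The generator emulates the statistical structure of a 30-sample glioblastoma
WGS/RNA-seq cohort so that every pipeline stage is testable without external
data:

* tumor purity ~ truncated normal, mean 0.71, SD 0.16, bounds [0.15, 0.95];
* exonic SNV burden ~ lognormal with median 157 (sigma 0.5, giving an IQR
  near 111), with a two-component hypermutant mixture (default 2/30 samples
  drawn uniformly from 1500-6000 exonic SNVs, covering the 1954/5881 scale);
* planted tier-mixture variants whose knowledge-base entries determine their
  intended tier (recorded in the truth tables);
* chr10-style whole-arm losses that include the PTEN analog, EGFR-style
  focal amplifications, CDKN2A-style homozygous deletions;
* paired DNA/RNA VAFs drawn binomially from a shared true VAF at the
  configured depths;
* spiked exon-skipping junctions (a MET exon-11 skip and an EGFRvIII-style
  exon-1-to-8 junction corroborated by a genomic deletion);
* panel observers (gene-space masking, call dropout, germline contamination
  when no matched normal is used) and automated-curator observers (set
  detection probability and false-call rate over a decoy pool).

All generators are pure functions of (config, seed). The genome is a
compact two-chromosome toy model (~50 genes, 8 exons each) at scaled
coordinates; real-genome coordinates are not required by any consumer.

The module also bundles the in-study cohort fixture: 30 samples' key
therapeutic variants with their associated drug strings (spelling variants
preserved verbatim) and clinical-trial identifiers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import Arm, ArmTable
from .ingest import (
    CopyNumberSegment,
    Exon,
    ExpressionTable,
    GeneInfo,
    GeneModel,
    GermlineCallset,
    JunctionTable,
    SomaticVariant,
    StructuralVariantRecord,
    write_cnv_segments,
    write_expression,
    write_gene_model,
    write_germline_vcf,
    write_junctions,
    write_somatic_vcf,
    write_sv,
)
from .concordance import CallSet
from .therapy import Finding

__all__ = [
    "CohortConfig",
    "ObserverConfig",
    "SampleTruth",
    "CohortBundle",
    "build_toy_genome",
    "simulate_cohort",
    "write_cohort",
    "observe_panel",
    "observe_curator",
    "study_cohort_fixture",
    "StudyCohortFixture",
]

# ---------------------------------------------------------------------------
# toy genome

_EXON_LEN = 300
_INTRON_LEN = 700
_N_EXONS = 8
_GENE_SPACING = 10_000

_CHR7_GENES = [
    "EGFR", "MET", "BRAF", "SMO", "CDK4", "MDM2", "KIT", "KDR", "PDGFRA",
    "RPTOR", "MYCN", "POLE", "SETD2", "SMARCA4",
]
_CHR10_GENES = [
    "PTEN", "MGMT", "CDKN2A", "MSH2", "TP53", "PIK3CA", "PIK3R1", "IDH1",
    "NF1", "TSC2", "STAG2", "PALB2", "RB1", "TERT", "POLA1", "MSH6", "MLH1",
    "PMS2", "ATRX", "CIC", "FUBP1",
]
_N_FILLER = 15  # per chromosome


def _lay_genes(chrom: str, names: list[str], strand_cycle: str = "+-") -> dict[str, GeneInfo]:
    genes = {}
    cursor = 5_000
    for i, name in enumerate(names):
        exons = []
        pos = cursor
        for n in range(1, _N_EXONS + 1):
            exons.append(Exon(chrom=chrom, start=pos, end=pos + _EXON_LEN, number=n))
            pos += _EXON_LEN + _INTRON_LEN
        strand = strand_cycle[i % len(strand_cycle)]
        if strand == "-":
            # renumber so exon 1 is the rightmost (biological 5' end)
            exons = [
                Exon(chrom=chrom, start=e.start, end=e.end, number=_N_EXONS - e.number + 1)
                for e in exons
            ]
            exons = sorted(exons, key=lambda e: e.number)
        genes[name] = GeneInfo(gene=name, chrom=chrom, strand=strand, exons=tuple(exons))
        cursor += _GENE_SPACING
    return genes


def build_toy_genome(promoter_window: int = 1000) -> tuple[GeneModel, ArmTable]:
    """Compact two-chromosome genome: ~50 genes, 8 exons each, scaled coordinates."""
    chr7_names = _CHR7_GENES + [f"GENE7_{i:02d}" for i in range(1, _N_FILLER + 1)]
    chr10_names = _CHR10_GENES + [f"GENE10_{i:02d}" for i in range(1, _N_FILLER + 1)]
    genes = {}
    genes.update(_lay_genes("chr7", chr7_names))
    genes.update(_lay_genes("chr10", chr10_names))
    model = GeneModel(genes=genes, promoter_window=promoter_window)

    def arm_pair(chrom: str, names: list[str]) -> list[Arm]:
        end = 5_000 + len(names) * _GENE_SPACING
        mid = end // 2
        return [Arm(chrom, 0, mid, "p"), Arm(chrom, mid, end, "q")]

    arms = ArmTable(arms=arm_pair("chr7", chr7_names) + arm_pair("chr10", chr10_names))
    return model, arms


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort."""

    seed: int
    n_samples: int = 30
    purity_mean: float = 0.71
    purity_sd: float = 0.16
    purity_bounds: tuple[float, float] = (0.15, 0.95)
    snv_median: float = 157.0
    snv_sigma: float = 0.5
    hypermutant_fraction: float = 2 / 30
    hypermutant_range: tuple[int, int] = (1500, 6000)
    # per-candidate-variant tier mixture (remainder: unlisted genes, no tier)
    tier_probs: dict = field(
        default_factory=lambda: {1: 0.01, 2: 0.02, 3: 0.25, 4: 0.22}
    )
    arm_loss_prob: float = 0.8  # chr10-style arm loss incl. PTEN analog
    focal_amp_prob: float = 0.27  # EGFR-style focal amplification
    hom_loss_prob: float = 0.30  # CDKN2A-style homozygous deletion
    dna_depth: float = 80.0
    rna_depth: float = 30.0
    reference_n: int = 169
    germline_per_sample: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.hypermutant_fraction <= 1:
            raise ValueError("hypermutant_fraction must be in [0, 1]")
        for p in (self.arm_loss_prob, self.focal_amp_prob, self.hom_loss_prob):
            if not 0 <= p <= 1:
                raise ValueError("event probabilities must be in [0, 1]")
        if self.purity_bounds[0] >= self.purity_bounds[1]:
            raise ValueError("purity bounds must be ordered")


@dataclass
class ObserverConfig:
    """Panel / curator observer parameters."""

    seed: int
    panel_genes: frozenset[str] = frozenset()
    matched_normal_used: bool = True
    dropout_prob: float = 0.0
    germline_contamination_rate: float = 0.0
    detect_prob: float = 1.0
    false_call_rate: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.germline_contamination_rate,
                  self.detect_prob, self.false_call_rate):
            if not 0 <= p <= 1:
                raise ValueError("observer probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SampleTruth:
    sample_id: str
    purity: float
    ploidy: float
    exonic_snv_count: int
    hypermutant: bool
    variant_tiers: dict = field(default_factory=dict)  # key -> intended tier (int|None)
    cnv_classes: list = field(default_factory=list)  # (chrom,start,end,class,focality)
    psi_events: list = field(default_factory=list)  # (gene, donor, acceptor, true_psi)


@dataclass
class CohortBundle:
    config: CohortConfig
    model: GeneModel
    arms: ArmTable
    variants: dict  # sample -> list[SomaticVariant]
    germline: dict  # sample -> GermlineCallset
    segments: dict  # sample -> list[CopyNumberSegment]
    svs: list  # list[StructuralVariantRecord]
    expression: ExpressionTable
    reference_expression: ExpressionTable
    junctions: JunctionTable
    rna_support: dict  # sample -> list[(variant_key, alt_reads, total_reads, dna_vaf)]
    truth: dict  # sample -> SampleTruth

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.truth)


_TIER1_SPECS = [("IDH1", "R132H"), ("BRAF", "V600E")]
_TIER2_SPECS = [("TP53", "R175H"), ("TP53", "R273C"), ("PIK3CA", "E542K")]
# actionable genes carrying drugs but no exact-variant evidence for a VUS spec
_TIER3_GENES = [
    "EGFR", "PTEN", "PIK3CA", "PIK3R1", "MET", "PDGFRA", "KIT", "KDR", "SMO",
    "NF1", "MDM2", "CDK4", "RPTOR", "TSC2", "STAG2", "MYCN",
]
# cancer-census genes that are not in the actionable set
_TIER4_GENES = ["MSH2", "MSH6", "MLH1", "PMS2", "POLE", "POLA1", "ATRX", "CIC",
                "FUBP1", "SMARCA4", "SETD2"]

_BASES = "ACGT"


def _random_spec(rng: np.random.Generator) -> str:
    aa = "ARNDCQEGHILKMFPSTWYV"
    return (
        aa[rng.integers(len(aa))]
        + str(int(rng.integers(30, 900)))
        + aa[rng.integers(len(aa))]
    )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def _exon_position(rng: np.random.Generator, gene: GeneInfo) -> int:
    e = gene.exons[rng.integers(len(gene.exons))]
    return int(rng.integers(e.start, e.end)) + 1  # 1-based


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full cohort bundle, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    model, arms = build_toy_genome()
    gene_names = list(model.genes)
    filler = [g for g in gene_names if g.startswith("GENE")]

    n_hyper = int(round(config.hypermutant_fraction * config.n_samples))
    hyper_idx = set(rng.choice(config.n_samples, size=n_hyper, replace=False).tolist())

    # shared reference expression cohort (TCGA-style)
    base_tpm = rng.lognormal(mean=3.0, sigma=1.0, size=len(gene_names))
    ref = np.maximum(
        0.0,
        base_tpm[:, None]
        * rng.lognormal(mean=0.0, sigma=0.3, size=(len(gene_names), config.reference_n)),
    )
    reference_expression = ExpressionTable(
        tpm=pd.DataFrame(
            ref, index=gene_names,
            columns=[f"REF{i + 1:03d}" for i in range(config.reference_n)],
        )
    )

    variants: dict = {}
    germline: dict = {}
    segments: dict = {}
    svs: list[StructuralVariantRecord] = []
    truth: dict = {}
    rna_support: dict = {}
    junction_rows = []
    tumor_tpm = {}

    tier_items = sorted(config.tier_probs.items())
    tier_p = np.array([p for _, p in tier_items])
    if tier_p.sum() > 1:
        raise ValueError("tier probabilities sum above 1")

    for si in range(config.n_samples):
        sample = f"SIM{si + 1:03d}"
        purity = _truncnorm(
            rng, config.purity_mean, config.purity_sd, *config.purity_bounds
        )
        ploidy = 2.0
        hyper = si in hyper_idx
        if hyper:
            n_snv = int(rng.integers(config.hypermutant_range[0], config.hypermutant_range[1]))
        else:
            n_snv = max(
                5, int(round(config.snv_median * rng.lognormal(0.0, config.snv_sigma)))
            )

        st = SampleTruth(
            sample_id=sample, purity=purity, ploidy=ploidy,
            exonic_snv_count=n_snv, hypermutant=hyper,
        )
        sample_vars: list[SomaticVariant] = []
        support: list = []
        used_pos: set = set()

        # which tier does each exonic SNV get?
        draws = rng.random(n_snv)
        for vi in range(n_snv):
            x = draws[vi]
            tier = None
            acc = 0.0
            for t, p in tier_items:
                acc += p
                if x < acc:
                    tier = t
                    break
            if tier == 1:
                gene_name, spec = _TIER1_SPECS[int(rng.integers(len(_TIER1_SPECS)))]
                consequence = "missense"
            elif tier == 2:
                gene_name, spec = _TIER2_SPECS[int(rng.integers(len(_TIER2_SPECS)))]
                consequence = "missense"
            elif tier == 3:
                gene_name = _TIER3_GENES[int(rng.integers(len(_TIER3_GENES)))]
                spec = _random_spec(rng)
                consequence = "missense"
            elif tier == 4:
                gene_name = _TIER4_GENES[int(rng.integers(len(_TIER4_GENES)))]
                spec = _random_spec(rng)
                consequence = str(
                    rng.choice(["missense", "nonsense", "frameshift"], p=[0.6, 0.25, 0.15])
                )
            else:
                gene_name = filler[int(rng.integers(len(filler)))]
                spec = _random_spec(rng)
                consequence = "missense"
            g = model.genes[gene_name]
            pos = _exon_position(rng, g)
            while (g.chrom, pos) in used_pos:
                pos = _exon_position(rng, g)
            used_pos.add((g.chrom, pos))
            ref_b = _BASES[int(rng.integers(4))]
            alt_b = _BASES[(_BASES.index(ref_b) + 1 + int(rng.integers(3))) % 4]
            if consequence == "frameshift":
                alt_b = ref_b + _BASES[int(rng.integers(4))]
            true_vaf = min(0.95, 0.5 * purity * float(rng.uniform(0.7, 1.1)))
            depth = max(20, int(rng.poisson(config.dna_depth)))
            alt_n = int(rng.binomial(depth, true_vaf))
            v = SomaticVariant(
                chrom=g.chrom, pos=pos, ref=ref_b, alt=alt_b, gene=gene_name,
                consequence=consequence, vaf=alt_n / depth, depth=depth,
                sample_id=sample, variant_spec=spec,
            )
            sample_vars.append(v)
            st.variant_tiers[v.key] = tier
            # paired RNA support from the same true VAF
            if tier in (1, 2, 3):
                rna_total = int(rng.poisson(config.rna_depth))
                rna_alt = int(rng.binomial(rna_total, true_vaf)) if rna_total else 0
                support.append((v.key, rna_alt, rna_total, v.vaf))

        # germline variants (never at somatic positions)
        gl: dict = {}
        for _ in range(config.germline_per_sample):
            gene_name = gene_names[int(rng.integers(len(gene_names)))]
            g = model.genes[gene_name]
            pos = _exon_position(rng, g)
            while (g.chrom, pos) in used_pos:
                pos = _exon_position(rng, g)
            used_pos.add((g.chrom, pos))
            ref_b = _BASES[int(rng.integers(4))]
            alt_b = _BASES[(_BASES.index(ref_b) + 1 + int(rng.integers(3))) % 4]
            hom = rng.random() < 0.2
            gl[(g.chrom, pos, ref_b, alt_b)] = 1.0 if hom else 0.5
        germline[sample] = GermlineCallset(sample_id=sample, calls=gl)

        # copy-number segments: baseline neutral + event menu
        segs: list[CopyNumberSegment] = []

        def mixed(t_cn: float) -> float:
            return purity * t_cn + (1 - purity) * 2.0

        for chrom in ("chr7", "chr10"):
            chrom_arms = [a for a in arms.arms if a.chrom == chrom]
            end = max(a.end for a in chrom_arms)
            if chrom == "chr10" and rng.random() < config.arm_loss_prob:
                # whole-arm single-copy loss of the arm holding the PTEN analog
                pg = model.genes["PTEN"]
                lost = arms.arm_of(pg.chrom, pg.start, pg.end)
                kept = [a for a in chrom_arms if a is not lost][0]
                segs.append(
                    CopyNumberSegment(chrom, kept.start, kept.end, mixed(2.0), sample)
                )
                segs.append(
                    CopyNumberSegment(chrom, lost.start, lost.end, mixed(1.0), sample)
                )
                st.cnv_classes.append(
                    (chrom, lost.start, lost.end, "heterozygous_loss", "arm_level")
                )
            else:
                segs.append(CopyNumberSegment(chrom, 0, end, mixed(2.0), sample))
        pten = model.genes["PTEN"]
        egfr = model.genes["EGFR"]
        cdkn2a = model.genes["CDKN2A"]
        if rng.random() < config.focal_amp_prob:
            amp_cn = float(rng.uniform(8, 30))
            segs.append(
                CopyNumberSegment(
                    egfr.chrom, egfr.start - 1000, egfr.end + 1000, mixed(amp_cn), sample
                )
            )
            st.cnv_classes.append(
                (egfr.chrom, egfr.start - 1000, egfr.end + 1000,
                 "focal_amplification", "focal")
            )
        if rng.random() < config.hom_loss_prob:
            segs.append(
                CopyNumberSegment(
                    cdkn2a.chrom, cdkn2a.start - 500, cdkn2a.end + 500, mixed(0.0), sample
                )
            )
            st.cnv_classes.append(
                (cdkn2a.chrom, cdkn2a.start - 500, cdkn2a.end + 500,
                 "homozygous_loss", "focal")
            )
        segments[sample] = segs

        # canonical junctions for a few expressed genes + spiked events
        for gene_name in ("MET", "EGFR", "PTEN", "TP53"):
            g = model.genes[gene_name]
            by_coord = sorted(g.exons, key=lambda e: e.start)
            for a, b in zip(by_coord, by_coord[1:]):
                junction_rows.append(
                    (g.chrom, a.end + 1, b.start, int(rng.poisson(50)), sample)
                )
        variants[sample] = sample_vars
        rna_support[sample] = support
        truth[sample] = st

        # tumor expression: reference-like with amplification-driven outliers
        col = np.maximum(
            0.0, base_tpm * rng.lognormal(0.0, 0.3, size=len(gene_names))
        )
        for chrom, s0, e0, cls, _foc in st.cnv_classes:
            factor = {"focal_amplification": 8.0, "homozygous_loss": 0.05,
                      "heterozygous_loss": 0.6}[cls]
            for gi, gene_name in enumerate(gene_names):
                g = model.genes[gene_name]
                if g.chrom == chrom and g.start < e0 and s0 < g.end:
                    col[gi] *= factor
        tumor_tpm[sample] = col

    # spiked splice events in the first two samples
    s_ids = sorted(truth)
    met = model.genes["MET"]
    met_coord = sorted(met.exons, key=lambda e: e.start)
    # MET exon-11-like skip: toy model has 8 exons, skip exon 4 analogously
    skip_target = met_coord[3]
    left, right = met_coord[2], met_coord[4]
    alt_reads = 30
    junction_rows.append((met.chrom, left.end + 1, right.start, alt_reads, s_ids[0]))
    truth[s_ids[0]].psi_events.append(("MET", left.end + 1, right.start, None))

    # EGFRvIII-style exon 1->8 junction + corroborating genomic DEL
    egfr = model.genes["EGFR"]
    by_num = {e.number: e for e in egfr.exons}
    e1, e8 = by_num[1], by_num[_N_EXONS]
    lo_e, hi_e = (e1, e8) if e1.start < e8.start else (e8, e1)
    junction_rows.append((egfr.chrom, lo_e.end + 1, hi_e.start, 32, s_ids[1]))
    truth[s_ids[1]].psi_events.append(("EGFR", lo_e.end + 1, hi_e.start, None))
    svs.append(
        StructuralVariantRecord(
            chrom_a=egfr.chrom, pos_a=lo_e.end + 2, strand_a="+",
            chrom_b=egfr.chrom, pos_b=hi_e.start - 1, strand_b="-",
            sv_type="DEL", genes_hit=("EGFR",), sample_id=s_ids[1], caller="delly",
        )
    )

    junctions = JunctionTable(
        rows=pd.DataFrame(
            junction_rows,
            columns=["chrom", "donor_pos", "acceptor_pos", "read_count", "sample_id"],
        )
    )
    expression = ExpressionTable(
        tpm=pd.DataFrame(tumor_tpm, index=gene_names)[sorted(tumor_tpm)]
    )
    return CohortBundle(
        config=config, model=model, arms=arms, variants=variants,
        germline=germline, segments=segments, svs=svs, expression=expression,
        reference_expression=reference_expression, junctions=junctions,
        rna_support=rna_support, truth=truth,
    )


def write_cohort(bundle: CohortBundle, outdir: Path | str) -> Path:
    """Write the bundle in the pipeline's on-disk formats (deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_segs = []
    for sample in bundle.sample_ids:
        write_somatic_vcf(bundle.variants[sample], outdir / f"{sample}.somatic.vcf")
        write_germline_vcf(bundle.germline[sample], outdir / f"{sample}.germline.vcf")
        all_segs.extend(bundle.segments[sample])
    write_cnv_segments(all_segs, outdir / "segments.tsv")
    write_expression(bundle.expression, outdir / "expression.tsv")
    write_expression(bundle.reference_expression, outdir / "reference_expression.tsv")
    write_junctions(bundle.junctions, outdir / "junctions.tsv")
    write_gene_model(bundle.model, outdir / "gene_model.tsv")
    bundle.arms.write(outdir / "arms.tsv")
    write_sv(bundle.svs, outdir / "svs.tsv")
    purity = pd.DataFrame(
        [
            (s, bundle.truth[s].purity, bundle.truth[s].ploidy)
            for s in bundle.sample_ids
        ],
        columns=["sample", "purity", "ploidy"],
    )
    purity.to_csv(outdir / "purity.tsv", sep="\t", index=False)
    tiers = pd.DataFrame(
        [
            (s, *key, "" if tier is None else tier)
            for s in bundle.sample_ids
            for key, tier in bundle.truth[s].variant_tiers.items()
        ],
        columns=["sample", "chrom", "pos", "ref", "alt", "intended_tier"],
    )
    tiers.to_csv(outdir / "truth_tiers.tsv", sep="\t", index=False)
    return outdir


# ---------------------------------------------------------------------------
# observer models


def observe_panel(
    truth_calls, germline_calls, observer: ObserverConfig, case_id: str
) -> CallSet:
    """Simulate a targeted panel's view of a case's true somatic calls.

    Calls outside the panel gene space are invisible; visible calls drop out
    with ``dropout_prob``. Without a matched normal, each germline call leaks
    into the report as an apparent somatic call with
    ``germline_contamination_rate``. Deterministic given ``observer.seed``.
    """
    rng = np.random.default_rng(observer.seed)
    kept = []
    for key in sorted(truth_calls):
        gene = key[0] if isinstance(key, tuple) else key
        if observer.panel_genes and gene not in observer.panel_genes:
            continue
        if rng.random() < observer.dropout_prob:
            continue
        kept.append(key)
    if not observer.matched_normal_used:
        for key in sorted(germline_calls):
            if rng.random() < observer.germline_contamination_rate:
                kept.append(key)
    return CallSet(
        case_id=case_id,
        calls=frozenset(kept),
        source="panel",
        matched_normal_used=observer.matched_normal_used,
    )


def observe_curator(
    truth_calls, detect_prob: float, false_call_rate: float, decoy_pool, seed: int,
    case_id: str = "case",
) -> CallSet:
    """Simulate an automated curator: keep truth calls with ``detect_prob``,
    add decoys with ``false_call_rate``. Decoys must be disjoint from truth."""
    truth_set = set(truth_calls)
    decoys = sorted(set(decoy_pool))
    if truth_set & set(decoys):
        raise ValueError("decoy pool overlaps the truth set")
    rng = np.random.default_rng(seed)
    kept = [k for k in sorted(truth_set) if rng.random() < detect_prob]
    kept += [d for d in decoys if rng.random() < false_call_rate]
    return CallSet(case_id=case_id, calls=frozenset(kept), source="curator")


# ---------------------------------------------------------------------------
# in-study cohort fixture

_FIXTURE_SHA256 = {
    "study_variants.tsv": "dd6b8a642927d9cd67676aaa9ac21f13db3f6367bb62b098eff55dfc75f28af4",
    "study_drugs.tsv": "1265c988d0bf3f841204a32b3b1e998794d851d1c852cdae0b74875a8b9ee578",
    "tier_exemplars.tsv": "3802294a28823fde0608eb9083a6d67704e5247da727c8f89ca60747c8d0f50c",
}


class FixtureIntegrityError(RuntimeError):
    """A bundled fixture file does not match its recorded checksum."""


@dataclass
class StudyCohortFixture:
    """The 30-sample key-variant fixture with verbatim drug/trial strings."""

    findings: dict  # sample -> list[Finding]
    drugs_raw: dict  # sample -> list of raw drug strings (verbatim)
    trials: dict  # sample -> list of trial-id strings (verbatim)
    tier_exemplars: list  # [(gene, variant_spec), ...]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.findings)


def _fixture_path(name: str) -> Path:
    path = Path(str(resources.files("oncotier").joinpath(f"data/{name}")))
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(f"{name}: checksum mismatch ({digest})")
    return path


def study_cohort_fixture() -> StudyCohortFixture:
    """Load the bundled 30-sample fixture (verbatim drugs, trials, typed variants)."""
    vdf = pd.read_csv(_fixture_path("study_variants.tsv"), sep="\t")
    ddf = pd.read_csv(_fixture_path("study_drugs.tsv"), sep="\t")
    xdf = pd.read_csv(_fixture_path("tier_exemplars.tsv"), sep="\t")

    findings: dict = {}
    for row in vdf.itertuples(index=False):
        findings.setdefault(row.sample, []).append(
            Finding(
                sample_id=str(row.sample),
                gene=str(row.gene).upper(),
                finding_type=str(row.finding_type),
                variant_spec=str(row.variant_spec),
            )
        )
    drugs_raw = {r.sample: str(r.drugs).split("|") for r in ddf.itertuples(index=False)}
    trials = {r.sample: str(r.trials).split() for r in ddf.itertuples(index=False)}
    exemplars = [(str(r.gene), str(r.variant_spec)) for r in xdf.itertuples(index=False)]
    return StudyCohortFixture(
        findings=findings, drugs_raw=drugs_raw, trials=trials, tier_exemplars=exemplars
    )
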