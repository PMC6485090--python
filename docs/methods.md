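# Methods

This note documents the models, thresholds and design choices behind
`oncotier`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Tiering model

Somatic SNVs/indels are assigned exactly one tier with precedence
1 > 2 > 3 > 4 > none:

1. **Tier 1** — an exact (gene, variant_spec) evidence row with
   significance `clinically_significant` and disease equal to the study
   disease (pipeline config, default `glioblastoma`).
2. **Tier 2** — the same, but the evidence disease differs.
3. **Tier 3** — no exact-variant evidence, gene in the `actionable_genes`
   set, and the gene carries at least one drug association. Any association
   qualifies the gene, including gain/loss-scoped ones: a missense VUS in a
   gene whose drugs are amplification-directed still marks the gene
   actionable, which matches how curators treat e.g. *EGFR* point variants.
4. **Tier 4** — otherwise, gene in the `cancer_census` set.

Evidence matching is exact string comparison on the variant label (R132H,
V600E, "amplification") after whitespace/case normalization — no HGVS
parsing. The precedence rule makes tiers disjoint: a gene qualifying for
Tier 3 can never land in Tier 4, so Tier 4 is census-only genes by
construction.

Candidate selection keeps exonic consequence classes (missense, nonsense,
frameshift, in-frame indel) and splice-site variants; synonymous variants
are excluded by default (configurable). Promoter candidates are positional:
a variant within the promoter window — default 1,000 bp upstream of the
annotated transcription start, configurable — of a promoter-listed gene
(default list: *TERT*). The window size is a convention choice; no standard
width exists for promoter calling.

**Low-VAF rescue.** Variants with VAF ≥ 0.15 pass outright. Variants below
0.15 are retained (flagged `rescue_flag`) when the gene is in the cancer
census set and total depth is ≥ 40 reads; others are dropped. The boundary
is inclusive at 0.15 because the rule drops *below-threshold* calls. This
mirrors manual review of likely subclonal drivers in impure tumors.

## RNA annotation

The modified z-score is z = (TPM − median_ref) / MAD_ref per gene, where
the reference statistics are the median and **raw** median absolute
deviation of TPM over a reference cohort of the same tumor type. The
1.4826 normal-consistency constant is deliberately not applied; the score
is a robust distance in MAD units, not an estimate of normal SDs. Genes
with MAD = 0 (unexpressed or constant in the reference) get an *undefined*
z rather than ±∞, and are reported flagged — this avoids promoting every
nonzero observation in a silent gene to an infinite outlier. The |z| ≥ 2
outlier flag is report highlighting only; no downstream rule consumes it.

Variant-level RNA support requires ≥ 5 total reads over the locus
("sufficient"); only sufficient records enter the DNA–RNA VAF Pearson
correlation. The correlation's p-value (t approximation) is reported but
never gates anything. Read counting from alignments is out of scope; the
synthetic generator supplies counts directly.

## Splicing

PSI uses the literal ratio convention, PSI = 100 · alt / canonical, where
`canonical` is the read count of the single annotated junction sharing the
event's **donor** site (falling back to the acceptor when the donor is not
an annotated boundary). This ratio can exceed 100 %; the more common
inclusion convention alt/(alt+canonical) is available behind
`psi_convention="inclusion"`. When canonical coverage is zero but
alternative reads exist, PSI is undefined-high: the event is still emitted,
flagged `saturated`. Events are reported when PSI is strictly above 10 %
and the gene is in the cancer-census set.

Exon skipping: any junction joining the 3′ boundary of exon *i* to the 5′
boundary of exon *j* with |j − i| > 1 and ≥ 5 supporting reads (the same
floor as RNA variant sufficiency) yields an event whose skipped exons are
those strictly between. Exon numbering follows the gene model's strand, so
minus-strand genes are handled by number, not coordinate. A same-sample
genomic deletion corroborates an event only when it overlaps **every**
skipped exon; partial overlap does not count.

## Copy-number model

Observed copy number in a sample with tumor purity ρ is modeled as the
two-population mixture obs = ρ·cn_tumor + (1−ρ)·2. Correction inverts this,
floored at zero; the inversion is exact (re-mixing recovers the observation
to 1e-9) wherever flooring did not apply. Purity and ploidy are *inputs* —
their estimation is out of scope.

Classification of corrected cn uses ±0.5 bands around integer states:
homozygous loss < 0.5 ≤ het loss < 1.5; amplification at ≥ 5 copies (the
five-copy line separates first-class amplifications from second-class
gains); the copy-neutral band is ±0.5 around the **sample ploidy**, not
around 2, so hyperploid genomes are not called gained genome-wide. A
segment is arm-level when it covers ≥ 50 % of its arm (the common
convention; published "arm-scale vs focal" phrasing comes with no number),
else focal. Priority ranks: 1 = homozygous loss / focal amplification (and
SVs hitting actionable genes), 2 = focal gain or focal het loss,
3 = arm-level gain or het loss, neutral unranked. Rank-3 findings are
included by default; `include_low_priority=False` emulates stricter
automated scopes that skip sub-5-copy gains and heterozygous losses.

## Therapy matching

Drug associations have four ordered evidence levels
(`approved_in_disease` > `approved_other_disease` > `clinical_trial` >
`preclinical`) — a repository convention, since published descriptions of
"strongest to weakest" evidence rarely enumerate their levels. Matching
rules: `any_alteration` rows match every alteration class; `gain`/`loss`
rows match their class; `specific_variant` rows require an exact spec
match. Tier-4-only SNVs emit nothing. Options are deduplicated on
(sample, drug, target); the same drug may appear once per distinct target.

Combinations: for each pathway in the bundled map (PI3K/AKT/mTOR, RTK/RAS/
RAF, CDK4/RB, p53/MDM2, SMO/GLI) hit by ≥ 2 distinct-gene findings that
each already have a monotherapy option, one combination option pairs the
best-evidence drug per finding. Differing member roles (upstream vs
downstream) give rationale `combination_same_pathway`; same-role members
give `combination_parallel_arms`.

Hypermutation rule: a sample is hypermutant when its exonic SNV count
exceeds max(1000, 5 × cohort median); both thresholds configurable. The
checkpoint-inhibitor option requires hypermutation **and** ≥ 1 disrupted
mismatch-repair gene (nonsense, frameshift or splice-site variant, or
homozygous loss, in MSH2/MSH6/MLH1/PMS2/POLE) — the conjunction is a design
choice; requiring either alone would fire on burden noise or on isolated
MMR passengers. Checkpoint drugs are ordinary knowledge-base rows under the
pseudo-gene key `TMB_HIGH`, keeping the matcher uniform. A `targeted_only`
switch drops chemo-/immunotherapy rows to emulate automated curators
restricted to molecularly targeted agents.

Ranking is a stable sort by evidence level, then best target tier, then
drug name; input order breaks remaining ties, so equal-evidence options
never reorder.

## Concordance

Call keys come in three granularities: `variant` (gene + variant label),
`gene` (collapses all alterations of a gene) and `drug_target` (normalized
drug names). Panel comparisons default to variant level; curator
comparisons are computed at both variant and drug_target level, since the
two views answer different questions ("same calls?" vs "same treatment
implications?"). Whether published per-case comparisons are variant- or
gene-granular is usually unstated; both are supported.

Germline miscalls are audited only for panels run **without** a matched
normal: a panel call whose key appears in the case's germline callset with
germline VAF ≥ 0.25 is flagged. Sensitivity = |truth ∩ test|/|truth| and
PPV = |truth ∩ test|/|test|; an empty truth or test set makes the
respective statistic undefined (None), and undefined rows are excluded
from cohort means and counted separately. SDs use the n−1 denominator
(small cohorts). The actionability-gain rate is the fraction of compared
cases with ≥ 1 WGS-unique call.

## Synthetic cohort

The generator's defaults are the study conditions, not tuning knobs:
30 samples; purity from a truncated normal (mean 0.71, SD 0.16, bounds
0.15–0.95); exonic SNV count lognormal around median 157 with σ = 0.5
(chosen so the IQR/median ratio ≈ 0.7, matching an IQR near 111), with a
2/30 hypermutant component drawn uniformly from 1,500–6,000; chr10-style
whole-arm loss containing the PTEN analog with probability 0.8 (≈ 24/30);
EGFR-style focal amplification at 0.27 (≈ 8/30); CDKN2A-style homozygous
deletion at 0.30. DNA and RNA allele fractions are binomial draws from a
shared true VAF (clonal heterozygous scaled by purity) at Poisson depths
80 (DNA) and 30 (RNA). Planted variants draw from a tier mixture whose
(gene, spec) pairs determine the intended tier against the bundled
knowledge base; the truth tables record every intended label, CNV class and
spiked splice event (a MET exon-skip and an EGFRvIII-style exon-1→8
junction with a corroborating genomic deletion).

The genome is a compact two-chromosome model (~50 genes of 8 × 300 bp
exons at scaled coordinates). What the generator does **not** emulate:
mutational signatures, read-level artifacts, segmentation noise, subclonal
architecture, gene-length variation, or linkage between events. Passing
tests therefore demonstrate the correctness of the interpretation logic
under the stated statistical structure — not calling performance on real
sequencing data.

The bundled 30-sample cohort fixture stores drug strings verbatim,
spelling variants intact, so that name normalization (case-fold,
hyphen/whitespace strip, alias table for the known misspellings) is
exercised end to end; the alias table is data (`data/kb/drug_aliases.tsv`),
not code.

## Numerical and degenerate-input choices

* Division-by-zero cases never produce infinities: MAD = 0 → undefined z;
  zero canonical reads → saturated PSI; empty truth/test sets → undefined
  sensitivity/PPV; < 3 pairs or zero variance → undefined correlation.
* VAF precedence when reading VCFs: explicit AF tag, then AD-derived
  (alt/(ref+alt) per allele, multiallelic sites split); records with
  neither are skipped with a logged count.
* Coordinates: VCF records, junctions and SV breakpoints are 1-based;
  segments and exon models are 0-based half-open. Junctions are stored
  unstranded (donor < acceptor by coordinate).
* Problem sizes: the default test cohort is 30 samples (~200 variants per
  sample, two hypermutants at a few thousand); burden-distribution checks
  use a 200-sample cohort; oracle-equivalence checks use 1,000 random
  small instances per statistic and the curator-recovery check 200 cases.
  These sizes make the whole suite run in well under a minute while keeping
  every statistical check comfortably powered.

## Known limitations

* Evidence matching is string-exact; variants described at different
  nomenclature levels (c. vs p.) will not unify.
* The bundled knowledge base is a compact curated table assembled for the
  packaged cohort, not a mirror of any live database; real deployments
  should load their own TSVs via `load_kb`.
* CNV "tiers" are expressed as priority ranks, not Tiers 1–4; only SNVs and
  indels are tiered.
* Fusion discovery, purity/ploidy estimation, alignment and variant calling
  are out of scope: their outputs are inputs here.
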