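# oncotier

Somatic variant actionability tiering and therapy matching for glioblastoma
WGS/RNA-seq cohorts.

`oncotier` re-implements, as a reusable and testable pipeline, the manual
curation workflow used to turn a tumor/normal whole-genome plus RNA-seq
profile into a tumor-board packet: which somatic alterations are clinically
meaningful, what the RNA says about them, and which drugs (and trials) they
point to. It is written for bioinformaticians who need a transparent,
scriptable reference for this kind of interpretation logic — every rule is a
small pure function with an explicit threshold, not an opaque annotation
service.

## What it computes

**Tiering.** Candidate somatic SNVs/indels (exonic, splice-site, and
promoter-window variants of promoter-listed genes such as *TERT*) are
classified against a clinical-evidence knowledge base with strict
precedence:

| Tier | Definition |
|------|------------|
| 1 | exact-variant evidence of clinical significance in the study disease |
| 2 | exact-variant evidence of clinical significance in another tumor type |
| 3 | VUS in an actionable gene carrying at least one drug association |
| 4 | VUS in a cancer-census gene |

A low-VAF rescue keeps sub-threshold calls (VAF < 15 %) in known cancer
genes when total depth ≥ 40 reads.

**RNA annotation.** Per-gene expression outliers use a modified z-score
against a reference cohort, z = (TPM − median_ref) / MAD_ref with the *raw*
median absolute deviation (no 1.4826 constant). Variant-level RNA support
(≥ 5 reads) feeds a DNA–RNA VAF Pearson correlation.

**Splicing.** Percent spliced in for an unannotated junction is the literal
ratio PSI = 100 · alt_reads / canonical_reads (the canonical denominator is
the annotated junction sharing the donor site). Junctions joining exon *i*
to exon *j* with *j* > *i*+1 are exon-skipping events (an EGFRvIII-style
exon-1→8 junction skips exons 2–7) and can be corroborated by a genomic
deletion spanning all skipped exons.

**CNV/SV prioritization.** Observed copy number is purity-corrected by
inverting the tumor/normal mixture, cn = (obs − 2(1−ρ))/ρ, then classified
(homozygous loss < 0.5; het loss < 1.5; neutral band ±0.5 around sample
ploidy; amplification ≥ 5 copies) and ranked: two-copy losses and focal
amplifications first, focal gains/losses second, arm-level events third.

**Therapy matching.** Tier 1–3 SNVs, prioritized CNVs and actionable SVs are
matched to a gene–drug knowledge base with evidence levels and NCT trial
ids; same-pathway combinations are proposed (e.g. an upstream RTK gain plus
downstream suppressor loss); hypermutant samples (exonic SNV count above
max(1000, 5 × cohort median)) with a disrupted mismatch-repair gene receive
checkpoint-inhibitor options.

**Concordance.** Call sets are compared per case: common/unique calls and a
germline-miscall audit for panels without a matched normal, and
sensitivity/PPV of a test curator against a truth curator, with cohort
means/SDs.

A seeded synthetic-cohort generator (`oncotier.synthetic`) reproduces the
statistical structure of a 30-sample GBM cohort (purity ~ N(0.71, 0.16²)
truncated to [0.15, 0.95], lognormal exonic burden with median 157 and rare
hypermutants, chr10-style arm losses, EGFR-style focal amplifications,
binomially coupled DNA/RNA VAFs) with full ground truth, so every stage is
testable offline.

## Worked example

The package bundles a 30-sample cohort fixture (key therapeutic variants,
drug strings verbatim including their spelling variants, trial ids) and a
curated knowledge base. Matching one sample:

```python
from oncotier import load_bundled_kb, study_cohort_fixture
from oncotier.therapy import match_therapies, suggest_combinations, rank_therapies, tier_finding
from oncotier.report import build_sample_report, render_sample_report

kb = load_bundled_kb()
fx = study_cohort_fixture()
findings = [tier_finding(f, kb) for f in fx.findings["GBM4"]]
options = match_therapies(findings, kb)
options += suggest_combinations(options, findings, kb.pathways)
_, text = render_sample_report(build_sample_report("GBM4", findings, rank_therapies(options)))
print(text)
```

prints

```
Sample report: GBM4  (schema 1.0)
============================================================
purity=None  ploidy=None  exonic SNVs=None

Findings (3):
  EGFR gain (cnv_gain)
  PTEN W111C (snv) [Tier 3]
  PTEN whole arm loss (cnv_loss)

Therapy options (9):
  CETUXIMAB  [approved_other_disease; direct_target]  trials: NCT01238237, NCT02573324
  ERLOTINIB  [approved_other_disease; direct_target]  trials: -
  CETUXIMAB + EVEROLIMUS  [clinical_trial; combination_same_pathway]  trials: NCT01238237, NCT02573324, NCT01870726
  EVEROLIMUS  [clinical_trial; direct_target]  trials: NCT01870726
  ...
```

The *EGFR* gain and *PTEN* loss both activate the PI3K/AKT axis, so the
matcher pairs an EGFR-directed antibody with an mTOR inhibitor as a
same-pathway combination, each option tagged with its evidence level and
trials. The same logic is exposed on the command line (`oncotier tier`,
`cnv`, `splice`, `match`, `report`, `simulate`, `compare-panels`,
`compare-curators`, …); CLI output equals the library API on identical
inputs.

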