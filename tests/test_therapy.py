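"""Therapy matching, combinations, hypermutation rule and ranking."""

import pytest

from oncotier.ingest import SomaticVariant
from oncotier.kb import DrugAssociation, KnowledgeBase
from oncotier.therapy import (
    Finding,
    apply_hypermutation_rule,
    compute_burden,
    match_therapies,
    rank_therapies,
    suggest_combinations,
    summarize_association_types,
    tier_finding,
)


def find(gene, ftype, spec="", sample="S1", tier=None):
    return Finding(sample_id=sample, gene=gene, finding_type=ftype,
                   variant_spec=spec, tier=tier)


class TestMatchTherapies:
    def test_egfr_gain_gets_cetuximab_class(self, kb):
        opts = match_therapies([find("EGFR", "cnv_gain", "focal gain")], kb)
        drugs = {d for o in opts for d in o.drugs}
        assert {"CETUXIMAB", "ABT414"} <= drugs
        assert all(o.trial_ids or o.evidence_level for o in opts)

    def test_tier4_only_finding_emits_nothing(self, kb):
        opts = match_therapies([find("MSH2", "snv", "c.366+1G>A", tier=4)], kb)
        assert opts == []

    def test_untier_snv_emits_nothing(self, kb):
        assert match_therapies([find("PTEN", "snv", "R130*")], kb) == []

    def test_empty_findings(self, kb):
        assert match_therapies([], kb) == []

    def test_dedup_same_drug_target(self, kb):
        f = find("PTEN", "cnv_loss", "loss")
        opts = match_therapies([f, f], kb)
        keys = [(o.sample_id, o.drugs, o.targets) for o in opts]
        assert len(keys) == len(set(keys))

    def test_monotone_in_kb(self, kb, fixture30):
        """Adding a drug association never removes an option."""
        findings = [tier_finding(f, kb) for f in fixture30.findings["GBM4"]]
        before = {(o.drugs, o.targets) for o in match_therapies(findings, kb)}
        richer = KnowledgeBase(
            evidence=kb.evidence,
            drugs=kb.drugs
            + [DrugAssociation("PTEN", "any_alteration", "NEWDRUG", "preclinical")],
            gene_sets=kb.gene_sets,
            pathways=kb.pathways,
            drug_aliases=kb.drug_aliases,
        )
        after = {(o.drugs, o.targets) for o in match_therapies(findings, richer)}
        assert before <= after

    def test_closed_world_on_fixture(self, kb, fixture30):
        """Every emitted drug exists in the knowledge base."""
        known = kb.known_drugs()
        for sample, findings in fixture30.findings.items():
            tiered = [tier_finding(f, kb) for f in findings]
            for o in match_therapies(tiered, kb):
                assert set(o.drugs) <= known

    def test_targeted_only_drops_chemo(self, kb):
        opts = match_therapies([find("MGMT", "cnv_loss", "loss")], kb)
        assert any("TEMOZOLOMIDE" in o.drugs for o in opts)
        strict = match_therapies([find("MGMT", "cnv_loss", "loss")], kb,
                                 targeted_only=True)
        assert not any("TEMOZOLOMIDE" in o.drugs for o in strict)


class TestCombinations:
    def test_egfr_gain_plus_pten_loss(self, kb):
        """Upstream RTK gain + downstream suppressor loss -> PI3K-axis combo."""
        findings = [find("EGFR", "cnv_gain", "gain"), find("PTEN", "cnv_loss", "loss")]
        opts = match_therapies(findings, kb)
        combos = suggest_combinations(opts, findings, kb.pathways)
        assert any(
            set(c.drugs) == {"CETUXIMAB", "EVEROLIMUS"}
            and c.rationale == "combination_same_pathway"
            for c in combos
        )

    def test_three_finding_pathway_combo(self, kb):
        findings = [
            find("PTEN", "cnv_loss", "loss"),
            find("MET", "cnv_gain", "gain"),
            tier_finding(find("PIK3R1", "snv", "E443del"), kb),
        ]
        opts = match_therapies(findings, kb)
        combos = suggest_combinations(opts, findings, kb.pathways)
        pi3k = [c for c in combos if len(c.targets) == 3]
        assert pi3k
        drugs = set(pi3k[0].drugs)
        assert "BKM120" in drugs and ("INC280" in drugs or "CRIZOTINIB" in drugs)

    def test_single_finding_no_combination(self, kb):
        findings = [find("EGFR", "cnv_gain", "gain")]
        opts = match_therapies(findings, kb)
        assert suggest_combinations(opts, findings, kb.pathways) == []

    def test_combination_targets_share_a_pathway(self, kb, fixture30):
        all_paths = kb.pathways
        for sample, findings in fixture30.findings.items():
            tiered = [tier_finding(f, kb) for f in findings]
            opts = match_therapies(tiered, kb)
            for c in suggest_combinations(opts, tiered, all_paths):
                genes = {t.gene for t in c.targets}
                assert any(
                    genes <= {g for g, _ in members} for members in all_paths.values()
                )


class TestHypermutation:
    def _burden(self, kb, count, with_mmr):
        mmr = kb.gene_set("mmr_genes").genes
        variants = [
            SomaticVariant("chr10", 1000 + i, "A", "G", "GENE10_01", "missense",
                           0.4, 80, "S1", f"V{i}A")
            for i in range(count)
        ]
        if with_mmr:
            variants.append(
                SomaticVariant("chr10", 50, "G", "A", "MSH2", "splice_site", 0.4,
                               80, "S1", "c.366+1G>A")
            )
        return compute_burden(variants, "S1", cohort_median=157, mmr_genes=mmr)

    def test_hypermutant_with_mmr_hit(self, kb):
        burden = self._burden(kb, 1954, with_mmr=True)
        assert burden.hypermutant and burden.mmr_hits
        opt = apply_hypermutation_rule(burden, kb)
        assert opt is not None
        assert set(opt.drugs) == {"PEMBROLIZUMAB", "NIVOLUMAB"}
        assert opt.rationale == "hypermutation_checkpoint"

    def test_median_burden_no_option(self, kb):
        burden = self._burden(kb, 157, with_mmr=False)
        assert not burden.hypermutant
        assert apply_hypermutation_rule(burden, kb) is None

    def test_high_burden_without_mmr_hit_no_option(self, kb):
        # the rule is a conjunction: both conditions are required
        burden = self._burden(kb, 5881, with_mmr=False)
        assert burden.hypermutant and not burden.mmr_hits
        assert apply_hypermutation_rule(burden, kb) is None


class TestRankTherapies:
    def test_approved_before_trial(self, kb):
        opts = match_therapies(
            [find("KDR", "cnv_gain", "gain"), find("EGFR", "cnv_gain", "gain")], kb
        )
        ranked = rank_therapies(opts)
        # KDR carries an approved-in-disease agent; trials come after
        assert ranked[0].evidence_level == "approved_in_disease"
        levels = [o.evidence_rank for o in ranked]
        assert levels == sorted(levels)

    def test_stability_on_equal_levels(self, kb):
        a = find("PTEN", "cnv_loss", "loss", sample="S1")
        opts = match_therapies([a], kb)
        ranked = rank_therapies(opts)
        same_level = [o for o in ranked if o.evidence_level == "clinical_trial"]
        drugs = [o.drugs for o in same_level]
        assert drugs == sorted(drugs)

    def test_empty(self):
        assert rank_therapies([]) == []


class TestSummarizeAssociationTypes:
    def test_all_snv(self, kb):
        opts = match_therapies([tier_finding(find("PIK3CA", "snv", "V344G"), kb)], kb)
        dist = summarize_association_types(opts)
        assert dist["SNV"] == 1.0

    def test_counting_oracle(self):
        mk = lambda ft, spec: Finding("S1", "EGFR", ft, spec, tier=3)
        opts = [
            # two SNV-target options, one CNV, one SV
            *(
                __import__("oncotier.therapy", fromlist=["TherapyOption"]).TherapyOption(
                    "S1", (d,), (t,), "clinical_trial"
                )
                for d, t in [
                    ("A", mk("snv", "A1B")),
                    ("B", mk("snv", "C2D")),
                    ("C", mk("cnv_gain", "gain")),
                    ("D", mk("sv", "vIII")),
                ]
            )
        ]
        dist = summarize_association_types(opts)
        assert dist == {"SNV": 0.5, "CNV": 0.25, "Indel": 0.0, "SV": 0.25}

    def test_empty_all_zero(self):
        dist = summarize_association_types([])
        assert set(dist.values()) == {0.0}
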