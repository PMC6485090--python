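"""Purity correction, copy-class assignment, focality and prioritization."""

import pytest
from hypothesis import given, strategies as st

from oncotier.cnv import (
    ArmTable,
    classify_segment,
    correct_copy_number,
    genes_in_segment,
    prioritize_findings,
)
from oncotier.ingest import CopyNumberSegment


class TestCorrectCopyNumber:
    def test_mixture_inversion_example(self):
        # mixture oracle: 0.5*6 + 0.5*2 = 4 observed
        assert correct_copy_number(4.0, 0.5) == pytest.approx(6.0)

    def test_pure_tumor_identity(self):
        assert correct_copy_number(3.7, 1.0) == pytest.approx(3.7)

    def test_floored_at_zero(self):
        assert correct_copy_number(1.0, 0.5) == 0.0

    @pytest.mark.parametrize("purity", [0.0, -0.1, 1.5])
    def test_invalid_purity(self, purity):
        with pytest.raises(ValueError):
            correct_copy_number(2.0, purity)

    @given(
        st.floats(min_value=0, max_value=50),
        st.floats(min_value=0.05, max_value=1.0),
    )
    def test_remixing_recovers_observed(self, tumor_cn, purity):
        """correct -> remix is the identity wherever no flooring occurred."""
        observed = purity * tumor_cn + (1 - purity) * 2.0
        corrected = correct_copy_number(observed, purity)
        if corrected > 0:
            remixed = purity * corrected + (1 - purity) * 2.0
            assert remixed == pytest.approx(observed, abs=1e-9)


class TestClassifySegment:
    def test_arm_level_het_loss_chr10_style(self, cohort):
        """A whole-arm single-copy loss containing the PTEN analog."""
        arms = cohort.arms
        pten = cohort.model.genes["PTEN"]
        arm = arms.arm_of(pten.chrom, pten.start, pten.end)
        purity = 0.7
        observed = purity * 1.0 + (1 - purity) * 2.0
        seg = CopyNumberSegment("chr10", arm.start, arm.end, observed, "S1")
        c = classify_segment(seg, purity, 2.0, arms, cohort.model)
        assert c.copy_class == "heterozygous_loss"
        assert c.focality == "arm_level"
        assert c.priority_rank == 3
        assert "PTEN" in c.genes_hit

    def test_focal_homozygous_loss_rank1(self, cohort):
        g = cohort.model.genes["CDKN2A"]
        purity = 0.8
        seg = CopyNumberSegment(g.chrom, g.start - 100, g.end + 100,
                                (1 - purity) * 2.0, "S1")
        c = classify_segment(seg, purity, 2.0, cohort.arms, cohort.model)
        assert c.copy_class == "homozygous_loss"
        assert c.focality == "focal"
        assert c.priority_rank == 1
        assert "CDKN2A" in c.genes_hit

    def test_neutral_at_ploidy_unranked(self, cohort):
        seg = CopyNumberSegment("chr7", 0, 5000, 2.0, "S1")
        c = classify_segment(seg, 1.0, 2.0, cohort.arms)
        assert c.copy_class == "neutral" and c.priority_rank is None

    def test_hyperploid_neutral_band(self, cohort):
        """cn = ploidy in a near-tetraploid genome is neutral, not a gain."""
        seg = CopyNumberSegment("chr7", 0, 5000, 4.0, "S1")
        c = classify_segment(seg, 1.0, 4.0, cohort.arms)
        assert c.copy_class == "neutral"

    def test_amplification_threshold(self, cohort):
        seg = CopyNumberSegment("chr7", 0, 5000, 12.0, "S1")
        c = classify_segment(seg, 1.0, 2.0, cohort.arms)
        assert c.copy_class == "focal_amplification" and c.priority_rank == 1

    def test_monotone_in_corrected_cn(self, cohort):
        """Increasing CN never moves a segment from gain toward loss classes."""
        order = {"homozygous_loss": 0, "heterozygous_loss": 1, "neutral": 2,
                 "gain": 3, "focal_amplification": 4}
        prev = -1
        for cn in [0.0, 0.4, 0.6, 1.2, 1.6, 2.0, 2.6, 3.2, 4.0, 5.0, 9.0]:
            seg = CopyNumberSegment("chr7", 0, 5000, cn, "S1")
            c = classify_segment(seg, 1.0, 2.0, cohort.arms)
            assert order[c.copy_class] >= prev
            prev = order[c.copy_class]


class TestGenesInSegment:
    def test_arm_segment_includes_pten(self, cohort):
        pten = cohort.model.genes["PTEN"]
        arm = cohort.arms.arm_of(pten.chrom, pten.start, pten.end)
        seg = CopyNumberSegment("chr10", arm.start, arm.end, 1.0, "S1")
        assert "PTEN" in genes_in_segment(seg, cohort.model)

    def test_half_open_boundary_excluded(self, cohort):
        g = cohort.model.genes["EGFR"]
        seg = CopyNumberSegment(g.chrom, max(0, g.start - 1000), g.start, 1.0, "S1")
        assert "EGFR" not in genes_in_segment(seg, cohort.model)

    def test_one_bp_overlap_included(self, cohort):
        g = cohort.model.genes["EGFR"]
        seg = CopyNumberSegment(g.chrom, g.start, g.start + 1, 1.0, "S1")
        assert "EGFR" in genes_in_segment(seg, cohort.model)


class TestPrioritizeFindings:
    def _classified(self, cohort):
        egfr = cohort.model.genes["EGFR"]
        arm7p = next(a for a in cohort.arms.arms if a.chrom == "chr7" and a.label == "p")
        focal_amp = classify_segment(
            CopyNumberSegment("chr7", egfr.start, egfr.end, 20.0, "S1"),
            1.0, 2.0, cohort.arms, cohort.model,
        )
        arm_gain = classify_segment(
            CopyNumberSegment("chr7", arm7p.start, arm7p.end, 3.0, "S1"),
            1.0, 2.0, cohort.arms, cohort.model,
        )
        return focal_amp, arm_gain

    def test_focal_amp_outranks_arm_gain(self, cohort):
        focal_amp, arm_gain = self._classified(cohort)
        ranked = prioritize_findings([arm_gain, focal_amp])
        assert ranked[0] is focal_amp

    def test_low_priority_scope_switch(self, cohort):
        focal_amp, arm_gain = self._classified(cohort)
        strict = prioritize_findings([arm_gain, focal_amp], include_low_priority=False)
        assert strict == [focal_amp]

    def test_empty(self):
        assert prioritize_findings([]) == []

    def test_permutation_no_loss_no_duplication(self, cohort):
        focal_amp, arm_gain = self._classified(cohort)
        neutral = classify_segment(
            CopyNumberSegment("chr7", 0, 5000, 2.0, "S1"), 1.0, 2.0, cohort.arms
        )
        ranked = prioritize_findings([arm_gain, neutral, focal_amp])
        assert sorted(id(c) for c in ranked) == sorted(id(c) for c in [arm_gain, focal_amp])
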