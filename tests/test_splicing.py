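"""PSI computation, splice-event calling and exon-skipping detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oncotier.ingest import Exon, GeneInfo, GeneModel, JunctionTable
from oncotier.splicing import (
    call_splice_events,
    compute_psi,
    corroborate_with_sv,
    detect_exon_skipping,
)
from oncotier.ingest import StructuralVariantRecord


def toy_model(n_exons=5, exon_len=100, intron_len=200, gene="MET", strand="+"):
    exons = []
    pos = 1000
    for n in range(1, n_exons + 1):
        exons.append(Exon("chr7", pos, pos + exon_len, n))
        pos += exon_len + intron_len
    if strand == "-":
        exons = [Exon("chr7", e.start, e.end, n_exons - e.number + 1) for e in exons]
        exons = sorted(exons, key=lambda e: e.number)
    g = GeneInfo(gene=gene, chrom="chr7", strand=strand, exons=tuple(exons))
    return GeneModel(genes={gene: g})


def junctions(rows):
    return JunctionTable(
        rows=pd.DataFrame(
            rows, columns=["chrom", "donor_pos", "acceptor_pos", "read_count", "sample_id"]
        )
    )


class TestComputePsi:
    def test_boundary_equals_threshold(self):
        # 5/50 -> exactly 10%, which a strict ">" threshold does not flag
        psi, saturated = compute_psi(5, 50)
        assert psi == 10.0 and not saturated

    def test_zero_alt(self):
        assert compute_psi(0, 50) == (0.0, False)

    def test_flagged_value(self):
        psi, _ = compute_psi(20, 50)
        assert psi == 40.0

    def test_saturated(self):
        psi, saturated = compute_psi(7, 0)
        assert psi is None and saturated

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 10)

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=1, max_value=10_000),
        st.integers(min_value=1, max_value=50),
    )
    def test_scale_invariance(self, alt, canonical, k):
        psi1, _ = compute_psi(alt, canonical)
        psi2, _ = compute_psi(alt * k, canonical * k)
        assert psi2 == pytest.approx(psi1)


class TestCallSpliceEvents:
    def test_hand_computed_ratio(self):
        """e1-e2 canonical 90 reads; e1-e3 alternative 30 reads -> PSI 33.3, skip exon 2."""
        model = toy_model()
        g = model.genes["MET"]
        e1, e2, e3 = g.exons[0], g.exons[1], g.exons[2]
        rows = [
            ("chr7", e1.end + 1, e2.start, 90, "S1"),  # annotated
            ("chr7", e1.end + 1, e3.start, 30, "S1"),  # exon-2 skip
        ]
        events = call_splice_events(junctions(rows), model, {"MET"})
        (ev,) = events
        assert ev.psi == pytest.approx(100 * 30 / 90)
        assert ev.skipped_exons == (2,)
        assert ev.canonical_reads == 90

    def test_annotated_only_no_events(self):
        model = toy_model()
        g = model.genes["MET"]
        rows = [("chr7", a.end + 1, b.start, 50, "S1")
                for a, b in zip(g.exons, g.exons[1:])]
        assert call_splice_events(junctions(rows), model, {"MET"}) == []

    def test_below_threshold_not_emitted(self):
        model = toy_model()
        g = model.genes["MET"]
        e1, e2, e3 = g.exons[:3]
        rows = [
            ("chr7", e1.end + 1, e2.start, 100, "S1"),
            ("chr7", e1.end + 1, e3.start, 10, "S1"),  # PSI exactly 10 -> strict
        ]
        assert call_splice_events(junctions(rows), model, {"MET"}) == []

    def test_non_census_gene_filtered(self):
        model = toy_model()
        g = model.genes["MET"]
        e1, e3 = g.exons[0], g.exons[2]
        rows = [("chr7", e1.end + 1, e3.start, 30, "S1")]
        assert call_splice_events(junctions(rows), model, set()) == []


class TestDetectExonSkipping:
    def test_egfr_viii_like(self, cohort, kb):
        events = detect_exon_skipping(cohort.junctions, cohort.model, "EGFR")
        viii = [e for e in events if e.skipped_exons == (2, 3, 4, 5, 6, 7)]
        assert len(viii) == 1
        assert viii[0].alt_reads == 32

    def test_adjacent_exon_junction_no_event(self):
        model = toy_model()
        g = model.genes["MET"]
        e1, e2 = g.exons[:2]
        rows = [("chr7", e1.end + 1, e2.start, 99, "S1")]
        assert detect_exon_skipping(junctions(rows), model, "MET") == []

    def test_below_support_floor(self):
        model = toy_model()
        g = model.genes["MET"]
        e1, e3 = g.exons[0], g.exons[2]
        rows = [("chr7", e1.end + 1, e3.start, 3, "S1")]
        assert detect_exon_skipping(junctions(rows), model, "MET", min_reads=5) == []

    @settings(max_examples=25, deadline=None)
    @given(
        st.integers(min_value=3, max_value=8),
        st.sampled_from(["+", "-"]),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_agrees_with_brute_force_enumeration(self, n_exons, strand, seed):
        """Emit exactly the exon pairs (i, j), |i-j| > 1, present with support."""
        rng = np.random.default_rng(seed)
        model = toy_model(n_exons=n_exons, strand=strand)
        g = model.genes["MET"]
        by_num = {e.number: e for e in g.exons}
        # random subset of exon pairs as junctions
        pairs = list(itertools.combinations(range(1, n_exons + 1), 2))
        chosen = [p for p in pairs if rng.random() < 0.5]
        rows = []
        for i, j in chosen:
            a, b = by_num[i], by_num[j]
            lo, hi = (a, b) if a.start < b.start else (b, a)
            rows.append(("chr7", lo.end + 1, hi.start, int(rng.integers(0, 20)), "S1"))
        if not rows:
            rows = [("chr7", 1, 2, 0, "S1")]
        events = detect_exon_skipping(junctions(rows), model, "MET", min_reads=5)
        expected = {
            tuple(range(min(i, j) + 1, max(i, j)))
            for (i, j), row in zip(chosen, rows)
            if abs(i - j) > 1 and row[3] >= 5
        }
        assert {e.skipped_exons for e in events} == expected


class TestCorroborateWithSv:
    def _event_and_model(self):
        model = toy_model(n_exons=8)
        g = model.genes["MET"]
        e2, e7 = g.exons[1], g.exons[6]
        rows = [("chr7", g.exons[0].end + 1, g.exons[7].start, 32, "S1")]
        events = detect_exon_skipping(junctions(rows), model, "MET")
        return events, model, e2, e7

    def test_full_span_del_corroborates(self):
        events, model, e2, e7 = self._event_and_model()
        sv = StructuralVariantRecord("chr7", e2.start - 5, "+", "chr7", e7.end + 5, "-",
                                     "DEL", ("MET",), "S1")
        (ev,) = corroborate_with_sv(events, [sv], model)
        assert ev.sv_corroborated

    def test_partial_del_does_not(self):
        events, model, e2, e7 = self._event_and_model()
        g = model.genes["MET"]
        e4 = g.exons[3]
        sv = StructuralVariantRecord("chr7", e2.start - 5, "+", "chr7", e4.end + 5, "-",
                                     "DEL", ("MET",), "S1")
        (ev,) = corroborate_with_sv(events, [sv], model)
        assert not ev.sv_corroborated

    def test_no_sv_false(self):
        events, model, *_ = self._event_and_model()
        (ev,) = corroborate_with_sv(events, [], model)
        assert not ev.sv_corroborated
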