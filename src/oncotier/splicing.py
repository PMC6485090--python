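"""Percent-spliced-in (PSI) scoring and exon-skipping detection.

PSI for an unannotated junction is the literal ratio

    PSI = 100 * alt_reads / canonical_reads

i.e. reads supporting the alternative event divided by reads supporting the
annotated event -- *not* the alt/(alt+canonical) inclusion convention, so
values above 100% are possible. The inclusion convention is available via
``psi_convention="inclusion"`` where noted. The canonical denominator is the
read count of the single annotated junction sharing the event's donor site
(falling back to the junction sharing its acceptor).

Junction coordinates are 1-based first/last intronic bases, stored
unstranded (donor < acceptor by coordinate); exon numbering follows the gene
model's strand. An exon-skipping junction joins the 3' end of exon i to the
5' start of exon j with j > i + 1 (an EGFRvIII-style exon-1-to-8 junction
skips exons 2-7).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Container

from .ingest import GeneInfo, GeneModel, JunctionTable, StructuralVariantRecord

__all__ = [
    "SpliceEvent",
    "compute_psi",
    "call_splice_events",
    "detect_exon_skipping",
    "corroborate_with_sv",
]

#: events with PSI strictly above this percent are flagged/emitted
MIN_PSI_PERCENT = 10.0

#: minimum junction read support for exon-skipping detection
MIN_JUNCTION_READS = 5


@dataclass(frozen=True)
class SpliceEvent:
    """An unannotated splice junction with PSI and optional exon-skipping call."""

    gene: str
    sample_id: str
    donor_pos: int
    acceptor_pos: int
    alt_reads: int
    canonical_reads: int
    psi: float | None  # percent; None when saturated (no canonical reads)
    saturated: bool = False
    skipped_exons: tuple[int, ...] = ()
    sv_corroborated: bool = False


def compute_psi(alt_reads: int, canonical_reads: int) -> tuple[float | None, bool]:
    """Return (psi_percent, saturated).

    ``saturated`` is True when alternative reads exist but no canonical
    reads do; psi is then undefined-high (None) and the event should still
    be emitted. Zero alternative reads give psi 0.
    """
    if alt_reads < 0 or canonical_reads < 0:
        raise ValueError("read counts must be >= 0")
    if canonical_reads == 0:
        if alt_reads == 0:
            return 0.0, False
        return None, True
    return 100.0 * alt_reads / canonical_reads, False


def _annotated_junctions(gene: GeneInfo) -> dict[tuple[int, int], tuple[int, int]]:
    """Map annotated (donor, acceptor) 1-based junctions -> (left, right) exon numbers."""
    out: dict[tuple[int, int], tuple[int, int]] = {}
    by_coord = sorted(gene.exons, key=lambda e: e.start)
    for a, b in zip(by_coord, by_coord[1:]):
        out[(a.end + 1, b.start)] = (a.number, b.number)
    return out


def _exon_boundary_maps(gene: GeneInfo) -> tuple[dict[int, int], dict[int, int]]:
    """(donor coordinate -> exon number, acceptor coordinate -> exon number)."""
    donor_of = {e.end + 1: e.number for e in gene.exons}
    acceptor_of = {e.start: e.number for e in gene.exons}
    return donor_of, acceptor_of


def _gene_for_junction(model: GeneModel, chrom: str, donor: int, acceptor: int) -> GeneInfo | None:
    for g in model.genes.values():
        if g.chrom == chrom and g.start < donor and acceptor <= g.end:
            return g
    return None


def call_splice_events(
    junctions: JunctionTable,
    model: GeneModel,
    cancer_census_set: Container[str],
    min_psi_percent: float = MIN_PSI_PERCENT,
    psi_convention: str = "ratio",
) -> list[SpliceEvent]:
    """Call alternative splice events (PSI strictly above threshold) in census genes.

    A junction not matching any annotated intron of its gene is unannotated;
    its canonical denominator is the annotated junction sharing its donor
    (fallback: acceptor). Events in genes absent from the model are skipped.
    Saturated events (alt reads but zero canonical coverage) are always
    emitted, flagged.
    """
    if psi_convention not in ("ratio", "inclusion"):
        raise ValueError("psi_convention must be 'ratio' or 'inclusion'")
    events: list[SpliceEvent] = []
    df = junctions.rows
    for sample_id, sub in df.groupby("sample_id", sort=False):
        # read counts of annotated junctions keyed by (gene, donor/acceptor)
        canon_by_donor: dict[tuple[str, int], int] = {}
        canon_by_acceptor: dict[tuple[str, int], int] = {}
        parsed = []
        for row in sub.itertuples(index=False):
            g = _gene_for_junction(model, str(row.chrom), int(row.donor_pos), int(row.acceptor_pos))
            if g is None:
                continue
            key = (int(row.donor_pos), int(row.acceptor_pos))
            annotated = _annotated_junctions(g)
            count = int(row.read_count)
            if key in annotated:
                canon_by_donor[(g.gene, key[0])] = canon_by_donor.get((g.gene, key[0]), 0) + count
                canon_by_acceptor[(g.gene, key[1])] = (
                    canon_by_acceptor.get((g.gene, key[1]), 0) + count
                )
            parsed.append((g, key, count, key in annotated))
        for g, (donor, acceptor), count, is_annotated in parsed:
            if is_annotated or count == 0:
                continue
            canonical = canon_by_donor.get((g.gene, donor))
            if canonical is None:
                canonical = canon_by_acceptor.get((g.gene, acceptor), 0)
            if psi_convention == "ratio":
                psi, saturated = compute_psi(count, canonical)
            else:
                psi, saturated = 100.0 * count / (count + canonical), False
            donor_of, acceptor_of = _exon_boundary_maps(g)
            skipped: tuple[int, ...] = ()
            if donor in donor_of and acceptor in acceptor_of:
                lo, hi = sorted((donor_of[donor], acceptor_of[acceptor]))
                if hi > lo + 1:
                    skipped = tuple(range(lo + 1, hi))
            if g.gene not in cancer_census_set:
                continue
            if saturated or (psi is not None and psi > min_psi_percent):
                events.append(
                    SpliceEvent(
                        gene=g.gene,
                        sample_id=str(sample_id),
                        donor_pos=donor,
                        acceptor_pos=acceptor,
                        alt_reads=count,
                        canonical_reads=canonical,
                        psi=psi,
                        saturated=saturated,
                        skipped_exons=skipped,
                    )
                )
    return events


def detect_exon_skipping(
    junctions: JunctionTable,
    model: GeneModel,
    gene: str,
    min_reads: int = MIN_JUNCTION_READS,
) -> list[SpliceEvent]:
    """Find exon-skipping junctions in one gene.

    Any junction joining the 3' boundary of exon i to the 5' boundary of
    exon j with |j - i| > 1 and read support >= ``min_reads`` yields an
    event whose ``skipped_exons`` are the exons strictly between i and j.
    """
    if gene not in model:
        raise KeyError(f"gene {gene!r} not in gene model")
    g = model.genes[gene]
    donor_of, acceptor_of = _exon_boundary_maps(g)
    annotated = _annotated_junctions(g)
    events = []
    for row in junctions.rows.itertuples(index=False):
        if str(row.chrom) != g.chrom:
            continue
        donor, acceptor = int(row.donor_pos), int(row.acceptor_pos)
        count = int(row.read_count)
        if count < min_reads or (donor, acceptor) in annotated:
            continue
        if donor in donor_of and acceptor in acceptor_of:
            lo, hi = sorted((donor_of[donor], acceptor_of[acceptor]))
            if hi > lo + 1:
                events.append(
                    SpliceEvent(
                        gene=gene,
                        sample_id=str(row.sample_id),
                        donor_pos=donor,
                        acceptor_pos=acceptor,
                        alt_reads=count,
                        canonical_reads=0,
                        psi=None,
                        saturated=False,
                        skipped_exons=tuple(range(lo + 1, hi)),
                    )
                )
    return events


def corroborate_with_sv(
    events: list[SpliceEvent],
    sv_records: list[StructuralVariantRecord],
    model: GeneModel,
) -> list[SpliceEvent]:
    """Mark events whose full skipped-exon span is covered by a same-gene DEL.

    A deletion corroborates an event only when it overlaps *every* skipped
    exon; partial overlap (e.g. exons 2-4 of a 2-7 skip) does not count.
    """
    out = []
    for ev in events:
        corroborated = False
        if ev.skipped_exons and ev.gene in model:
            g = model.genes[ev.gene]
            exons = {e.number: e for e in g.exons}
            for sv in sv_records:
                if sv.sv_type != "DEL" or ev.gene not in sv.genes_hit:
                    continue
                if sv.sample_id != ev.sample_id:
                    continue
                lo = min(sv.pos_a, sv.pos_b) - 1  # to 0-based
                hi = max(sv.pos_a, sv.pos_b)
                if all(
                    exons[n].start < hi and lo < exons[n].end for n in ev.skipped_exons
                ):
                    corroborated = True
                    break
        out.append(replace(ev, sv_corroborated=corroborated))
    return out
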