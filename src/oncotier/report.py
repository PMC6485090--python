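"""Tumor-board-style reporting: deterministic JSON per sample + text rendering.

The JSON report is the canonical artifact (schema-versioned, sorted keys,
byte-stable for identical inputs); the text rendering is a human-readable
view over the same dict. Every therapy option in a report traces back to at
least one listed finding.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .therapy import Finding, TherapyOption

__all__ = [
    "build_sample_report",
    "render_sample_report",
    "write_findings_tsv",
    "read_findings_tsv",
    "write_options_tsv",
]

REPORT_SCHEMA_VERSION = "1.0"


class MissingStageError(ValueError):
    """A required pipeline stage output was not provided."""


def _finding_dict(f: Finding) -> dict:
    return {
        "gene": f.gene,
        "type": f.finding_type,
        "variant_spec": f.variant_spec,
        "tier": f.tier,
        "priority_rank": f.priority_rank,
    }


def _option_dict(o: TherapyOption) -> dict:
    return {
        "drugs": list(o.drugs),
        "targets": [f"{t.gene}:{t.variant_spec or t.finding_type}" for t in o.targets],
        "evidence_level": o.evidence_level,
        "trial_ids": list(o.trial_ids),
        "rationale": o.rationale,
        "rank": o.rank,
    }


def build_sample_report(
    sample_id: str,
    findings: list[Finding],
    options: list[TherapyOption],
    purity: float | None = None,
    ploidy: float | None = None,
    burden_count: int | None = None,
    splice_events: list | None = None,
    provenance: dict | None = None,
) -> dict:
    """Assemble the per-sample report dict.

    ``findings`` and ``options`` are required stage outputs (empty lists are
    valid); a ``None`` for either names the missing stage.
    """
    if findings is None:
        raise MissingStageError("missing stage output: findings (tiering/cnv)")
    if options is None:
        raise MissingStageError("missing stage output: options (therapy)")
    listed = {f.key for f in findings}
    for o in options:
        if not any(t.key in listed or t.finding_type == "burden" for t in o.targets):
            raise ValueError(
                f"option {o.drugs} does not trace to a listed finding"
            )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "sample_id": sample_id,
        "metadata": {
            "purity": purity,
            "ploidy": ploidy,
            "exonic_snv_count": burden_count,
        },
        "findings": [_finding_dict(f) for f in findings],
        "therapy_options": [_option_dict(o) for o in options],
        "splice_events": [
            {
                "gene": e.gene,
                "donor_pos": e.donor_pos,
                "acceptor_pos": e.acceptor_pos,
                "psi": e.psi,
                "saturated": e.saturated,
                "skipped_exons": list(e.skipped_exons),
                "sv_corroborated": e.sv_corroborated,
            }
            for e in (splice_events or [])
        ],
        "provenance": provenance or {},
    }
    return report


def render_sample_report(report: dict) -> tuple[str, str]:
    """Render a report dict as (canonical JSON, human-readable text)."""
    js = json.dumps(report, sort_keys=True, indent=2) + "\n"
    lines = [
        f"Sample report: {report['sample_id']}  (schema {report['schema_version']})",
        "=" * 60,
    ]
    meta = report["metadata"]
    lines.append(
        f"purity={meta.get('purity')}  ploidy={meta.get('ploidy')}  "
        f"exonic SNVs={meta.get('exonic_snv_count')}"
    )
    lines.append("")
    lines.append(f"Findings ({len(report['findings'])}):")
    for f in report["findings"]:
        tier = f" [Tier {f['tier']}]" if f.get("tier") else ""
        rank = f" [rank {f['priority_rank']}]" if f.get("priority_rank") else ""
        lines.append(f"  {f['gene']} {f['variant_spec']} ({f['type']}){tier}{rank}")
    lines.append("")
    lines.append(f"Therapy options ({len(report['therapy_options'])}):")
    for o in report["therapy_options"]:
        drugs = " + ".join(o["drugs"])
        trials = ", ".join(o["trial_ids"]) or "-"
        lines.append(
            f"  {drugs}  [{o['evidence_level']}; {o['rationale']}]  trials: {trials}"
        )
    if report["splice_events"]:
        lines.append("")
        lines.append(f"Splice events ({len(report['splice_events'])}):")
        for e in report["splice_events"]:
            psi = "saturated" if e["saturated"] else f"PSI={e['psi']:.1f}%"
            skip = (
                f" skipped exons {e['skipped_exons']}" if e["skipped_exons"] else ""
            )
            sv = " [SV-corroborated]" if e["sv_corroborated"] else ""
            lines.append(f"  {e['gene']} {psi}{skip}{sv}")
    return js, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# findings / options TSV plumbing (stage outputs)

_FINDING_COLS = ["sample", "gene", "finding_type", "variant_spec", "tier", "priority_rank"]


def write_findings_tsv(findings: list[Finding], path: Path | str) -> Path:
    df = pd.DataFrame(
        [
            (
                f.sample_id,
                f.gene,
                f.finding_type,
                f.variant_spec,
                "" if f.tier is None else f.tier,
                "" if f.priority_rank is None else f.priority_rank,
            )
            for f in findings
        ],
        columns=_FINDING_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_findings_tsv(path: Path | str) -> list[Finding]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            Finding(
                sample_id=str(r.sample),
                gene=str(r.gene).upper(),
                finding_type=str(r.finding_type),
                variant_spec=str(r.variant_spec),
                tier=int(r.tier) if str(r.tier) != "" else None,
                priority_rank=(
                    int(r.priority_rank) if str(r.priority_rank) != "" else None
                ),
            )
        )
    return out


def write_options_tsv(options: list[TherapyOption], path: Path | str) -> Path:
    df = pd.DataFrame(
        [
            (
                o.sample_id,
                "+".join(o.drugs),
                ";".join(f"{t.gene}:{t.variant_spec or t.finding_type}" for t in o.targets),
                o.evidence_level,
                ";".join(o.trial_ids),
                o.rationale,
                "" if o.rank is None else o.rank,
            )
            for o in options
        ],
        columns=[
            "sample",
            "drugs",
            "targets",
            "evidence_level",
            "trial_ids",
            "rationale",
            "rank",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
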