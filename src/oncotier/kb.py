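"""Clinical-evidence knowledge bases: variant evidence, drug-gene associations,
gene sets and pathway membership.

Three flat TSV tables (plus a pathway map and a drug-name alias table) drive
variant tiering and therapy matching:

* ``evidence.tsv`` -- CIViC-style variant-level clinical evidence
  (gene, variant_spec, disease, significance, source_id),
* ``drugs.tsv`` -- gene-to-drug associations with evidence levels and
  NCT trial identifiers,
* ``gene_sets.tsv`` -- named gene sets (actionable genes, cancer census
  genes, mismatch-repair genes, promoter-annotated genes),
* ``pathways.tsv`` -- pathway membership with upstream/downstream/
  parallel-arm role tags, used for combination-therapy logic.

Evidence matching is exact string match on ``variant_spec`` after
normalization (named protein changes such as R132H or V600E, or structured
classes such as "amplification"); no HGVS parsing is attempted. Drug names
are aggressively normalized (case-folded, hyphens and whitespace stripped,
alias table applied) because real-world curation tables contain spelling
variants of the same compound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "EvidenceEntry",
    "DrugAssociation",
    "GeneSet",
    "KnowledgeBase",
    "EvidenceQueryResult",
    "EVIDENCE_LEVELS",
    "SIGNIFICANCE_VALUES",
    "ALTERATION_CLASSES",
    "normalize_drug_name",
    "split_drug_entry",
    "load_kb",
    "load_bundled_kb",
    "write_kb",
    "query_evidence",
    "query_drugs",
]

#: Ordered from strongest to weakest supporting evidence.
EVIDENCE_LEVELS = (
    "approved_in_disease",
    "approved_other_disease",
    "clinical_trial",
    "preclinical",
)

SIGNIFICANCE_VALUES = ("clinically_significant", "resistance", "unknown")

VARIANT_SCOPES = ("any_alteration", "gain", "loss", "specific_variant")

#: Alteration classes accepted by :func:`query_drugs`.
ALTERATION_CLASSES = ("snv", "gain", "loss", "sv", "expression")

PATHWAY_ROLES = ("upstream", "downstream", "parallel_arm")

_NCT_RE = re.compile(r"^NCT\d+$")


class KbSchemaError(ValueError):
    """A KB file is missing a required column or has malformed rows."""


@dataclass(frozen=True)
class EvidenceEntry:
    """One variant-level clinical-evidence row."""

    gene: str
    variant_spec: str
    disease: str
    significance: str
    source_id: str = ""

    def __post_init__(self) -> None:
        for f in ("gene", "variant_spec", "disease"):
            if not getattr(self, f):
                raise ValueError(f"EvidenceEntry.{f} must be non-empty")
        if self.significance not in SIGNIFICANCE_VALUES:
            raise ValueError(f"unknown significance {self.significance!r}")


@dataclass(frozen=True)
class DrugAssociation:
    """One gene-to-drug association with evidence level and trials."""

    gene: str
    variant_scope: str
    drug: str
    evidence_level: str
    variant_spec: str = ""
    trial_ids: tuple[str, ...] = ()
    disease: str = ""

    def __post_init__(self) -> None:
        if self.variant_scope not in VARIANT_SCOPES:
            raise ValueError(f"unknown variant_scope {self.variant_scope!r}")
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence_level {self.evidence_level!r}")
        bad = [t for t in self.trial_ids if not _NCT_RE.match(t)]
        if bad:
            raise KbSchemaError(f"malformed trial ids {bad} for {self.gene}/{self.drug}")

    @property
    def evidence_rank(self) -> int:
        return EVIDENCE_LEVELS.index(self.evidence_level)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


# pathway map: pathway name -> tuple of (gene, role)
PathwayMap = dict[str, tuple[tuple[str, str], ...]]


@dataclass
class KnowledgeBase:
    """Validated bundle of evidence, drug associations, gene sets and pathways."""

    evidence: list[EvidenceEntry] = field(default_factory=list)
    drugs: list[DrugAssociation] = field(default_factory=list)
    gene_sets: dict[str, GeneSet] = field(default_factory=dict)
    pathways: PathwayMap = field(default_factory=dict)
    drug_aliases: dict[str, str] = field(default_factory=dict)

    def gene_set(self, name: str) -> GeneSet:
        if name not in self.gene_sets:
            raise KeyError(f"gene set {name!r} not in knowledge base")
        return self.gene_sets[name]

    def known_drugs(self) -> frozenset[str]:
        return frozenset(d.drug for d in self.drugs)

    def genes_with_drugs(self) -> frozenset[str]:
        return frozenset(d.gene for d in self.drugs)


def normalize_drug_name(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a single drug name.

    Case-folds to upper case, removes hyphens and internal whitespace, then
    applies the alias map (keys and values compared post-normalization).
    Idempotent. Combination entries such as ``"RG7112/RG7388"`` must be split
    with :func:`split_drug_entry` *before* calling this.
    """
    if not raw or not raw.strip():
        raise ValueError("drug name must be non-empty")
    name = re.sub(r"[-\s]+", "", raw).upper()
    if aliases:
        name = aliases.get(name, name)
    return name


def split_drug_entry(raw: str) -> list[str]:
    """Split a combination entry ("A/B") into its component drug strings."""
    return [p.strip() for p in raw.split("/") if p.strip()]


def _normalize_aliases(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for alias, canonical in pairs:
        out[normalize_drug_name(alias)] = normalize_drug_name(canonical)
    return out


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: object) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KbSchemaError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df


def load_kb(paths: Mapping[str, Path | str], study_disease: str = "glioblastoma") -> KnowledgeBase:
    """Load and validate a knowledge base from role->path TSV files.

    Recognized roles: ``evidence``, ``drugs``, ``gene_sets``, ``pathways``,
    ``drug_aliases`` (all optional; missing roles yield empty components).
    Gene symbols are uppercased, drug names normalized, duplicate rows
    collapsed.
    """
    aliases: dict[str, str] = {}
    if "drug_aliases" in paths:
        adf = _read_tsv(paths["drug_aliases"])
        _require_columns(adf, ["alias", "canonical"], paths["drug_aliases"])
        aliases = _normalize_aliases(zip(adf["alias"], adf["canonical"]))

    evidence: list[EvidenceEntry] = []
    if "evidence" in paths:
        edf = _read_tsv(paths["evidence"])
        _require_columns(
            edf, ["gene", "variant_spec", "disease", "significance"], paths["evidence"]
        )
        seen: set[tuple] = set()
        for row in edf.itertuples(index=False):
            entry = EvidenceEntry(
                gene=row.gene.strip().upper(),
                variant_spec=row.variant_spec.strip(),
                disease=row.disease.strip().lower(),
                significance=row.significance.strip(),
                source_id=getattr(row, "source_id", ""),
            )
            key = (entry.gene, entry.variant_spec, entry.disease, entry.significance)
            if key not in seen:
                seen.add(key)
                evidence.append(entry)

    drugs: list[DrugAssociation] = []
    if "drugs" in paths:
        ddf = _read_tsv(paths["drugs"])
        _require_columns(
            ddf,
            ["gene", "variant_scope", "variant_spec", "drug", "evidence_level"],
            paths["drugs"],
        )
        bad_rows: list[int] = []
        seen_d: set[tuple] = set()
        for i, row in enumerate(ddf.itertuples(index=False)):
            trial_raw = getattr(row, "trial_ids", "") or ""
            trials = tuple(t.strip() for t in trial_raw.split(";") if t.strip())
            try:
                assoc = DrugAssociation(
                    gene=row.gene.strip().upper(),
                    variant_scope=row.variant_scope.strip(),
                    variant_spec=row.variant_spec.strip(),
                    drug=normalize_drug_name(row.drug, aliases),
                    evidence_level=row.evidence_level.strip(),
                    trial_ids=trials,
                    disease=(getattr(row, "disease", "") or "").strip().lower(),
                )
            except KbSchemaError:
                bad_rows.append(i + 2)  # 1-based incl. header
                continue
            key = (assoc.gene, assoc.variant_spec, assoc.disease, assoc.drug, assoc.variant_scope)
            if key not in seen_d:
                seen_d.add(key)
                drugs.append(assoc)
        if bad_rows:
            raise KbSchemaError(f"{paths['drugs']}: malformed trial ids on line(s) {bad_rows}")

    gene_sets: dict[str, GeneSet] = {}
    if "gene_sets" in paths:
        gdf = _read_tsv(paths["gene_sets"])
        _require_columns(gdf, ["set_name", "gene"], paths["gene_sets"])
        for name, group in gdf.groupby("set_name"):
            gene_sets[str(name)] = GeneSet(
                name=str(name),
                genes=frozenset(g.strip().upper() for g in group["gene"]),
            )

    pathways: PathwayMap = {}
    if "pathways" in paths:
        pdf = _read_tsv(paths["pathways"])
        _require_columns(pdf, ["pathway", "gene", "role"], paths["pathways"])
        for name, group in pdf.groupby("pathway", sort=False):
            members: list[tuple[str, str]] = []
            seen_g: dict[str, str] = {}
            for row in group.itertuples(index=False):
                gene = row.gene.strip().upper()
                role = row.role.strip()
                if role not in PATHWAY_ROLES:
                    raise KbSchemaError(f"unknown pathway role {role!r} for {gene}")
                if gene in seen_g:
                    raise KbSchemaError(
                        f"gene {gene} appears twice in pathway {name}"
                    )
                seen_g[gene] = role
                members.append((gene, role))
            pathways[str(name)] = tuple(members)

    return KnowledgeBase(
        evidence=evidence,
        drugs=drugs,
        gene_sets=gene_sets,
        pathways=pathways,
        drug_aliases=aliases,
    )


_BUNDLED_ROLES = {
    "evidence": "evidence.tsv",
    "drugs": "drugs.tsv",
    "gene_sets": "gene_sets.tsv",
    "pathways": "pathways.tsv",
    "drug_aliases": "drug_aliases.tsv",
}


def bundled_kb_paths() -> dict[str, Path]:
    """Paths of the packaged knowledge-base TSVs."""
    base = resources.files("oncotier").joinpath("data/kb")
    return {role: Path(str(base.joinpath(fname))) for role, fname in _BUNDLED_ROLES.items()}


def load_bundled_kb() -> KnowledgeBase:
    """Load the knowledge base shipped with the package."""
    return load_kb(bundled_kb_paths())


def write_kb(kb: KnowledgeBase, outdir: Path | str) -> dict[str, Path]:
    """Serialize a KnowledgeBase back to its TSV files (round-trips with load_kb)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edf = pd.DataFrame(
        [
            (e.gene, e.variant_spec, e.disease, e.significance, e.source_id)
            for e in kb.evidence
        ],
        columns=["gene", "variant_spec", "disease", "significance", "source_id"],
    )
    paths["evidence"] = outdir / "evidence.tsv"
    edf.to_csv(paths["evidence"], sep="\t", index=False)

    ddf = pd.DataFrame(
        [
            (
                d.gene,
                d.variant_scope,
                d.variant_spec,
                d.drug,
                d.evidence_level,
                ";".join(d.trial_ids),
                d.disease,
            )
            for d in kb.drugs
        ],
        columns=[
            "gene",
            "variant_scope",
            "variant_spec",
            "drug",
            "evidence_level",
            "trial_ids",
            "disease",
        ],
    )
    paths["drugs"] = outdir / "drugs.tsv"
    ddf.to_csv(paths["drugs"], sep="\t", index=False)

    rows = [
        (name, gene)
        for name, gs in sorted(kb.gene_sets.items())
        for gene in sorted(gs.genes)
    ]
    gdf = pd.DataFrame(rows, columns=["set_name", "gene"])
    paths["gene_sets"] = outdir / "gene_sets.tsv"
    gdf.to_csv(paths["gene_sets"], sep="\t", index=False)

    prow = [
        (name, gene, role)
        for name, members in kb.pathways.items()
        for gene, role in members
    ]
    pdf = pd.DataFrame(prow, columns=["pathway", "gene", "role"])
    paths["pathways"] = outdir / "pathways.tsv"
    pdf.to_csv(paths["pathways"], sep="\t", index=False)

    adf = pd.DataFrame(sorted(kb.drug_aliases.items()), columns=["alias", "canonical"])
    paths["drug_aliases"] = outdir / "drug_aliases.tsv"
    adf.to_csv(paths["drug_aliases"], sep="\t", index=False)
    return paths


@dataclass(frozen=True)
class EvidenceQueryResult:
    """Exact-match evidence partitioned by disease context."""

    same_disease: tuple[EvidenceEntry, ...]
    other_disease: tuple[EvidenceEntry, ...]

    @property
    def all(self) -> tuple[EvidenceEntry, ...]:
        return self.same_disease + self.other_disease

    def __bool__(self) -> bool:
        return bool(self.same_disease or self.other_disease)


def query_evidence(
    kb: KnowledgeBase, gene: str, variant_spec: str, disease: str
) -> EvidenceQueryResult:
    """Exact (gene, variant_spec) evidence lookup, split by disease match.

    Disease labels are free text compared case-insensitively.
    """
    gene = gene.upper()
    disease = disease.lower()
    same, other = [], []
    for e in kb.evidence:
        if e.gene == gene and e.variant_spec == variant_spec:
            (same if e.disease == disease else other).append(e)
    return EvidenceQueryResult(tuple(same), tuple(other))


def query_drugs(
    kb: KnowledgeBase,
    gene: str,
    alteration_class: str,
    variant_spec: str | None = None,
) -> list[DrugAssociation]:
    """Drug associations compatible with an alteration of ``gene``.

    ``any_alteration`` rows match every class; ``gain``/``loss`` rows match
    their class only; ``specific_variant`` rows require an exact
    ``variant_spec`` match.
    """
    if alteration_class not in ALTERATION_CLASSES:
        raise ValueError(
            f"unknown alteration_class {alteration_class!r}; "
            f"expected one of {ALTERATION_CLASSES}"
        )
    gene = gene.upper()
    out = []
    for d in kb.drugs:
        if d.gene != gene:
            continue
        if d.variant_scope == "any_alteration":
            out.append(d)
        elif d.variant_scope == "specific_variant":
            if variant_spec is not None and d.variant_spec == variant_spec:
                out.append(d)
        elif d.variant_scope == alteration_class:  # gain / loss
            out.append(d)
    return out
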