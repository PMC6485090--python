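"""Call-set concordance: WGS vs panel, manual vs automated curation.

Two comparison modes:

* **Panel comparison** -- per-case set algebra between the comprehensive
  (WGS/RNA-seq) call set and a targeted-panel call set: common calls,
  WGS-unique calls, panel-unique calls, and a germline-miscall audit for
  panels run without a matched normal (a panel call whose key appears in
  the case's germline callset with germline VAF >= 0.25 is flagged).
* **Curator comparison** -- per-case sensitivity and positive predictive
  value of a test call set against a truth set (manual curation as truth,
  automated curation as test): sensitivity = |truth & test| / |truth|,
  PPV = |truth & test| / |test|.

Cohort summaries report means and SDs (n-1 denominator) over cases where
the statistic is defined, plus the actionability-gain rate: the fraction of
compared cases with at least one WGS-unique targetable call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean, median, stdev

from .ingest import GermlineCallset
from .kb import GeneSet, normalize_drug_name

__all__ = [
    "CallSet",
    "PanelComparison",
    "CuratorComparison",
    "ConcordanceSummary",
    "normalize_call",
    "compare_panel",
    "sensitivity_ppv",
    "summarize_cohort",
    "GERMLINE_VAF_MIN",
]

KEY_LEVELS = ("variant", "gene", "drug_target")

#: minimum germline VAF for a panel call to count as a germline miscall
GERMLINE_VAF_MIN = 0.25


@dataclass
class CallSet:
    """A set of normalized call keys for one case."""

    case_id: str
    calls: frozenset
    source: str = ""
    matched_normal_used: bool = True


def normalize_call(raw, key_level: str = "variant"):
    """Build a canonical call key from a finding-like object.

    ``raw`` needs ``gene`` (and ``variant_spec`` for variant-level keys, or a
    drug name for drug_target-level keys). Gene-level keys collapse all
    alterations of a gene; drug_target keys are normalized drug names.
    """
    if key_level not in KEY_LEVELS:
        raise ValueError(f"key_level must be one of {KEY_LEVELS}")
    if key_level == "drug_target":
        drug = raw if isinstance(raw, str) else getattr(raw, "drug", None)
        if not drug:
            raise ValueError("drug_target key requires a drug name")
        return normalize_drug_name(drug)
    gene = raw if isinstance(raw, str) and key_level == "gene" else getattr(raw, "gene", None)
    if isinstance(raw, tuple):
        gene = raw[0]
    if not gene:
        raise ValueError("call key requires a gene")
    gene = gene.upper()
    if key_level == "gene":
        return gene
    spec = raw[1] if isinstance(raw, tuple) else getattr(raw, "variant_spec", "")
    if not spec:
        raise ValueError(f"variant-level key for {gene} requires variant_spec")
    return (gene, spec)


@dataclass
class PanelComparison:
    """Per-case panel-vs-WGS set algebra."""

    case_id: str
    common: frozenset
    wgs_unique: frozenset
    panel_unique: frozenset
    germline_miscalls: frozenset = frozenset()
    wgs_off_space: frozenset = frozenset()  # WGS-unique calls outside the panel's gene space

    def __post_init__(self) -> None:
        if self.common & self.wgs_unique or self.common & self.panel_unique:
            raise ValueError("common and unique sets must be disjoint")


@dataclass
class CuratorComparison:
    """Per-case sensitivity/PPV of a test call set against a truth set."""

    case_id: str
    sensitivity: float | None
    ppv: float | None
    truth_n: int
    test_n: int


@dataclass
class ConcordanceSummary:
    """Cohort-level concordance statistics."""

    n_cases: int
    mean_sensitivity: float | None = None
    sd_sensitivity: float | None = None
    mean_ppv: float | None = None
    sd_ppv: float | None = None
    n_undefined_sensitivity: int = 0
    n_undefined_ppv: int = 0
    actionability_gain_rate: float | None = None
    median_wgs_unique: float | None = None
    iqr_wgs_unique: float | None = None
    median_common: float | None = None
    iqr_common: float | None = None
    median_panel_unique: float | None = None
    iqr_panel_unique: float | None = None


def compare_panel(
    wgs: CallSet,
    panel: CallSet,
    germline: GermlineCallset | None = None,
    panel_gene_space: GeneSet | None = None,
    germline_keys: frozenset | None = None,
) -> PanelComparison:
    """Set algebra between a WGS call set and a panel call set for one case.

    When ``panel_gene_space`` is given, the WGS set is restricted to it for
    the in-space comparison and off-space WGS calls are reported separately.
    Germline miscalls are audited only for panels without a matched normal;
    pass ``germline_keys`` (keys at the same level, pre-filtered to
    germline VAF >= GERMLINE_VAF_MIN) or a raw ``germline`` callset whose
    keys are (gene, spec)-style tuples matching the call keys.
    """
    if wgs.case_id != panel.case_id:
        raise ValueError(f"case mismatch: {wgs.case_id!r} vs {panel.case_id!r}")
    wgs_calls = wgs.calls
    off_space: frozenset = frozenset()
    if panel_gene_space is not None:
        def in_space(key) -> bool:
            gene = key[0] if isinstance(key, tuple) else key
            return gene in panel_gene_space

        off_space = frozenset(k for k in wgs_calls if not in_space(k))
        wgs_calls = wgs_calls - off_space
    common = wgs_calls & panel.calls
    wgs_unique = wgs_calls - panel.calls
    panel_unique = panel.calls - wgs_calls
    miscalls: frozenset = frozenset()
    if not panel.matched_normal_used:
        if germline_keys is None and germline is not None:
            germline_keys = frozenset(
                k for k, vaf in germline.calls.items() if vaf >= GERMLINE_VAF_MIN
            )
        if germline_keys:
            miscalls = panel.calls & germline_keys
    return PanelComparison(
        case_id=wgs.case_id,
        common=common,
        wgs_unique=wgs_unique,
        panel_unique=panel_unique,
        germline_miscalls=miscalls,
        wgs_off_space=off_space,
    )


def sensitivity_ppv(truth: CallSet, test: CallSet) -> CuratorComparison:
    """Per-case sensitivity and PPV of ``test`` against ``truth``.

    Empty truth -> sensitivity undefined; empty test -> PPV undefined (and
    sensitivity 0 unless truth is also empty). Undefined values are None and
    excluded from cohort means.
    """
    if truth.case_id != test.case_id:
        raise ValueError(f"case mismatch: {truth.case_id!r} vs {test.case_id!r}")
    tp = len(truth.calls & test.calls)
    sens = tp / len(truth.calls) if truth.calls else None
    ppv = tp / len(test.calls) if test.calls else None
    return CuratorComparison(
        case_id=truth.case_id,
        sensitivity=sens,
        ppv=ppv,
        truth_n=len(truth.calls),
        test_n=len(test.calls),
    )


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    m = mean(values)
    sd = stdev(values) if len(values) >= 2 else None
    return m, sd


def _iqr(values: list[float]) -> float:
    if not values:
        return math.nan
    lo = _quantile(values, 0.25)
    hi = _quantile(values, 0.75)
    return hi - lo


def _quantile(values: list[float], q: float) -> float:
    xs = sorted(values)
    idx = q * (len(xs) - 1)
    lo = math.floor(idx)
    hi = math.ceil(idx)
    if lo == hi:
        return xs[lo]
    frac = idx - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def summarize_cohort(rows) -> ConcordanceSummary:
    """Summarize a cohort of CuratorComparison or PanelComparison rows.

    For curator rows: mean/SD of sensitivity and PPV over defined cases.
    For panel rows: actionability-gain rate (cases with >= 1 WGS-unique
    call) plus medians/IQRs of the per-case common/unique counts.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("summarize_cohort requires >= 1 row")
    if isinstance(rows[0], CuratorComparison):
        sens = [r.sensitivity for r in rows if r.sensitivity is not None]
        ppvs = [r.ppv for r in rows if r.ppv is not None]
        if not sens and not ppvs:
            raise ValueError("no defined sensitivity/PPV rows to summarize")
        ms, ss = _mean_sd(sens)
        mp, sp = _mean_sd(ppvs)
        return ConcordanceSummary(
            n_cases=len(rows),
            mean_sensitivity=ms,
            sd_sensitivity=ss,
            mean_ppv=mp,
            sd_ppv=sp,
            n_undefined_sensitivity=len(rows) - len(sens),
            n_undefined_ppv=len(rows) - len(ppvs),
        )
    if isinstance(rows[0], PanelComparison):
        gain = sum(1 for r in rows if len(r.wgs_unique) >= 1)
        wgs_u = [float(len(r.wgs_unique)) for r in rows]
        comm = [float(len(r.common)) for r in rows]
        pan_u = [float(len(r.panel_unique)) for r in rows]
        return ConcordanceSummary(
            n_cases=len(rows),
            actionability_gain_rate=gain / len(rows),
            median_wgs_unique=median(wgs_u),
            iqr_wgs_unique=_iqr(wgs_u),
            median_common=median(comm),
            iqr_common=_iqr(comm),
            median_panel_unique=median(pan_u),
            iqr_panel_unique=_iqr(pan_u),
        )
    raise TypeError(f"cannot summarize rows of type {type(rows[0]).__name__}")
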