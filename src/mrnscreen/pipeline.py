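"""End-to-end analysis glue: classify, collapse, and run burden models.

Connects the variant-model rules to the statistics layer over tabular
inputs: apply the rarity filter, assign effective classes and severities
per observation, collapse each subject to their single most severe
(class, grade), and fit the binary and graded burden models per analysis
class set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gvgd import Grade
from .splice import INNOCUOUS_CALL, MODERATE_DAMAGE_PROBABILITY, SEVERE_DAMAGE_PROBABILITY, SpliceCall
from .stats import OrResult, TrendResult, TwoByTwo, adjusted_or, crude_or, graded_trend
from .variants import (
    DEFAULT_SEVERITY_CONFIG,
    DomainAnnotation,
    EffectiveClass,
    ReferenceFrequencies,
    SeverityConfig,
    VariantObservation,
    collapse_subject,
    effective_class,
    in_key_domain,
    is_rare,
    severity,
)

__all__ = [
    "classify_table",
    "collapse_table",
    "BurdenRow",
    "burden_analysis",
    "trend_from_collapsed",
    "CLASS_SETS",
]

#: Named analysis class sets (mirroring the published groupings).
CLASS_SETS: dict[str, tuple[EffectiveClass, ...]] = {
    "silent": (EffectiveClass.silent,),
    "innocuous_splice": (EffectiveClass.innocuous_splice,),
    "tsjv": (EffectiveClass.truncating, EffectiveClass.severe_splice, EffectiveClass.moderate_splice),
    "keydomain_rms": (EffectiveClass.keydomain_rMS,),
    "combined": (
        EffectiveClass.truncating,
        EffectiveClass.severe_splice,
        EffectiveClass.moderate_splice,
        EffectiveClass.keydomain_rMS,
    ),
}

_CATEGORY_CALL = {
    "severe": SpliceCall(-3.0, True, "severe", SEVERE_DAMAGE_PROBABILITY, 5.7),
    "moderate": SpliceCall(-1.5, True, "moderate", MODERATE_DAMAGE_PROBABILITY, 2.4),
    "none": INNOCUOUS_CALL,
    "": INNOCUOUS_CALL,
}


def _splice_call_for(rec: Mapping, splice_calls: Mapping[str, SpliceCall] | None):
    key = f"{rec['gene']}:{rec['cdna_change']}"
    if splice_calls and key in splice_calls:
        return splice_calls[key]
    return _CATEGORY_CALL.get(str(rec.get("splice_category", "")).strip().lower(), INNOCUOUS_CALL)


def classify_table(
    observations: pd.DataFrame,
    ref: ReferenceFrequencies | None = None,
    domains: Iterable[DomainAnnotation] = (),
    rarity_threshold: float = 1e-3,
    splice_calls: Mapping[str, SpliceCall] | None = None,
    config: SeverityConfig = DEFAULT_SEVERITY_CONFIG,
) -> pd.DataFrame:
    """Per-observation effective class and severity.

    Observations failing the rarity filter are dropped.  GVGD grades are
    taken from a ``gvgd_grade`` column when present (e.g. emitted by the
    simulator or by the missense-scoring stage); splice calls come from
    ``splice_calls`` keyed by variant, falling back to a
    ``splice_category`` column.
    """
    domains = list(domains)
    rows = []
    for rec in observations.to_dict("records"):
        key = f"{rec['gene']}:{rec['cdna_change']}"
        if ref is not None and not is_rare(key, ref, rarity_threshold):
            continue
        last_exon_raw = str(rec.get("last_exon", "")).strip().lower()
        v = VariantObservation(
            subject_id=rec["subject_id"],
            gene=rec["gene"],
            cdna_change=rec["cdna_change"],
            raw_class=str(rec["raw_class"]).strip().lower(),
            protein_position=int(float(rec["protein_position"]))
            if str(rec.get("protein_position", "")).strip()
            else None,
            ref_aa=rec.get("ref_aa") or None,
            alt_aa=rec.get("alt_aa") or None,
            last_exon={"true": True, "false": False, "1": True, "0": False}.get(last_exon_raw),
            splice_region_kind=rec.get("splice_region_kind") or "none",
        )
        call = _splice_call_for(rec, splice_calls)
        ec = effective_class(v, splice=call, domains=domains)
        grade_raw = str(rec.get("gvgd_grade", "")).strip()
        grade = Grade[grade_raw] if grade_raw else None
        key_membership = (
            in_key_domain(v.gene, v.protein_position, domains=domains)
            if v.protein_position is not None
            else False
        )
        sev = severity(
            ec,
            grade=grade,
            splice=call if call.category != "none" else None,
            config=config,
            in_key=key_membership,
            is_inframe=(v.raw_class == "inframe_indel" and ec == EffectiveClass.keydomain_rMS),
        )
        rows.append(
            {
                "subject_id": v.subject_id,
                "gene": v.gene,
                "cdna_change": v.cdna_change,
                "variant_key": key,
                "effective_class": ec.name,
                "binary_severity": sev.binary,
                "graded_severity": sev.graded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "gene", "cdna_change", "variant_key",
            "effective_class", "binary_severity", "graded_severity",
        ],
    )


def collapse_table(subjects: pd.DataFrame, classified: pd.DataFrame) -> pd.DataFrame:
    """One row per subject with the most severe (class, severity)."""
    from .variants import SeverityGrade

    by_subject: dict[str, list] = {}
    for rec in classified.to_dict("records"):
        by_subject.setdefault(rec["subject_id"], []).append(
            (EffectiveClass[rec["effective_class"]], SeverityGrade(rec["binary_severity"], rec["graded_severity"]))
        )
    rows = []
    for rec in subjects.to_dict("records"):
        ec, sev = collapse_subject(by_subject.get(rec["subject_id"], []))
        rows.append(
            {
                **{k: rec[k] for k in ("subject_id", "status", "ethnicity", "center")},
                "collapsed_class": ec.name,
                "binary_severity": sev.binary,
                "graded_severity": sev.graded,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BurdenRow:
    class_set: str
    carriers_case: int
    carriers_control: int
    crude: OrResult
    adjusted: OrResult | None


def burden_analysis(
    collapsed: pd.DataFrame,
    class_sets: Mapping[str, Sequence[EffectiveClass]] = CLASS_SETS,
    covariates: Sequence[str] = ("ethnicity", "center"),
    binary_only: bool = True,
) -> list[BurdenRow]:
    """Binary collapsing model per analysis class set.

    Carriers of a class set are subjects whose collapsed class is in the
    set (and, by default, with binary severity 1 for the potentially
    pathogenic sets containing key-domain missense — C0 carriers do not
    count as carriers there); the comparison pool is everyone whose
    collapsed class is *not* more severe, i.e. all non-carriers of any
    analysed set never double-count a subject.
    """
    status = (collapsed["status"] == "case").astype(int)
    rows = []
    for name, classes in class_sets.items():
        names = {c.name for c in classes}
        member = collapsed["collapsed_class"].isin(names)
        if binary_only and EffectiveClass.keydomain_rMS in classes:
            member &= collapsed["binary_severity"] == 1.0
        t = TwoByTwo(
            int((member & (status == 1)).sum()),
            int((member & (status == 0)).sum()),
            int((~member & (status == 1)).sum()),
            int((~member & (status == 0)).sum()),
        )
        adj = None
        if member.sum() > 0 and t.carriers_case > 0 and t.carriers_control > 0:
            adj = adjusted_or(status, member.astype(int), collapsed[list(covariates)])
        rows.append(
            BurdenRow(
                class_set=name,
                carriers_case=t.carriers_case,
                carriers_control=t.carriers_control,
                crude=crude_or(t),
                adjusted=adj,
            )
        )
    return rows


def trend_from_collapsed(
    collapsed: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    max_grade: float = 6.0,
) -> TrendResult:
    """Graded trend over the collapsed per-subject severities."""
    status = (collapsed["status"] == "case").astype(int)
    cov = collapsed[list(covariates)] if covariates else None
    return graded_trend(status, collapsed["graded_severity"], cov, max_grade=max_grade)
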