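"""Subjects, variant observations, rarity filtering, class and severity rules.

The analysis collapses each subject's rare-variant observations to a
single most-severe (class, severity) pair, so that every subject is
counted in exactly one analysis class.  Class assignment implements the
screening study's rules:

* nonsense and frameshift variants outside the last coding exon are
  protein-truncating; a frameshift in the last exon escapes
  nonsense-mediated decay and is treated as an in-frame-deletion
  equivalent, graded by the worst missense substitution its scrambled
  tail creates;
* splice-region variants carry a calibrated splice-damage call (severe /
  moderate / innocuous);
* missense substitutions and in-frame indels are split by whether they
  fall in a key functional domain (regions required for the complex's
  DNA-repair activity; explicitly non-key regions such as MRE11A's second
  DNA-binding domain do not count);
* severity follows the binary/graded scheme: truncating (1.0, 6.0),
  severe splice (1.0, 5.7), moderate splice (1.0, 2.4), key-domain
  missense graded C15..C65 -> (1.0, 1..6), key-domain C0 and everything
  milder -> (0.0, 0.0).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .gvgd import Grade, GvgdScore, ProteinAlignment, score_missense
from .splice import SpliceCall

__all__ = [
    "Subject",
    "ReferenceFrequencies",
    "VariantObservation",
    "EffectiveClass",
    "SeverityGrade",
    "DomainAnnotation",
    "SeverityConfig",
    "DEFAULT_SEVERITY_CONFIG",
    "is_rare",
    "in_key_domain",
    "effective_class",
    "severity",
    "collapse_subject",
    "worst_frameshift_missense",
    "NONCARRIER",
]

RawClass = Literal[
    "silent",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "intronic",
    "splice_region",
]

DEFAULT_POPULATIONS = ("CaucasianAmerican", "AfricanAmerican", "EastAsian")
DEFAULT_RARITY_THRESHOLD = 0.001


@dataclass(frozen=True)
class Subject:
    subject_id: str
    status: Literal["case", "control"]
    ethnicity: str
    center: str
    age_band: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"subject {self.subject_id}: status must be case/control")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


class ReferenceFrequencies:
    """Allele frequencies per variant per reference population.

    A variant absent from a population's table is taken to be unobserved
    there (frequency 0), which is the rare-friendly reading: the screening
    threshold requires rarity in *every* declared population.
    """

    def __init__(
        self,
        populations: Sequence[str] = DEFAULT_POPULATIONS,
        frequencies: Mapping[str, Mapping[str, float]] | None = None,
    ) -> None:
        self.populations = tuple(populations)
        self._freqs: dict[str, dict[str, float]] = {}
        if frequencies:
            for key, by_pop in frequencies.items():
                for pop, f in by_pop.items():
                    self.add(key, pop, f)

    def add(self, variant_key: str, population: str, frequency: float) -> None:
        if population not in self.populations:
            raise ValueError(
                f"unknown reference population {population!r}; declared: {self.populations}"
            )
        if not 0.0 <= frequency <= 1.0:
            raise ValueError(f"{variant_key}: frequency {frequency} outside [0, 1]")
        self._freqs.setdefault(variant_key, {})[population] = frequency

    def frequency(self, variant_key: str, population: str) -> float:
        if population not in self.populations:
            raise ValueError(f"unknown reference population {population!r}")
        return self._freqs.get(variant_key, {}).get(population, 0.0)

    def max_frequency(self, variant_key: str) -> float:
        return max(self.frequency(variant_key, p) for p in self.populations)

    def known_variants(self) -> list[str]:
        return list(self._freqs)


@dataclass(frozen=True)
class VariantObservation:
    """One rare variant carried by one subject."""

    subject_id: str
    gene: str
    cdna_change: str
    raw_class: RawClass
    protein_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    last_exon: bool | None = None
    splice_region_kind: Literal["acceptor", "donor", "none"] = "none"

    def __post_init__(self) -> None:
        protein_affecting = self.raw_class in ("missense", "nonsense", "frameshift", "inframe_indel")
        if protein_affecting and self.protein_position is None:
            raise ValueError(
                f"{self.gene} {self.cdna_change}: {self.raw_class} requires protein_position"
            )
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError(f"{self.gene} {self.cdna_change}: protein_position must be >= 1")

    @property
    def variant_key(self) -> str:
        return f"{self.gene}:{self.cdna_change}"


class EffectiveClass(enum.IntEnum):
    """Analysis classes, ascending in the declared severity precedence."""

    noncarrier = 0
    silent = 1
    innocuous_splice = 2
    non_keydomain_rMS = 3
    keydomain_rMS = 4
    inframe_equivalent = 5
    moderate_splice = 6
    severe_splice = 7
    truncating = 8


@dataclass(frozen=True)
class SeverityGrade:
    binary: float
    graded: float

    def __post_init__(self) -> None:
        if self.binary not in (0.0, 1.0):
            raise ValueError("binary severity must be 0.0 or 1.0")
        if self.binary == 0.0 and self.graded != 0.0:
            raise ValueError("binary 0 implies graded 0")
        if not 0.0 <= self.graded <= 6.0:
            raise ValueError("graded severity must lie in [0, 6]")


NONCARRIER = (EffectiveClass.noncarrier, SeverityGrade(0.0, 0.0))


@dataclass(frozen=True)
class DomainAnnotation:
    """Protein-coordinate domain interval (1-based, inclusive)."""

    gene: str
    domain_name: str
    start: int
    end: int
    is_key: bool

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene} {self.domain_name}: bad interval {self.start}-{self.end}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class SeverityConfig:
    """Tunables of the severity scheme (defaults = the study's scheme)."""

    max_grade: float = 6.0
    severe_splice_severity: float = 5.7   # 0.95 x 6
    moderate_splice_severity: float = 2.4  # 0.40 x 6
    #: graded severity per missense grade
    grade_severities: Mapping[Grade, float] = field(
        default_factory=lambda: {
            Grade.C0: 0.0,
            Grade.C15: 1.0,
            Grade.C25: 2.0,
            Grade.C35: 3.0,
            Grade.C45: 4.0,
            Grade.C55: 5.0,
            Grade.C65: 6.0,
        }
    )


DEFAULT_SEVERITY_CONFIG = SeverityConfig()


def is_rare(
    variant_key: str,
    ref: ReferenceFrequencies,
    threshold: float = DEFAULT_RARITY_THRESHOLD,
) -> bool:
    """True iff the variant's frequency is <= threshold in every declared population."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"rarity threshold {threshold} outside (0, 1)")
    return all(ref.frequency(variant_key, p) <= threshold for p in ref.populations)


def in_key_domain(
    gene: str,
    start: int,
    end: int | None = None,
    domains: Iterable[DomainAnnotation] = (),
) -> bool:
    """Whether a protein span overlaps any key domain of the gene.

    A position inside an explicitly non-key annotation (e.g. the excluded
    second DNA-binding domain) does not count even if a key annotation
    also covers it is absent; only ``is_key`` intervals qualify.
    """
    end = end if end is not None else start
    return any(
        d.is_key and d.gene == gene and d.overlaps(start, end) for d in domains
    )


def effective_class(
    v: VariantObservation,
    splice: SpliceCall | None = None,
    domains: Iterable[DomainAnnotation] = (),
) -> EffectiveClass:
    """Map a raw variant observation to its analysis class.

    Each variant gets exactly one class.  Purely splice-region variants
    (intronic or annotated splice_region) take their calibrated splice
    call.  An exonic variant that also lies in a splice region takes the
    splice class only when predicted damaging; otherwise it keeps its
    exonic class.
    """
    if v.raw_class in ("intronic", "splice_region"):
        if splice is None:
            raise ValueError(f"{v.variant_key}: splice-region variant needs a splice call")
        if splice.category == "severe":
            return EffectiveClass.severe_splice
        if splice.category == "moderate":
            return EffectiveClass.moderate_splice
        return EffectiveClass.innocuous_splice
    if v.splice_region_kind != "none" and splice is not None:
        if splice.category == "severe":
            return EffectiveClass.severe_splice
        if splice.category == "moderate":
            return EffectiveClass.moderate_splice
    if v.raw_class == "silent":
        return EffectiveClass.silent
    if v.raw_class == "nonsense":
        return EffectiveClass.truncating
    if v.raw_class == "frameshift":
        if v.last_exon is None:
            raise ValueError(f"{v.variant_key}: frameshift requires a last_exon flag")
        return EffectiveClass.inframe_equivalent if v.last_exon else EffectiveClass.truncating
    if v.raw_class == "missense":
        key = in_key_domain(v.gene, v.protein_position, domains=domains)
        return EffectiveClass.keydomain_rMS if key else EffectiveClass.non_keydomain_rMS
    if v.raw_class == "inframe_indel":
        key = in_key_domain(v.gene, v.protein_position, domains=domains)
        return EffectiveClass.keydomain_rMS if key else EffectiveClass.non_keydomain_rMS
    raise ValueError(f"{v.variant_key}: unrecognised raw class {v.raw_class!r}")


def severity(
    ec: EffectiveClass,
    grade: Grade | GvgdScore | None = None,
    splice: SpliceCall | None = None,
    config: SeverityConfig = DEFAULT_SEVERITY_CONFIG,
    *,
    in_key: bool = False,
    is_inframe: bool = False,
) -> SeverityGrade:
    """Binary and graded severity for an effective class.

    Key-domain missense needs a grade; key-domain in-frame indels (and
    the in-frame-equivalent last-exon frameshift, when it falls in a key
    domain) take the maximum grade.  ``is_inframe`` marks a
    keydomain_rMS-classed observation that is an in-frame indel rather
    than a substitution.
    """
    if ec == EffectiveClass.truncating:
        return SeverityGrade(1.0, config.max_grade)
    if ec == EffectiveClass.severe_splice:
        if splice is not None and splice.category != "severe":
            raise ValueError("severe_splice class with a non-severe splice call")
        return SeverityGrade(1.0, config.severe_splice_severity)
    if ec == EffectiveClass.moderate_splice:
        if splice is not None and splice.category != "moderate":
            raise ValueError("moderate_splice class with a non-moderate splice call")
        return SeverityGrade(1.0, config.moderate_splice_severity)
    if ec == EffectiveClass.inframe_equivalent:
        if in_key:
            return SeverityGrade(1.0, config.max_grade)
        return SeverityGrade(0.0, 0.0)
    if ec == EffectiveClass.keydomain_rMS:
        if is_inframe:
            return SeverityGrade(1.0, config.max_grade)
        if grade is None:
            raise ValueError("key-domain missense requires a GVGD grade")
        g = grade.grade if isinstance(grade, GvgdScore) else grade
        graded = config.grade_severities[g]
        return SeverityGrade(0.0 if g == Grade.C0 else 1.0, graded)
    # silent, innocuous splice, non-key-domain missense/indel, noncarrier
    return SeverityGrade(0.0, 0.0)


def collapse_subject(
    classified: Iterable[tuple[EffectiveClass, SeverityGrade]],
) -> tuple[EffectiveClass, SeverityGrade]:
    """Most severe (class, severity) among a subject's observations.

    Precedence is the declared class order; within a class, higher graded
    severity wins.  No observations -> noncarrier.
    """
    best = NONCARRIER
    for ec, grade in classified:
        if (ec, grade.graded) > (best[0], best[1].graded):
            best = (ec, grade)
    return best


def worst_frameshift_missense(
    ref_protein_tail: str,
    frameshifted_tail: str,
    alignment: ProteinAlignment,
    offset: int,
    **score_kwargs,
) -> GvgdScore:
    """Worst missense grade created by a frameshifted coding tail.

    The reference and frameshifted tails are compared position by
    position from the frameshift point (human protein position
    ``offset``); every position where they differ is scored as a missense
    substitution and the most severe score is returned (grade order, ties
    broken by larger GD).  Scoring stops at a stop codon ('*') in the
    frameshifted tail.
    """
    if not ref_protein_tail or not frameshifted_tail:
        raise ValueError("empty protein tail")
    best: GvgdScore | None = None
    for i, (ref_aa, alt_aa) in enumerate(zip(ref_protein_tail, frameshifted_tail)):
        if alt_aa == "*":
            break
        if ref_aa == alt_aa:
            continue
        s = score_missense(alignment, offset + i, ref_aa, alt_aa, **score_kwargs)
        if best is None or s.sort_key() > best.sort_key():
            best = s
    if best is None:
        # tail identical to reference: no substitution, mildest possible score
        s0 = score_missense(
            alignment, offset, ref_protein_tail[0], ref_protein_tail[0], **score_kwargs
        )
        best = s0
    return best
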