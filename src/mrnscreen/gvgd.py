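"""Alignment-based missense grading (GV/GD and ordered C-grades).

A missense substitution is graded against a curated protein multiple
sequence alignment.  Grantham Variation (GV) measures the physicochemical
spread of the residues observed at the substituted position; Grantham
Deviation (GD) measures how far the variant residue falls outside that
observed range.  The two are combined into seven ordered grades, C0 (least
likely deleterious) through C65 (most likely deleterious).

Positions that are invariant across deep evolutionary time have GV = 0, so
any substitution there is graded purely by its Grantham distance from the
conserved residue; positions that already tolerate wide variation absorb
most substitutions at grade C0.  Restricting the alignment to a taxon
subset (e.g. mammals only) can only shrink the observed range, so grades
under a subset are at least as severe as under the full alignment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from math import sqrt
from typing import Iterable, Sequence

from .grantham import DEFAULT_MODEL, GranthamModel, grantham_distance

__all__ = [
    "Grade",
    "GradeBoundaries",
    "DEFAULT_BOUNDARIES",
    "ProteinAlignment",
    "GvgdScore",
    "column_ranges",
    "gv",
    "gd",
    "grade",
    "score_missense",
]

GAP_CHARS = frozenset("-.*")


class Grade(enum.IntEnum):
    """The seven ordered missense grades; integer value = GD threshold."""

    C0 = 0
    C15 = 15
    C25 = 25
    C35 = 35
    C45 = 45
    C55 = 55
    C65 = 65


@dataclass(frozen=True)
class GradeBoundaries:
    """Configurable grade-boundary surface.

    Default rule: a substitution at a position whose GV is below the
    conservation cutoff receives the highest grade whose GD threshold it
    meets; positions with GV at or above the cutoff already tolerate wide
    physicochemical variation and everything is graded C0 there.  The
    cutoff default (61.3) follows the published grading surface's GV
    break.  A replacement boundary table can be dropped in via the
    ``gd_thresholds`` mapping without code changes.
    """

    gv_cutoff: float = 61.3
    gd_thresholds: dict[Grade, float] = field(
        default_factory=lambda: {g: float(g) for g in Grade if g is not Grade.C0}
    )

    def __post_init__(self) -> None:
        if self.gv_cutoff <= 0:
            raise ValueError("gv_cutoff must be positive")
        for g, t in self.gd_thresholds.items():
            if not isinstance(g, Grade) or g is Grade.C0 or t <= 0:
                raise ValueError(f"malformed grade boundary entry {g!r}: {t!r}")


DEFAULT_BOUNDARIES = GradeBoundaries()


@dataclass
class ProteinAlignment:
    """Gapped protein alignment with per-sequence taxon metadata.

    ``sequences`` maps species tags to aligned strings of equal length;
    ``mammal_flags`` declares which tags form the mammals-only subset.
    The human sequence (``human_tag``) provides the reference residue
    coordinate system: position ``i`` (1-based) is the i-th non-gap
    residue of the human sequence.
    """

    gene: str
    sequences: dict[str, str]
    mammal_flags: dict[str, bool] = field(default_factory=dict)
    human_tag: str = "human"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences have unequal lengths")
        if self.human_tag not in self.sequences:
            raise ValueError(f"alignment lacks the human sequence {self.human_tag!r}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def mammal_subset(self) -> list[str]:
        return [t for t in self.sequences if self.mammal_flags.get(t, False)]

    def column_for_position(self, position: int) -> int:
        """Alignment column index (0-based) of 1-based human residue position."""
        human = self.sequences[self.human_tag]
        count = 0
        for i, ch in enumerate(human):
            if ch not in GAP_CHARS:
                count += 1
                if count == position:
                    return i
        raise IndexError(
            f"position {position} beyond human sequence of {self.gene} ({count} residues)"
        )

    def column_residues(
        self, column: int, taxon_subset: Iterable[str] | None = None
    ) -> list[str]:
        """Standard residues observed in a column, gaps/ambiguous excluded."""
        tags = list(taxon_subset) if taxon_subset is not None else list(self.sequences)
        unknown = [t for t in tags if t not in self.sequences]
        if unknown:
            raise KeyError(f"taxon subset names absent from alignment: {unknown}")
        residues = []
        for t in tags:
            ch = self.sequences[t][column].upper()
            if ch in GAP_CHARS:
                continue
            if ch in DEFAULT_MODEL.properties:
                residues.append(ch)
        return residues


@dataclass(frozen=True)
class GvgdScore:
    gv: float
    gd: float
    grade: Grade
    subset: str = "full"

    def sort_key(self) -> tuple[int, float]:
        # severity order: grade first, larger GD breaks ties
        return (int(self.grade), self.gd)


Ranges = tuple[float, float, float, float, float, float]


def column_ranges(
    alignment: ProteinAlignment,
    position: int,
    taxon_subset: Iterable[str] | None = None,
) -> Ranges:
    """Property extrema (c_min, c_max, p_min, p_max, v_min, v_max) at a position.

    ``position`` is 1-based in human protein coordinates.  Gaps and
    ambiguous residues are skipped; an all-gap column is an error.
    """
    col = alignment.column_for_position(position)
    residues = alignment.column_residues(col, taxon_subset)
    if not residues:
        raise ValueError(
            f"no scorable residues at {alignment.gene} position {position} "
            "(all-gap or ambiguous column)"
        )
    return ranges_of(residues)


def ranges_of(residues: Sequence[str], model: GranthamModel = DEFAULT_MODEL) -> Ranges:
    """Property extrema over an explicit residue set."""
    props = [model.properties[r] for r in residues]
    cs, ps, vs = zip(*props)
    return (min(cs), max(cs), min(ps), max(ps), min(vs), max(vs))


def gv(ranges: Ranges, model: GranthamModel = DEFAULT_MODEL) -> float:
    """Grantham Variation: scaled diameter of the observed property box."""
    c0, c1, p0, p1, v0, v1 = ranges
    return model.rho * sqrt(
        model.alpha * (c1 - c0) ** 2
        + model.beta * (p1 - p0) ** 2
        + model.gamma * (v1 - v0) ** 2
    )


def gd(ranges: Ranges, alt_aa: str, model: GranthamModel = DEFAULT_MODEL) -> float:
    """Grantham Deviation: scaled distance from ``alt_aa`` to the property box.

    Each property contributes the distance from the variant residue's
    value to the observed [min, max] interval (zero if inside), so GD is 0
    exactly when the variant lies within the observed range on all three
    axes.
    """
    if alt_aa not in model.properties:
        raise ValueError(f"non-standard amino acid {alt_aa!r}")
    c0, c1, p0, p1, v0, v1 = ranges
    c, p, v = model.properties[alt_aa]
    dc = max(c0 - c, 0.0, c - c1)
    dp = max(p0 - p, 0.0, p - p1)
    dv = max(v0 - v, 0.0, v - v1)
    return model.rho * sqrt(
        model.alpha * dc**2 + model.beta * dp**2 + model.gamma * dv**2
    )


def grade(
    gv_value: float, gd_value: float, boundaries: GradeBoundaries = DEFAULT_BOUNDARIES
) -> Grade:
    """Ordered grade from a (GV, GD) pair under a boundary table."""
    if gd_value == 0.0:
        return Grade.C0
    if gv_value >= boundaries.gv_cutoff:
        return Grade.C0
    best = Grade.C0
    for g, threshold in boundaries.gd_thresholds.items():
        if gd_value >= threshold and g > best:
            best = g
    return best


def score_missense(
    alignment: ProteinAlignment,
    position: int,
    ref_aa: str,
    alt_aa: str,
    taxon_subset: Iterable[str] | None = None,
    model: GranthamModel = DEFAULT_MODEL,
    boundaries: GradeBoundaries = DEFAULT_BOUNDARIES,
    subset_name: str | None = None,
) -> GvgdScore:
    """Grade one missense substitution against the alignment.

    The human reference residue is part of the alignment and therefore of
    the observed range.  ``ref_aa``, when given, is checked against the
    human sequence as a coordinate sanity check.
    """
    col = alignment.column_for_position(position)
    human_res = alignment.sequences[alignment.human_tag][col].upper()
    if human_res in GAP_CHARS:
        raise ValueError(
            f"human residue at {alignment.gene} position {position} is a gap; unscorable"
        )
    if ref_aa and human_res != ref_aa.upper():
        raise ValueError(
            f"reference residue mismatch at {alignment.gene} position {position}: "
            f"expected {ref_aa}, alignment has {human_res}"
        )
    subset = list(taxon_subset) if taxon_subset is not None else None
    ranges = column_ranges(alignment, position, subset)
    gv_value = gv(ranges, model)
    gd_value = gd(ranges, alt_aa.upper(), model)
    name = subset_name or ("full" if subset is None else "subset")
    return GvgdScore(gv=gv_value, gd=gd_value, grade=grade(gv_value, gd_value, boundaries), subset=name)
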