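"""Splice-site strength calibration and damage classification.

Raw splice-site strength scores (e.g. maximum-entropy model scores for
acceptor or donor motifs) are standardised against the distribution of
wild-type junction scores of the same site kind: z = (score - mean) / sd.
A variant that *reduces* its site's score and lands at z <= -2 has an
approximately 95% probability of damaging splicing (severe); one landing
in -2 < z <= -1 has an approximately 40% probability (moderate).  The
probability-weighted graded severities are 0.95 x 6 = 5.7 and
0.40 x 6 = 2.4 on the 0-6 severity scale.

The calibration population (which wild-type junctions to pool) is an
input, not a constant; acceptors and donors are calibrated separately.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = [
    "SpliceCalibration",
    "SpliceCall",
    "SEVERE_DAMAGE_PROBABILITY",
    "MODERATE_DAMAGE_PROBABILITY",
    "calibrate",
    "in_splice_region",
    "classify_splice",
    "INNOCUOUS_CALL",
]

SiteKind = Literal["acceptor", "donor"]

SEVERE_DAMAGE_PROBABILITY = 0.95
MODERATE_DAMAGE_PROBABILITY = 0.40

#: Window sizes defining the screened splice region, in bp.
ACCEPTOR_INTRON_WINDOW = 20
DONOR_INTRON_WINDOW = 8
EXON_EDGE_WINDOW = 3


@dataclass(frozen=True)
class SpliceCalibration:
    """Mean/sd of wild-type junction scores for one site kind."""

    site_kind: SiteKind
    mean: float
    sd: float
    n_sites: int

    def z(self, score: float) -> float:
        return (score - self.mean) / self.sd


@dataclass(frozen=True)
class SpliceCall:
    """Calibrated damage assessment for one splice-region variant."""

    z_variant: float
    reduced: bool
    category: Literal["severe", "moderate", "none"]
    p_damage: float
    severity: float


#: The call attached to splice-region variants that do not qualify as damaging.
INNOCUOUS_CALL = SpliceCall(z_variant=0.0, reduced=False, category="none", p_damage=0.0, severity=0.0)


def calibrate(wt_scores: Sequence[float], site_kind: SiteKind) -> SpliceCalibration:
    """Sample mean and sd (n-1 denominator) of wild-type junction scores."""
    if len(wt_scores) < 2:
        raise ValueError(f"need at least 2 wild-type {site_kind} scores to calibrate")
    mean = statistics.fmean(wt_scores)
    sd = statistics.stdev(wt_scores)
    if sd == 0:
        raise ValueError(f"wild-type {site_kind} scores have zero variance")
    return SpliceCalibration(site_kind=site_kind, mean=mean, sd=sd, n_sites=len(wt_scores))


def in_splice_region(
    *,
    intronic: bool,
    acceptor_distance: int | None = None,
    donor_distance: int | None = None,
    exon_position_from_start: int | None = None,
    exon_position_from_end: int | None = None,
) -> Literal["acceptor", "donor", "none"]:
    """Which splice region, if any, a variant position falls in.

    Distances are positive base counts from the relevant junction
    (intronic offsets of either sign are accepted and taken in absolute
    value; exon positions are 1-based from the respective exon edge).
    Intronic variants qualify within 20 bp of an acceptor or 8 bp of a
    donor; exonic variants within the first or last 3 bp of an exon.
    """
    if intronic:
        if acceptor_distance is not None and 0 < abs(acceptor_distance) <= ACCEPTOR_INTRON_WINDOW:
            return "acceptor"
        if donor_distance is not None and 0 < abs(donor_distance) <= DONOR_INTRON_WINDOW:
            return "donor"
        return "none"
    if exon_position_from_start is not None and 1 <= exon_position_from_start <= EXON_EDGE_WINDOW:
        return "acceptor"
    if exon_position_from_end is not None and 1 <= exon_position_from_end <= EXON_EDGE_WINDOW:
        return "donor"
    return "none"


def classify_splice(
    wt_score: float,
    variant_score: float,
    calib: SpliceCalibration,
    max_grade: float = 6.0,
) -> SpliceCall:
    """Classify a splice-region variant as severe / moderate / none.

    Only variants that reduce their own junction's score can qualify.  The
    boundary z = -2 is assigned to the severe band (closed at the damaging
    side).  Graded severity is the damage probability times ``max_grade``.
    """
    reduced = variant_score < wt_score
    z = calib.z(variant_score)
    if reduced and z <= -2.0:
        category, p = "severe", SEVERE_DAMAGE_PROBABILITY
    elif reduced and z <= -1.0:
        category, p = "moderate", MODERATE_DAMAGE_PROBABILITY
    else:
        category, p = "none", 0.0
    return SpliceCall(
        z_variant=z,
        reduced=reduced,
        category=category,
        p_damage=p,
        severity=p * max_grade,
    )
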