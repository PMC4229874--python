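"""Published carrier counts from the MRN case-control mutation screening.

The source study mutation-screened the coding exons and proximal splice
junctions of MRE11A, RAD50 and NBN in 1,312 early-onset breast cancer
cases and 1,121 population controls, and reported carrier counts per
collapsed variant class.  Those printed counts are inputs to the
desk-scale re-analyses here: crude odds ratios and the graded trend fit
are exactly recomputable from them.

All pairs are (cases, controls).
"""

from __future__ import annotations

COHORT_TOTALS = (1312, 1121)

#: Cohort composition by self-reported race/ethnicity.
ETHNICITY_COUNTS = {
    "Caucasian": (848, 967),
    "EastAsian": (208, 71),
    "Latina": (158, 47),
    "AfricanAncestry": (98, 36),
}

#: Cohort composition by study center.
CENTER_COUNTS = {
    "Australia": (593, 522),
    "Canada": (302, 463),
    "NorthernCalifornia": (417, 136),
}

#: Cohort composition by age band (cases were diagnosed at <= 45 years;
#: controls were frequency matched within +/- 10 years).
AGE_BAND_COUNTS = {
    "<=30": (108, 67),
    "31-35": (325, 172),
    "36-40": (436, 237),
    "41-45": (443, 203),
    "46-50": (0, 230),
    "51-55": (0, 212),
}

# ---------------------------------------------------------------------------
# Largely innocuous classes (noncarrier pool excludes carriers of any of the
# three classes below).

INNOCUOUS_NONCARRIERS = (1240, 1060)
INNOCUOUS_CLASS_COUNTS = {
    "silent": (10, 10),
    "innocuous_splice": (14, 13),
    "any_rMS_or_inframe": (48, 38),
}

# ---------------------------------------------------------------------------
# Potentially pathogenic classes.  The noncarrier pool excludes carriers of
# truncating/spliceogenic variants and key-domain rMS of grade > C0; the
# key-domain C0 carriers sit inside this pool and are moved out for the
# analysis of all key-domain rMS including C0.

PATHOGENIC_NONCARRIERS = (1283, 1114)
KEYDOMAIN_C0_CARRIERS = (4, 1)

TSJV_BY_GENE = {"MRE11A": (1, 0), "RAD50": (4, 3), "NBN": (4, 0)}
KEYDOMAIN_ANY_BY_GENE = {"MRE11A": (10, 1), "RAD50": (10, 2), "NBN": (4, 2)}
KEYDOMAIN_GT_C0_BY_GENE = {"MRE11A": (7, 1), "RAD50": (10, 2), "NBN": (3, 1)}
COMBINED_BY_GENE = {"MRE11A": (8, 1), "RAD50": (14, 5), "NBN": (7, 1)}

#: T+SJV plus key-domain rMS of mid severity (C0 < grade < C65).
MID_SEVERITY_COMBINED = (19, 5)

#: Severity scheme: class -> (binary, graded, n_variants, cases, controls).
SEVERITY_SCHEME = {
    "frameshift_excl_last_exon": (1.0, 6.0, 4, 2, 3),
    "nonsense_excl_last_exon": (1.0, 6.0, 3, 3, 0),
    "severe_acceptor_damage": (1.0, 5.7, 1, 1, 0),
    "moderate_acceptor_damage": (1.0, 2.4, 0, 0, 0),
    "severe_donor_damage": (1.0, 5.7, 1, 1, 0),
    "moderate_donor_damage": (1.0, 2.4, 2, 2, 0),
    "keydomain_rMS_C0": (0.0, 0.0, 4, 4, 1),
    "keydomain_rMS_C15": (1.0, 1.0, 1, 1, 0),
    "keydomain_rMS_C25": (1.0, 2.0, 6, 6, 1),
    "keydomain_rMS_C35": (1.0, 3.0, 1, 0, 1),
    "keydomain_rMS_C45": (1.0, 4.0, 3, 3, 0),
    "keydomain_rMS_C55": (1.0, 5.0, 0, 0, 0),
    "keydomain_rMS_C65": (1.0, 6.0, 8, 10, 1),
    "keydomain_inframe_deletion": (1.0, 6.0, 1, 0, 1),
}


def graded_trend_counts() -> list[tuple[float, int, int]]:
    """(grade, cases, controls) rows for the combined T+SJV + key-domain
    missense graded trend fit.

    Grade 0 pools the potentially-pathogenic noncarriers with the
    key-domain C0 carriers; every carrier row sits at its scheme grade.
    """
    nc_cases, nc_controls = PATHOGENIC_NONCARRIERS
    c0_cases, c0_controls = KEYDOMAIN_C0_CARRIERS
    rows: dict[float, list[int]] = {0.0: [nc_cases + c0_cases, nc_controls + c0_controls]}
    for cls, (binary, graded, _nv, cases, controls) in SEVERITY_SCHEME.items():
        if binary == 0.0:
            continue
        rows.setdefault(graded, [0, 0])
        rows[graded][0] += cases
        rows[graded][1] += controls
    return [(g, c[0], c[1]) for g, c in sorted(rows.items())]
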