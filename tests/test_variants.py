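"""Rarity filter, class assignment, severity scheme, per-subject collapsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrnscreen.gvgd import Grade, ProteinAlignment
from mrnscreen.splice import SpliceCall, INNOCUOUS_CALL
from mrnscreen.variants import (
    EffectiveClass,
    NONCARRIER,
    ReferenceFrequencies,
    SeverityGrade,
    VariantObservation,
    collapse_subject,
    effective_class,
    in_key_domain,
    is_rare,
    severity,
    worst_frameshift_missense,
)

SEVERE = SpliceCall(-3.0, True, "severe", 0.95, 5.7)
MODERATE = SpliceCall(-1.5, True, "moderate", 0.40, 2.4)


class TestIsRare:
    def test_below_threshold_everywhere(self):
        ref = ReferenceFrequencies(
            frequencies={"g:c.1A>G": {"CaucasianAmerican": 5e-4, "AfricanAmerican": 5e-4, "EastAsian": 5e-4}}
        )
        assert is_rare("g:c.1A>G", ref)

    def test_common_in_one_population_fails(self):
        # e.g. a missense at 0.37% in one reference population is not rare
        ref = ReferenceFrequencies(frequencies={"NBN:p.R215W": {"CaucasianAmerican": 0.0037}})
        assert not is_rare("NBN:p.R215W", ref)

    def test_absent_everywhere_is_rare(self):
        ref = ReferenceFrequencies()
        assert is_rare("never:seen", ref)

    def test_matches_brute_force_on_toy_table(self):
        freqs = {
            "v1": {"CaucasianAmerican": 0.0005},
            "v2": {"CaucasianAmerican": 0.002},
            "v3": {"EastAsian": 0.0009, "AfricanAmerican": 0.0011},
            "v4": {},
            "v5": {"CaucasianAmerican": 0.001},  # boundary: <= threshold
        }
        ref = ReferenceFrequencies(frequencies=freqs)
        pops = ref.populations
        expected = {
            k for k in freqs
            if all(freqs[k].get(p, 0.0) <= 0.001 for p in pops)
        }
        assert {k for k in freqs if is_rare(k, ref)} == expected == {"v1", "v4", "v5"}

    @given(t_low=st.floats(1e-5, 0.5), t_high=st.floats(1e-5, 0.5))
    @settings(max_examples=40, derandomize=True)
    def test_threshold_monotone(self, t_low, t_high):
        t_low, t_high = sorted([t_low, t_high])
        ref = ReferenceFrequencies(
            frequencies={"v": {"CaucasianAmerican": 0.003, "EastAsian": 0.0002}}
        )
        if is_rare("v", ref, t_low):
            assert is_rare("v", ref, t_high)

    def test_unknown_population_rejected(self):
        ref = ReferenceFrequencies()
        with pytest.raises(ValueError):
            ref.add("v", "Martian", 0.1)


def obs(raw_class, gene="MRE11A", pos=None, last_exon=None, splice_kind="none", **kw):
    return VariantObservation(
        subject_id="s1",
        gene=gene,
        cdna_change="c.1T>A",
        raw_class=raw_class,
        protein_position=pos,
        last_exon=last_exon,
        splice_region_kind=splice_kind,
        **kw,
    )


class TestEffectiveClass:
    def test_last_exon_frameshift_is_inframe_equivalent(self, toy_domains):
        v = obs("frameshift", gene="RAD50", pos=1284, last_exon=True)
        assert effective_class(v, domains=toy_domains) is EffectiveClass.inframe_equivalent

    def test_nonsense_outside_last_exon_truncating(self, toy_domains):
        v = obs("nonsense", pos=100, last_exon=False)
        assert effective_class(v, domains=toy_domains) is EffectiveClass.truncating

    def test_missense_in_excluded_domain_is_non_keydomain(self, toy_domains):
        # position inside the explicitly non-key second DNA-binding domain
        v = obs("missense", pos=600, ref_aa="A", alt_aa="V")
        assert effective_class(v, domains=toy_domains) is EffectiveClass.non_keydomain_rMS

    def test_missense_in_key_domain(self, toy_domains):
        v = obs("missense", pos=150, ref_aa="A", alt_aa="V")
        assert effective_class(v, domains=toy_domains) is EffectiveClass.keydomain_rMS

    def test_frameshift_without_last_exon_flag_rejected(self):
        with pytest.raises(ValueError):
            effective_class(obs("frameshift", pos=5))

    def test_splice_classes_follow_call(self):
        v = obs("intronic", splice_kind="donor")
        assert effective_class(v, splice=SEVERE) is EffectiveClass.severe_splice
        assert effective_class(v, splice=MODERATE) is EffectiveClass.moderate_splice
        assert effective_class(v, splice=INNOCUOUS_CALL) is EffectiveClass.innocuous_splice

    def test_splice_region_variant_requires_call(self):
        with pytest.raises(ValueError):
            effective_class(obs("intronic", splice_kind="acceptor"))

    def test_silent_stays_silent_unless_splice_damaging(self):
        v = obs("silent", splice_kind="donor")
        assert effective_class(v, splice=INNOCUOUS_CALL) is EffectiveClass.silent
        assert effective_class(v, splice=SEVERE) is EffectiveClass.severe_splice

    def test_key_domain_overlap_rule_for_spans(self, toy_domains):
        # any overlap of an indel span with a key domain counts as inside
        assert in_key_domain("MRE11A", 295, 310, toy_domains)
        assert not in_key_domain("MRE11A", 310, 320, toy_domains)


# the complete severity scheme: (class, grade, in_key, is_inframe, splice) -> (binary, graded)
SCHEME_CASES = [
    ("truncating", None, False, False, None, (1.0, 6.0)),    # frameshift excl. last exon
    ("truncating", None, False, False, None, (1.0, 6.0)),    # nonsense excl. last exon
    ("severe_splice", None, False, False, SEVERE, (1.0, 5.7)),    # severe acceptor
    ("moderate_splice", None, False, False, MODERATE, (1.0, 2.4)),  # moderate acceptor
    ("severe_splice", None, False, False, SEVERE, (1.0, 5.7)),    # severe donor
    ("moderate_splice", None, False, False, MODERATE, (1.0, 2.4)),  # moderate donor
    ("keydomain_rMS", Grade.C0, True, False, None, (0.0, 0.0)),
    ("keydomain_rMS", Grade.C15, True, False, None, (1.0, 1.0)),
    ("keydomain_rMS", Grade.C25, True, False, None, (1.0, 2.0)),
    ("keydomain_rMS", Grade.C35, True, False, None, (1.0, 3.0)),
    ("keydomain_rMS", Grade.C45, True, False, None, (1.0, 4.0)),
    ("keydomain_rMS", Grade.C55, True, False, None, (1.0, 5.0)),
    ("keydomain_rMS", Grade.C65, True, False, None, (1.0, 6.0)),
    ("keydomain_rMS", None, True, True, None, (1.0, 6.0)),    # key-domain in-frame deletion
]


class TestSeverity:
    @pytest.mark.parametrize("ec,grade,in_key,is_inframe,splice,expected", SCHEME_CASES)
    def test_severity_scheme_golden(self, ec, grade, in_key, is_inframe, splice, expected):
        got = severity(
            EffectiveClass[ec], grade=grade, splice=splice, in_key=in_key, is_inframe=is_inframe
        )
        assert (got.binary, got.graded) == expected

    def test_inframe_equivalent_in_key_domain_max_grade(self):
        got = severity(EffectiveClass.inframe_equivalent, in_key=True)
        assert (got.binary, got.graded) == (1.0, 6.0)
        got = severity(EffectiveClass.inframe_equivalent, in_key=False)
        assert (got.binary, got.graded) == (0.0, 0.0)

    def test_mild_classes_are_zero(self):
        for ec in (EffectiveClass.silent, EffectiveClass.innocuous_splice, EffectiveClass.non_keydomain_rMS):
            assert severity(ec) == SeverityGrade(0.0, 0.0)

    def test_keydomain_missense_without_grade_rejected(self):
        with pytest.raises(ValueError):
            severity(EffectiveClass.keydomain_rMS)

    def test_binary_zero_implies_graded_zero(self):
        with pytest.raises(ValueError):
            SeverityGrade(0.0, 2.0)


GRADED = {
    EffectiveClass.noncarrier: [0.0],
    EffectiveClass.silent: [0.0],
    EffectiveClass.innocuous_splice: [0.0],
    EffectiveClass.non_keydomain_rMS: [0.0],
    EffectiveClass.keydomain_rMS: [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    EffectiveClass.inframe_equivalent: [0.0, 6.0],
    EffectiveClass.moderate_splice: [2.4],
    EffectiveClass.severe_splice: [5.7],
    EffectiveClass.truncating: [6.0],
}

classified_items = st.sampled_from(
    [
        (ec, SeverityGrade(1.0 if g > 0 else 0.0, g))
        for ec, grades in GRADED.items()
        for g in grades
        if ec is not EffectiveClass.noncarrier
    ]
)


class TestCollapse:
    def test_empty_is_noncarrier(self):
        assert collapse_subject([]) == NONCARRIER

    def test_silent_plus_c65_keydomain(self):
        items = [
            (EffectiveClass.silent, SeverityGrade(0.0, 0.0)),
            (EffectiveClass.keydomain_rMS, SeverityGrade(1.0, 6.0)),
        ]
        assert collapse_subject(items) == items[1]

    def test_innocuous_splice_beats_silent(self):
        items = [
            (EffectiveClass.innocuous_splice, SeverityGrade(0.0, 0.0)),
            (EffectiveClass.silent, SeverityGrade(0.0, 0.0)),
        ]
        assert collapse_subject(items)[0] is EffectiveClass.innocuous_splice

    @given(st.lists(classified_items, max_size=6))
    @settings(max_examples=80, derandomize=True)
    def test_equals_brute_force_max_over_declared_order(self, items):
        got = collapse_subject(items)
        expected = max(
            items, key=lambda t: (t[0], t[1].graded), default=NONCARRIER
        )
        if items:
            assert (got[0], got[1].graded) == (expected[0], expected[1].graded)
        else:
            assert got == NONCARRIER


class TestWorstFrameshiftMissense:
    def test_radical_change_at_invariant_column_scores_that_column(self, toy_alignment):
        # positions 1-4 of the toy alignment; only position 1 differs (G->W)
        s = worst_frameshift_missense("GITA", "WITA", toy_alignment, offset=1)
        assert s.grade is Grade.C65  # invariant G column, radical W

    def test_identical_tail_is_c0(self, toy_alignment):
        s = worst_frameshift_missense("GIT", "GIT", toy_alignment, offset=1)
        assert s.gd == 0.0 and s.grade is Grade.C0

    def test_exhaustive_scan_matches_maximum(self, toy_alignment):
        from mrnscreen.gvgd import score_missense

        ref, alt = "GITA", "WLMS"
        best = max(
            (
                score_missense(toy_alignment, 1 + i, r, a)
                for i, (r, a) in enumerate(zip(ref, alt))
                if r != a
            ),
            key=lambda s: s.sort_key(),
        )
        got = worst_frameshift_missense(ref, alt, toy_alignment, offset=1)
        assert got.sort_key() == best.sort_key()

    def test_stop_terminates_scan(self, toy_alignment):
        s = worst_frameshift_missense("GITA", "G*WW", toy_alignment, offset=1)
        assert s.gd == 0.0  # nothing scored before the stop

    def test_empty_tail_rejected(self, toy_alignment):
        with pytest.raises(ValueError):
            worst_frameshift_missense("", "A", toy_alignment, offset=1)
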