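"""Odds ratios, adjusted logistic models, trend tests, exact heterogeneity."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import gammaln

from mrnscreen.stats import (
    TwoByTwo,
    adjusted_or,
    build_pseudo_cohort,
    crude_or,
    default_frequency_bins,
    frequency_bin_analysis,
    graded_trend,
    heterogeneity_exact,
)


class TestCrudeOr:
    def test_published_carrier_table(self):
        r = crude_or(TwoByTwo(9, 3, 1283, 1114))
        assert r.odds_ratio == pytest.approx(2.60, abs=0.005)
        assert r.ci_low == pytest.approx(0.70, abs=0.005)
        assert r.ci_high == pytest.approx(9.65, abs=0.01)

    def test_symmetric_table_is_unity(self):
        r = crude_or(TwoByTwo(7, 7, 400, 400))
        assert r.odds_ratio == pytest.approx(1.0)

    def test_zero_control_cell_reports_exact_p(self):
        r = crude_or(TwoByTwo(4, 0, 1283, 1114))
        assert r.odds_ratio is None and r.method == "exact"
        assert r.p_value == pytest.approx(0.13, abs=0.005)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_logistic_regression_without_covariates(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(3, 60, size=4)
        t = TwoByTwo(int(a), int(b), int(c), int(d))
        status = [1] * (a + c) + [0] * (b + d)
        carrier = [1] * a + [0] * c + [1] * b + [0] * d
        logit = adjusted_or(status, carrier)
        assert logit.odds_ratio == pytest.approx(crude_or(t).odds_ratio, rel=1e-5)


def _simulate(n_cases, n_controls, p_control_by_stratum, or_, strata_case_frac, rng):
    """Two-stratum cohort with stratum-specific carrier prevalence."""
    rows = []
    for status, n in (("case", n_cases), ("control", n_controls)):
        frac = strata_case_frac if status == "case" else 1 - strata_case_frac
        n_a = int(n * frac)
        for i in range(n):
            stratum = "A" if i < n_a else "B"
            p0 = p_control_by_stratum[stratum]
            odds = p0 / (1 - p0) * (or_ if status == "case" else 1.0)
            p = odds / (1 + odds)
            rows.append(
                {"status": status, "stratum": stratum, "carrier": int(rng.random() < p)}
            )
    return pd.DataFrame(rows)


class TestAdjustedOr:
    def test_no_confounding_matches_crude(self, rng):
        df = _simulate(6000, 6000, {"A": 0.02, "B": 0.02}, 2.5, 0.5, rng)
        y = (df["status"] == "case").astype(int)
        adj = adjusted_or(y, df["carrier"], df[["stratum"]])
        t = TwoByTwo(
            int((df["carrier"] & (y == 1)).sum()),
            int((df["carrier"] & (y == 0)).sum()),
            int((~df["carrier"].astype(bool) & (y == 1)).sum()),
            int((~df["carrier"].astype(bool) & (y == 0)).sum()),
        )
        assert adj.odds_ratio == pytest.approx(crude_or(t).odds_ratio, rel=0.05)

    def test_carriers_clustered_in_case_heavy_stratum_shrink_on_adjustment(self, rng):
        # carriers live almost entirely in stratum A where cases outnumber
        # controls 3:1, inflating the crude OR; adjustment removes it
        df = _simulate(4000, 4000, {"A": 0.05, "B": 0.0005}, 1.5, 0.75, rng)
        y = (df["status"] == "case").astype(int)
        adj = adjusted_or(y, df["carrier"], df[["stratum"]])
        t = TwoByTwo(
            int((df["carrier"] & (y == 1)).sum()),
            int((df["carrier"] & (y == 0)).sum()),
            int((~df["carrier"].astype(bool) & (y == 1)).sum()),
            int((~df["carrier"].astype(bool) & (y == 0)).sum()),
        )
        assert adj.odds_ratio < crude_or(t).odds_ratio

    def test_all_noncarriers_gives_p_one(self):
        r = adjusted_or([1, 1, 0, 0], [0, 0, 0, 0])
        assert r.odds_ratio is None and r.p_value == 1.0

    def test_covariate_relabeling_invariance(self, rng):
        df = _simulate(800, 800, {"A": 0.05, "B": 0.01}, 2.0, 0.6, rng)
        y = (df["status"] == "case").astype(int)
        r1 = adjusted_or(y, df["carrier"], df[["stratum"]])
        relabeled = df[["stratum"]].replace({"A": "zz_9", "B": "aa_1"})
        r2 = adjusted_or(y, df["carrier"], relabeled)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6)


class TestGradedTrend:
    def test_modeled_or_is_exp_six_beta(self, rng):
        grades = rng.choice([0, 0, 0, 2, 4, 6], size=600)
        logits = -1 + 0.3 * grades
        y = rng.random(600) < 1 / (1 + np.exp(-logits))
        r = graded_trend(y.astype(int), grades)
        assert r.modeled_or_max == pytest.approx(math.exp(6 * r.beta))

    def test_single_carrier_grade_reduces_to_binary_model(self):
        # all carriers at grade 6: slope*6 = ln(binary OR)
        status = [1] * 40 + [0] * 15 + [1] * 500 + [0] * 500
        grades = [6.0] * 55 + [0.0] * 1000
        r = graded_trend(status, grades)
        binary = crude_or(TwoByTwo(40, 15, 500, 500))
        assert 6 * r.beta == pytest.approx(math.log(binary.odds_ratio), abs=1e-4)

    def test_slope_recovery_from_generated_trend(self, rng):
        grades = rng.choice([0.0, 1.0, 2.4, 4.0, 6.0], size=4000, p=[0.7, 0.1, 0.1, 0.05, 0.05])
        logits = -0.5 + 0.25 * grades
        y = (rng.random(4000) < 1 / (1 + np.exp(-logits))).astype(int)
        r = graded_trend(y, grades)
        se = (r.ci_high - r.beta) / 1.96
        assert abs(r.beta - 0.25) < 3 * se

    def test_constant_grades_rejected(self):
        with pytest.raises(ValueError):
            graded_trend([1, 0, 1], [2.0, 2.0, 2.0])


def _exact_rxc_brute(table):
    """All-tables enumeration oracle for tiny margins."""
    obs = np.asarray(table)
    rows, cols = obs.sum(1), obs.sum(0)
    n = obs.sum()
    lf = gammaln(np.arange(n + 1) + 1)

    def log_p(t):
        t = np.asarray(t)
        return lf[rows].sum() + lf[cols].sum() - lf[n] - lf[t.ravel()].sum()

    cells = []
    r, c = obs.shape
    # enumerate upper-left (r-1)x(c-1) submatrix exhaustively
    free = [(i, j) for i in range(r - 1) for j in range(c - 1)]
    total, hit = 0.0, 0.0
    ranges = [range(min(rows[i], cols[j]) + 1) for i, j in free]
    p_obs = log_p(obs)
    for combo in product(*ranges):
        t = np.zeros((r, c), dtype=int)
        for (i, j), v in zip(free, combo):
            t[i, j] = v
        t[:-1, -1] = rows[:-1] - t[:-1, :-1].sum(1)
        t[-1, :] = cols - t[:-1, :].sum(0)
        if (t >= 0).all():
            lp = log_p(t)
            total += math.exp(lp)
            if lp <= p_obs + 1e-7:
                hit += math.exp(lp)
    return hit / total


class TestHeterogeneityExact:
    def test_identical_ratios_give_p_one(self):
        assert heterogeneity_exact([[10, 5], [20, 10], [40, 20]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 1], [1, 3]],
            [[5, 0], [1, 4]],
            [[2, 7], [8, 2]],
        ],
    )
    def test_2x2_matches_fisher(self, table):
        assert heterogeneity_exact(table) == pytest.approx(
            sps.fisher_exact(table)[1], rel=1e-9
        )

    @pytest.mark.parametrize(
        "table",
        [
            [[2, 0, 0, 2], [0, 3, 3, 0]],
            [[1, 1, 1], [1, 1, 1]],
            [[4, 0], [0, 4], [1, 1]],
            [[2, 1, 0], [0, 1, 2]],
        ],
    )
    def test_matches_enumeration_oracle_on_small_tables(self, table):
        assert heterogeneity_exact(table) == pytest.approx(_exact_rxc_brute(table), rel=1e-9)

    def test_extreme_clustering_is_significant(self):
        # all carriers in two of four columns
        assert heterogeneity_exact([[6, 6, 0, 0], [0, 0, 6, 6]]) < 0.01

    def test_degenerate_margins(self):
        assert heterogeneity_exact([[0, 0], [3, 4]]) == 1.0
        assert heterogeneity_exact([[5, 0], [3, 0]]) == 1.0

    def test_monte_carlo_agrees_with_enumeration(self):
        table = [[8, 2, 1], [3, 6, 4]]
        exact = heterogeneity_exact(table)
        mc = heterogeneity_exact(table, max_enumeration=1, n_monte_carlo=40000, seed=7)
        assert mc == pytest.approx(exact, abs=0.02)


class TestFrequencyBins:
    def test_default_bins_are_half_log_decades(self):
        bins = default_frequency_bins()
        assert [b.upper for b in bins] == [0.01, 0.0032, 0.001, 0.00032]
        assert bins[-1].lower == 0.0

    def test_only_rarest_bin_populated(self):
        status = [1, 1, 0, 0]
        freqs = [[1e-5], [], [2e-5], []]
        res = frequency_bin_analysis(status, freqs)
        labels = [b.label for b in default_frequency_bins()]
        assert res[labels[0]] is None and res[labels[1]] is None and res[labels[2]] is None
        assert res[labels[3]] is not None

    def test_risk_confined_to_rarest_bin(self, rng):
        n = 4000
        status = np.array([1] * (n // 2) + [0] * (n // 2))
        freqs = []
        for s in status:
            carried = []
            # rare, risk-associated variants (OR ~ 2.5)
            p = 0.04 if s else 0.016
            if rng.random() < p:
                carried.append(1e-4)
            # mid-frequency neutral variants
            if rng.random() < 0.03:
                carried.append(2e-3)
            freqs.append(carried)
        res = frequency_bin_analysis(status, freqs)
        labels = [b.label for b in default_frequency_bins()]
        rare_bin = res[labels[3]]
        mid_bin = res[labels[1]]
        # true rare-bin OR = (0.04/0.96)/(0.016/0.984) ~ 2.56; 3-sigma bands
        for r, truth in ((rare_bin, 2.56), (mid_bin, 1.0)):
            se = (math.log(r.ci_high) - math.log(r.odds_ratio)) / 1.96
            assert abs(math.log(r.odds_ratio) - math.log(truth)) < 3 * se
        assert rare_bin.odds_ratio > mid_bin.odds_ratio

    def test_overlapping_bins_rejected(self):
        from mrnscreen.stats import FrequencyBin

        with pytest.raises(ValueError):
            frequency_bin_analysis(
                [1, 0], [[], []],
                bins=[FrequencyBin(0.001, 0.01), FrequencyBin(0.005, 0.02)],
            )


class TestPseudoCohort:
    def test_definitions(self):
        df = pd.DataFrame(
            {
                "record_id": ["r1", "r2", "r3", "r4"],
                "affected": [True, True, False, True],
                "pathogenic_BRCA1": [False, False, False, True],
                "pathogenic_BRCA2": [False, True, False, False],
            }
        )
        out = build_pseudo_cohort(df, "BRCA1", "BRCA2")
        assert list(out["record_id"]) == ["r1", "r2"]
        assert list(out["status"]) == ["case", "control"]

    def test_missing_flag_rejected(self):
        df = pd.DataFrame({"affected": [True], "pathogenic_BRCA1": [None], "pathogenic_BRCA2": [False]})
        with pytest.raises(ValueError):
            build_pseudo_cohort(df, "BRCA1", "BRCA2")
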