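"""Case-control burden statistics.

Crude odds ratios with Woolf confidence intervals from 2x2 carrier
tables; covariate-adjusted odds ratios and likelihood-ratio p-values from
unconditional logistic regression (race/ethnicity and study center as
unordered categorical main effects); the graded log-linear OR trend test
(logistic regression of case status on the 0-6 numeric severity grade);
a Fisher-type exact heterogeneity test for r x c tables; allele-frequency
bin analyses; and pseudo-case/pseudo-control construction for
clinical-testing datasets.

Zero carrier cells make the crude OR undefined or infinite; following the
source study's convention those rows report the two-sided Fisher exact
p-value instead of a Woolf interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TwoByTwo",
    "OrResult",
    "TrendResult",
    "FrequencyBin",
    "DEFAULT_BIN_EDGES",
    "default_frequency_bins",
    "SeparationError",
    "crude_or",
    "adjusted_or",
    "graded_trend",
    "heterogeneity_exact",
    "frequency_bin_analysis",
    "build_pseudo_cohort",
]

Z975 = sps.norm.ppf(0.975)

#: IRLS settings for all logistic fits.
LOGIT_TOL = 1e-8
LOGIT_MAXITER = 100


class SeparationError(RuntimeError):
    """Logistic fit failed to converge / quasi-separated; no silent estimate."""


@dataclass(frozen=True)
class TwoByTwo:
    carriers_case: int
    carriers_control: int
    noncarriers_case: int
    noncarriers_control: int

    def __post_init__(self) -> None:
        for v in (self.carriers_case, self.carriers_control, self.noncarriers_case, self.noncarriers_control):
            if v < 0:
                raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.carriers_case, self.noncarriers_case],
                [self.carriers_control, self.noncarriers_control],
            ]
        )


@dataclass(frozen=True)
class OrResult:
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float
    method: Literal["crude", "adjusted", "exact"]

    def __post_init__(self) -> None:
        if self.odds_ratio is not None and self.ci_low is not None:
            if not (self.ci_low <= self.odds_ratio <= self.ci_high):
                raise ValueError("odds ratio outside its confidence interval")


@dataclass(frozen=True)
class TrendResult:
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    modeled_or_max: float
    observed_or_max: float | None
    max_grade: float = 6.0


def crude_or(t: TwoByTwo) -> OrResult:
    """Crude OR = (a*d)/(b*c) with a Woolf log-normal 95% CI.

    Any zero cell leaves the OR (or its variance) undefined; those tables
    report the two-sided Fisher exact p instead.
    """
    a, b = t.carriers_case, t.carriers_control
    c, d = t.noncarriers_case, t.noncarriers_control
    if 0 in (a, b, c, d):
        p = sps.fisher_exact(t.as_array(), alternative="two-sided")[1]
        return OrResult(odds_ratio=None, ci_low=None, ci_high=None, p_value=p, method="exact")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return OrResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p_value=p,
        method="crude",
    )


def _design(
    covariate_frame: pd.DataFrame | None, n: int
) -> pd.DataFrame:
    """Intercept + dummy-coded categorical covariates (first level dropped)."""
    X = pd.DataFrame({"const": np.ones(n)})
    if covariate_frame is not None and not covariate_frame.empty:
        dummies = pd.get_dummies(
            covariate_frame.astype("category"), drop_first=True, dtype=float
        )
        X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Binomial())
    res = model.fit(maxiter=LOGIT_MAXITER, tol=LOGIT_TOL)
    if not res.converged:
        raise SeparationError("logistic regression did not converge")
    if np.any(np.abs(res.params) > 15):
        raise SeparationError(
            "diverging coefficient (|beta| > 15): separation or a structurally empty cell"
        )
    return res


def _lrt_p(full, reduced, df: int = 1) -> float:
    stat = 2.0 * (full.llf - reduced.llf)
    return float(sps.chi2.sf(max(stat, 0.0), df))


def adjusted_or(
    status: Sequence[int] | pd.Series,
    carrier: Sequence[int] | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> OrResult:
    """Covariate-adjusted OR from unconditional logistic regression.

    ``status`` is 1 for cases, ``carrier`` 1 for carriers of the class
    under test; ``covariates`` is a frame of categorical columns
    (typically ethnicity and center).  The OR is exp of the carrier
    coefficient with a Wald 95% CI; the p-value is the likelihood-ratio
    test of the carrier term.
    """
    y = np.asarray(status, dtype=float)
    ind = np.asarray(carrier, dtype=float)
    if y.shape != ind.shape:
        raise ValueError("status and carrier must have equal length")
    if ind.sum() == 0:
        return OrResult(odds_ratio=None, ci_low=None, ci_high=None, p_value=1.0, method="adjusted")
    X0 = _design(covariates, len(y))
    X1 = X0.copy()
    X1.insert(1, "carrier", ind)
    full = _fit_logit(y, X1)
    reduced = _fit_logit(y, X0)
    beta = full.params[1]
    se = full.bse[1]
    return OrResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p_value=_lrt_p(full, reduced),
        method="adjusted",
    )


def graded_trend(
    status: Sequence[int] | pd.Series,
    grades: Sequence[float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    max_grade: float = 6.0,
    top_grade_cutoff: float | None = None,
) -> TrendResult:
    """Log-linear OR trend across graded severities.

    Logistic regression of case status on the numeric severity grade
    (0 for noncarriers and C0 carriers, up to ``max_grade`` for the most
    severe classes), optionally covariate-adjusted.  Reports the ln(OR)
    per grade slope with Wald CI and LRT p, the modeled OR at the top
    grade exp(max_grade * beta), and the observed OR comparing carriers
    at grade >= ``top_grade_cutoff`` (default: exactly ``max_grade``)
    with everyone else.
    """
    y = np.asarray(status, dtype=float)
    g = np.asarray(grades, dtype=float)
    if np.all(g == g[0]):
        raise ValueError("all severity grades are equal; no trend to fit")
    if g.min() < 0 or g.max() > max_grade:
        raise ValueError(f"grades must lie in [0, {max_grade}]")
    X0 = _design(covariates, len(y))
    X1 = X0.copy()
    X1.insert(1, "grade", g)
    full = _fit_logit(y, X1)
    reduced = _fit_logit(y, X0)
    beta = float(full.params[1])
    se = float(full.bse[1])
    cutoff = max_grade if top_grade_cutoff is None else top_grade_cutoff
    top = g >= cutoff
    observed = None
    t = TwoByTwo(
        int(y[top].sum()),
        int((1 - y[top]).sum()),
        int(y[~top].sum()),
        int((1 - y[~top]).sum()),
    )
    if 0 not in (t.carriers_case, t.carriers_control, t.noncarriers_case, t.noncarriers_control):
        observed = crude_or(t).odds_ratio
    return TrendResult(
        beta=beta,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        p_value=_lrt_p(full, reduced),
        modeled_or_max=float(np.exp(max_grade * beta)),
        observed_or_max=observed,
        max_grade=max_grade,
    )


# ---------------------------------------------------------------------------
# exact heterogeneity test


def _log_table_prob(table: np.ndarray, lf: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (
        lf[rows].sum() + lf[cols].sum() - lf[n] - lf[table.ravel()].sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def rec(i: int, remaining_cols: np.ndarray, current: list[np.ndarray]):
        if i == r - 1:
            yield np.array(current + [remaining_cols.copy()])
            return
        # enumerate row i cell by cell
        row_total = rows[i]

        def cells(j: int, left: int, row: list[int]):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    yield row + [left]
                return
            for x in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - x, row + [x])

        for row in cells(0, row_total, []):
            row_arr = np.array(row)
            yield from rec(i + 1, remaining_cols - row_arr, current + [row_arr])

    yield from rec(0, cols.astype(int).copy(), [])


def _count_tables_estimate(rows: np.ndarray, cols: np.ndarray) -> float:
    """Crude upper bound on the number of fixed-margin tables."""
    est = 1.0
    for r in rows[:-1]:
        # compositions of r into len(cols) parts
        est *= math.comb(int(r) + len(cols) - 1, len(cols) - 1)
    return est


def heterogeneity_exact(
    table: Sequence[Sequence[int]] | np.ndarray,
    *,
    max_enumeration: float = 2e6,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher-type exact p for an r x c contingency table.

    The p-value is the total probability, under the fixed-margin
    hypergeometric null, of tables no more probable than the observed one
    (probability ordering).  Enumerated exhaustively when feasible;
    otherwise estimated by seeded Monte-Carlo sampling of fixed-margin
    tables with the add-one correction.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a non-negative 2-D count array")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    # degenerate margins: fewer than two non-empty rows or columns
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        return 1.0
    obs = obs[rows > 0][:, cols > 0]
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    lf = gammaln(np.arange(n + 2) + 1)  # log factorials 0..n+1
    log_p_obs = _log_table_prob(obs, lf)
    eps = 1e-7
    if _count_tables_estimate(rows, cols) <= max_enumeration:
        total = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _log_table_prob(t, lf)
            if lp <= log_p_obs + eps:
                total += math.exp(lp)
        return min(total, 1.0)
    # Monte-Carlo fallback: permute column labels against row labels
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_monte_carlo):
        perm = rng.permutation(col_labels)
        t = np.zeros_like(obs)
        np.add.at(t, (row_labels, perm), 1)
        if _log_table_prob(t, lf) <= log_p_obs + eps:
            hits += 1
    return (hits + 1) / (n_monte_carlo + 1)


# ---------------------------------------------------------------------------
# frequency bins


@dataclass(frozen=True)
class FrequencyBin:
    """Half-open allele-frequency interval (lower, upper]; the lowest bin
    is closed at zero."""

    lower: float
    upper: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise ValueError(f"bad bin bounds ({self.lower}, {self.upper}]")
        if not self.label:
            object.__setattr__(self, "label", f"{self.upper:.3%}-{self.lower:.3%}")

    def contains(self, freq: float) -> bool:
        if self.lower == 0.0:
            return 0.0 <= freq <= self.upper
        return self.lower < freq <= self.upper


#: Half-log-decade default edges, as fractions: 1%, 0.32%, 0.1%, 0.032%, 0.
DEFAULT_BIN_EDGES = (0.01, 0.0032, 0.001, 0.00032, 0.0)


def default_frequency_bins(edges: Sequence[float] = DEFAULT_BIN_EDGES) -> list[FrequencyBin]:
    edges = sorted(set(edges), reverse=True)
    bins = []
    for hi, lo in zip(edges[:-1], edges[1:]):
        bins.append(FrequencyBin(lower=lo, upper=hi))
    return bins


def frequency_bin_analysis(
    status: Sequence[int] | pd.Series,
    subject_variant_freqs: Sequence[Sequence[float]],
    bins: Sequence[FrequencyBin] | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict[str, OrResult | None]:
    """Per-frequency-bin carrier ORs.

    ``subject_variant_freqs[i]`` lists, for subject i, the maximum
    reference-population allele frequency of each rare variant the
    subject carries (a variant common anywhere is assigned by its highest
    frequency — the conservative choice).  Each bin gets its own carrier
    indicator and a covariate-adjusted logistic OR; bins with no carriers
    in one arm fall back to the crude zero-cell rule; bins with no
    variants at all report ``None``.
    """
    bins = list(bins) if bins is not None else default_frequency_bins()
    for i, b1 in enumerate(bins):
        for b2 in bins[i + 1 :]:
            if b1.lower < b2.upper and b2.lower < b1.upper:
                raise ValueError(f"overlapping frequency bins {b1.label} and {b2.label}")
    y = np.asarray(status, dtype=int)
    results: dict[str, OrResult | None] = {}
    for b in bins:
        ind = np.array(
            [any(b.contains(f) for f in freqs) for freqs in subject_variant_freqs],
            dtype=int,
        )
        if ind.sum() == 0:
            results[b.label] = None
            continue
        t = TwoByTwo(
            int((ind & (y == 1)).sum()),
            int((ind & (y == 0)).sum()),
            int(((1 - ind) & (y == 1)).sum()),
            int(((1 - ind) & (y == 0)).sum()),
        )
        if t.carriers_case == 0 or t.carriers_control == 0:
            results[b.label] = crude_or(t)
        else:
            results[b.label] = adjusted_or(y, ind, covariates)
    return results


def build_pseudo_cohort(
    test_records: pd.DataFrame,
    target_gene: str,
    partner_gene: str,
) -> pd.DataFrame:
    """Pseudo-case/pseudo-control cohort from clinical-testing records.

    ``test_records`` needs boolean columns ``affected`` and
    ``pathogenic_<gene>`` for both genes.  Pseudo-cases are affected
    individuals carrying a pathogenic variant in neither gene;
    pseudo-controls are affected carriers of a pathogenic variant in the
    partner gene (which explains their history).  Unaffected individuals
    and target-gene pathogenic carriers are excluded.
    """
    for col in ("affected", f"pathogenic_{target_gene}", f"pathogenic_{partner_gene}"):
        if col not in test_records.columns:
            raise ValueError(f"test records missing required column {col!r}")
        if test_records[col].isna().any():
            bad = test_records.index[test_records[col].isna()][0]
            raise ValueError(f"record {bad!r} missing a value for {col!r}")
    affected = test_records["affected"].astype(bool)
    path_target = test_records[f"pathogenic_{target_gene}"].astype(bool)
    path_partner = test_records[f"pathogenic_{partner_gene}"].astype(bool)
    pseudo_case = affected & ~path_target & ~path_partner
    pseudo_control = affected & path_partner & ~path_target
    out = test_records.loc[pseudo_case | pseudo_control].copy()
    out["status"] = np.where(pseudo_case[pseudo_case | pseudo_control], "case", "control")
    return out
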