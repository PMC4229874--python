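"""Synthetic data generation for the screening pipeline.

Generates case-control cohorts, per-subject variant observations,
reference allele-frequency tables, protein alignments with species trees,
and splice-score tables with the statistical structure the analysis
assumes, so every stage is testable without external data.

The default cohort configuration reproduces the source study's
conditions: 1,312 cases and 1,121 controls with the study's
race/ethnicity, center and age-band margins, per-class control carrier
prevalences taken from the observed control counts, and per-class odds
ratios near the reported estimates.  Carrier status is drawn from a
stratum-specific model in which the configured OR is exactly the
estimand of the analysis stage: within each stratum,
odds(carrier | case) = OR x odds(carrier | control).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import study_counts
from .grantham import AMINO_ACIDS
from .gvgd import ProteinAlignment
from .splice import MODERATE_DAMAGE_PROBABILITY, SEVERE_DAMAGE_PROBABILITY
from .variants import DomainAnnotation

__all__ = [
    "ClassSpec",
    "SimulationConfig",
    "DEFAULT_CONFIG",
    "default_domains",
    "simulate_cohort",
    "simulate_alignment",
    "simulate_splice_scores",
]

GENES = ("MRE11A", "RAD50", "NBN")


@dataclass(frozen=True)
class ClassSpec:
    """Generative description of one variant class.

    ``prevalence_controls`` is the carrier probability among controls in
    an unweighted stratum; ``odds_ratio`` the within-stratum carrier OR
    for cases; ``ethnicity_weights`` multiply the control-arm carrier
    odds in selected strata (clustering); ``grade_dist`` (key-domain
    missense only) gives the distribution of GVGD grades.
    """

    prevalence_controls: float
    odds_ratio: float = 1.0
    raw_class: str = "missense"
    in_key_domain: bool = False
    splice_category: str = "none"
    ethnicity_weights: Mapping[str, float] = field(default_factory=dict)
    grade_dist: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_controls <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


def _default_classes() -> dict[str, ClassSpec]:
    n_controls = study_counts.COHORT_TOTALS[1]
    return {
        "silent": ClassSpec(10 / n_controls, 1.0, raw_class="silent"),
        "innocuous_splice": ClassSpec(
            13 / n_controls, 1.0, raw_class="intronic", splice_category="none"
        ),
        "non_keydomain_rms": ClassSpec(33 / n_controls, 1.0, raw_class="missense"),
        "keydomain_rms": ClassSpec(
            5 / n_controls,
            3.1,
            raw_class="missense",
            in_key_domain=True,
            grade_dist={"C0": 0.2, "C25": 0.25, "C35": 0.05, "C45": 0.1, "C65": 0.4},
        ),
        "moderate_splice": ClassSpec(
            0.5 / n_controls, 2.4, raw_class="intronic", splice_category="moderate"
        ),
        "severe_splice": ClassSpec(
            0.5 / n_controls, 2.6, raw_class="intronic", splice_category="severe"
        ),
        "truncating": ClassSpec(3 / n_controls, 2.6, raw_class="nonsense"),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = study_counts.COHORT_TOTALS[0]
    n_controls: int = study_counts.COHORT_TOTALS[1]
    ethnicity_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(study_counts.ETHNICITY_COUNTS)
    )
    center_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(study_counts.CENTER_COUNTS)
    )
    age_band_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(study_counts.AGE_BAND_COUNTS)
    )
    classes: Mapping[str, ClassSpec] = field(default_factory=_default_classes)
    #: probability that a carrier additionally carries a second, silent variant
    multi_variant_rate: float = 0.0
    #: reference allele frequencies drawn log-uniform over this range
    rare_freq_range: tuple[float, float] = (1e-5, 8e-4)
    rarity_threshold: float = 1e-3
    seed: int = 0

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def validate(self) -> None:
        for name, counts, total in (
            ("ethnicity", self.ethnicity_counts, (self.n_cases, self.n_controls)),
            ("center", self.center_counts, (self.n_cases, self.n_controls)),
            ("age_band", self.age_band_counts, (self.n_cases, self.n_controls)),
        ):
            cases = sum(c for c, _ in counts.values())
            controls = sum(c for _, c in counts.values())
            if (cases, controls) != total:
                raise ValueError(
                    f"infeasible {name} margins: {(cases, controls)} != {total}"
                )


DEFAULT_CONFIG = SimulationConfig()


def default_domains() -> list[DomainAnnotation]:
    """Synthetic stand-in key-domain intervals (toy coordinates).

    The real key-domain boundaries are an annotation input; these toy
    intervals exist so that simulated positions have somewhere to land.
    Each gene gets two key domains plus one explicitly non-key domain.
    """
    return [
        DomainAnnotation("MRE11A", "nuclease", 1, 300, True),
        DomainAnnotation("MRE11A", "capping", 301, 480, True),
        DomainAnnotation("MRE11A", "dna_binding_II", 501, 700, False),
        DomainAnnotation("RAD50", "atpase_n", 1, 200, True),
        DomainAnnotation("RAD50", "zinc_hook", 600, 700, True),
        DomainAnnotation("RAD50", "atpase_c", 1200, 1312, True),
        DomainAnnotation("NBN", "fha", 20, 110, True),
        DomainAnnotation("NBN", "brct", 111, 330, True),
        DomainAnnotation("NBN", "mre11_binding", 680, 754, False),
    ]


def _margin_labels(counts: Mapping[str, tuple[int, int]], arm: int) -> list[str]:
    labels: list[str] = []
    for name, pair in counts.items():
        labels.extend([name] * pair[arm])
    return labels


def _key_position(rng: np.random.Generator, gene: str, domains, want_key: bool) -> int:
    spans = [
        (d.start, d.end) for d in domains if d.gene == gene and d.is_key == want_key
    ]
    if not spans or not want_key:
        # outside any key domain: pick from a fixed non-key region
        key_spans = [(d.start, d.end) for d in domains if d.gene == gene and d.is_key]
        hi = max((e for _, e in key_spans), default=500) + 500
        while True:
            pos = int(rng.integers(1, hi))
            if not any(s <= pos <= e for s, e in key_spans):
                return pos
    s, e = spans[int(rng.integers(len(spans)))]
    return int(rng.integers(s, e + 1))


def simulate_cohort(
    config: SimulationConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: (subjects, variant observations, reference frequencies).

    Subjects carry the configured stratum margins exactly (ethnicity,
    center and age band are assigned independently within each arm).
    Carrier status is drawn per class from the stratum-specific model;
    each carrier receives one variant record with the class's raw
    fields, gene, and (for key-domain missense) a GVGD grade drawn from
    the configured distribution.  Reference frequencies for every
    generated variant are drawn below the rarity threshold.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    domains = default_domains()

    frames = []
    for arm, status, n in ((0, "case", config.n_cases), (1, "control", config.n_controls)):
        eth = np.array(_margin_labels(config.ethnicity_counts, arm))
        cen = np.array(_margin_labels(config.center_counts, arm))
        age = np.array(_margin_labels(config.age_band_counts, arm))
        rng.shuffle(cen)
        rng.shuffle(age)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{status[:2]}{i:05d}" for i in range(n)],
                    "status": status,
                    "ethnicity": eth,
                    "center": cen,
                    "age_band": age,
                }
            )
        )
    subjects = pd.concat(frames, ignore_index=True)

    obs_rows: list[dict] = []
    freq_rows: list[dict] = []
    variant_serial = 0
    aa = [a for a in AMINO_ACIDS]
    for cls_name, spec in config.classes.items():
        is_case = (subjects["status"] == "case").to_numpy()
        weights = subjects["ethnicity"].map(
            lambda e: spec.ethnicity_weights.get(e, 1.0)
        ).to_numpy()
        odds0 = spec.prevalence_controls / (1 - spec.prevalence_controls) * weights
        odds1 = odds0 * spec.odds_ratio
        p = np.where(is_case, odds1 / (1 + odds1), odds0 / (1 + odds0))
        carrier = rng.random(len(subjects)) < p
        for idx in np.flatnonzero(carrier):
            variant_serial += 1
            gene = GENES[int(rng.integers(len(GENES)))]
            cdna = f"c.{variant_serial}{'del' if spec.raw_class == 'frameshift' else ''}A>G"
            row = {
                "subject_id": subjects["subject_id"].iat[idx],
                "gene": gene,
                "cdna_change": cdna,
                "raw_class": spec.raw_class,
                "protein_position": "",
                "ref_aa": "",
                "alt_aa": "",
                "last_exon": "",
                "splice_region_kind": "none",
                "gvgd_grade": "",
                "true_class": cls_name,
            }
            if spec.raw_class in ("missense", "nonsense", "frameshift", "inframe_indel"):
                pos = _key_position(rng, gene, domains, spec.in_key_domain)
                row["protein_position"] = pos
                if spec.raw_class == "missense":
                    r, a = rng.choice(len(aa), size=2, replace=False)
                    row["ref_aa"], row["alt_aa"] = aa[int(r)], aa[int(a)]
                if spec.raw_class in ("nonsense", "frameshift"):
                    row["last_exon"] = False
            if spec.raw_class in ("intronic", "splice_region"):
                row["splice_region_kind"] = "acceptor" if rng.random() < 0.5 else "donor"
                row["splice_category"] = spec.splice_category
            if spec.grade_dist:
                grades = sorted(spec.grade_dist)
                probs = np.array([spec.grade_dist[g] for g in grades])
                row["gvgd_grade"] = grades[
                    int(rng.choice(len(grades), p=probs / probs.sum()))
                ]
            obs_rows.append(row)
            lo, hi = config.rare_freq_range
            for pop in ("CaucasianAmerican", "AfricanAmerican", "EastAsian"):
                freq = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                freq_rows.append(
                    {"variant_key": f"{gene}:{cdna}", "population": pop, "frequency": freq}
                )
            if rng.random() < config.multi_variant_rate:
                variant_serial += 1
                obs_rows.append(
                    {
                        "subject_id": subjects["subject_id"].iat[idx],
                        "gene": gene,
                        "cdna_change": f"c.{variant_serial}T>C",
                        "raw_class": "silent",
                        "protein_position": "",
                        "ref_aa": "",
                        "alt_aa": "",
                        "last_exon": "",
                        "splice_region_kind": "none",
                        "gvgd_grade": "",
                        "true_class": "silent",
                    }
                )

    columns = [
        "subject_id", "gene", "cdna_change", "raw_class", "protein_position",
        "ref_aa", "alt_aa", "last_exon", "splice_region_kind", "gvgd_grade",
        "splice_category", "true_class",
    ]
    observations = pd.DataFrame(obs_rows)
    if observations.empty:
        observations = pd.DataFrame(columns=columns)
    else:
        for c in columns:
            if c not in observations.columns:
                observations[c] = ""
        observations = observations[columns].fillna("")
    ref_freqs = pd.DataFrame(freq_rows, columns=["variant_key", "population", "frequency"])
    return subjects, observations, ref_freqs


# ---------------------------------------------------------------------------
# alignment + tree


def simulate_alignment(
    n_species: int = 16,
    length: int = 100,
    conservation_profile: float | Sequence[float] = 3.0,
    seed: int = 0,
    n_mammals: int = 9,
    gene: str = "SIM",
) -> tuple[ProteinAlignment, dendropy.Tree]:
    """Simulate a gapless protein alignment and its species tree.

    ``conservation_profile`` gives the expected number of substitution
    events per column (scalar, or one value per column); events are
    placed on uniformly random edges of a birth-death tree over
    ``n_species`` tips, so the Fitch parsimony count per column is at
    most the event count (slightly lower when events collide).  A profile
    of 0 yields a fully invariant alignment.  The first ``n_mammals``
    leaves (in leaf order, including the human tip) are flagged as the
    mammals-only subset.
    """
    if np.isscalar(conservation_profile):
        profile = np.full(length, float(conservation_profile))
    else:
        profile = np.asarray(conservation_profile, dtype=float)
        if len(profile) != length:
            raise ValueError("conservation profile length must equal alignment length")
    pyrng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=pyrng
    )
    leaves = list(tree.leaf_node_iter())
    labels = ["human"] + [f"sp{i:02d}" for i in range(2, n_species + 1)]
    for leaf, label in zip(leaves, labels):
        leaf.taxon.label = label
    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]

    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    seqs: dict[str, list[str]] = {label: [] for label in labels}
    for col in range(length):
        root_state = aa[int(rng.integers(len(aa)))]
        n_events = int(rng.poisson(profile[col]))
        events_per_edge: dict[int, int] = {}
        for _ in range(n_events):
            e = int(rng.integers(len(edges)))
            events_per_edge[e] = events_per_edge.get(e, 0) + 1
        states: dict[int, str] = {id(tree.seed_node): root_state}
        for i, node in enumerate(edges):
            state = states[id(node.parent_node)]
            for _ in range(events_per_edge.get(i, 0)):
                choices = [x for x in aa if x != state]
                state = choices[int(rng.integers(len(choices)))]
            states[id(node)] = state
        for leaf, label in zip(leaves, labels):
            seqs[label].append(states[id(leaf)])

    alignment = ProteinAlignment(
        gene=gene,
        sequences={label: "".join(s) for label, s in seqs.items()},
        mammal_flags={label: i < n_mammals for i, label in enumerate(labels)},
        human_tag="human",
    )
    return alignment, tree


# ---------------------------------------------------------------------------
# splice scores


def simulate_splice_scores(
    n_junctions: int = 50,
    mean: float = 8.5,
    sd: float = 1.5,
    effect_sizes: Sequence[float] = (),
    seed: int = 0,
    site_kind: str = "donor",
    gene: str = "SIM",
) -> pd.DataFrame:
    """Simulate wild-type junction scores and variant effects.

    Wild-type scores are Normal(mean, sd^2); the i-th effect size is
    applied to junction i (cycling if more effects than junctions are
    requested).  The ground-truth category recorded per variant uses the
    *generating* mean/sd, so recovery can be checked against calibration
    from the sampled wild-type scores.
    """
    rng = np.random.default_rng(seed)
    wt = rng.normal(mean, sd, size=n_junctions)
    rows = []
    for j in range(n_junctions):
        rows.append(
            {
                "gene": gene,
                "junction_id": f"j{j:03d}",
                "site_kind": site_kind,
                "wt_score": wt[j],
                "variant_key": "",
                "variant_score": "",
                "true_category": "",
            }
        )
    for i, effect in enumerate(effect_sizes):
        j = i % n_junctions
        vscore = wt[j] + effect
        z_true = (vscore - mean) / sd
        if effect < 0 and z_true <= -2:
            cat = "severe"
        elif effect < 0 and z_true <= -1:
            cat = "moderate"
        else:
            cat = "none"
        rows.append(
            {
                "gene": gene,
                "junction_id": f"j{j:03d}",
                "site_kind": site_kind,
                "wt_score": wt[j],
                "variant_key": f"{gene}:sv{i:03d}",
                "variant_score": vscore,
                "true_category": cat,
            }
        )
    return pd.DataFrame(rows)
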