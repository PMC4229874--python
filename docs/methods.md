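# Methods

## The analysis model

The package treats three genes whose products form one protein complex as
a single concatenated candidate gene and asks whether rare variants in it
shift case-control status. Because eligible variants are individually
rare (reference-population allele frequency ≤ 0.1%), inference happens at
the class level: each subject is reduced to an indicator (binary
collapsing model) or a numeric severity grade (graded trend model) of the
most severe eligible variant they carry, and that per-subject summary is
the exposure in an unconditional logistic regression of case status.

Assumptions worth stating explicitly:

- *One class per subject.* Observations are collapsed to the single most
  severe (class, grade) under a declared total order: silent <
  innocuous splice < non-key-domain missense < key-domain missense
  (ordered internally by grade) < in-frame-equivalent < moderate splice <
  severe splice < truncating, ties broken by graded severity. Every
  subject therefore lands in exactly one analysis class, and class counts
  over a cohort sum to the cohort size. The order encodes the view that
  predicted loss-of-function outranks graded missense evidence; subjects
  carrying both a top-grade missense and a damaging splice variant are
  rare enough that the choice does not move the headline estimates.
- *Classes are exchangeable within a gene set.* Pooling across the three
  genes assumes a shared effect size per class; the exact heterogeneity
  test is the check on that assumption (across genes and across
  ethnic strata).
- *Covariates.* Adjusted models use race/ethnicity and study center as
  unordered categorical main effects only. Age is matched by design and
  not adjusted for. No interaction terms are fitted: the interaction
  structure is not identifiable at these carrier counts, and main-effects
  adjustment already absorbs the stratum-level case:control imbalance
  that produces the confounding seen in the data (see "Adjustment
  behaviour" below).

## Missense grading

Grantham's metric places residues in (composition, polarity, volume)
space with weights α = 1.833, β = 0.1018, γ = 0.000399. The scale factor
ρ is computed at model construction so that the mean over the 190
unordered residue pairs is exactly 100; with the classical property table
this gives ρ ≈ 50.7 and reproduces the published distance matrix to
within a unit.

For a substitution at an aligned position, GV is the scaled diameter of
the property box spanned by the residues observed at that column (gaps
and ambiguous residues excluded; the human residue is part of the
alignment and hence of the box), and GD is the scaled distance from the
variant residue to that box (zero inside). Grades: GD = 0 → C0;
otherwise, when GV is below a conservation cutoff, the grade is the
highest threshold in {15, 25, 35, 45, 55, 65} that GD reaches; positions
with GV at or above the cutoff grade C0. The cutoff defaults to 61.3,
the GV break of the published grading surface; the full boundary table is
a config object (`GradeBoundaries`), so a different published surface can
be dropped in without code changes. Only the grade *ordering* and the
C0/non-C0 split enter the downstream statistics, which is why a
single-cutoff surface suffices as the default.

Two consequences the tests exercise: restricting to a taxon subset
(mammals-only) can only shrink the observed box, so subset grades are
always ≥ full-alignment grades; and at an invariant column GD reduces to
the pairwise Grantham distance, so a radical substitution there grades
C65 under any surface.

A last-exon frameshift is graded by scanning the scrambled tail against
the reference tail position by position and taking the most severe
missense score (grade first, larger GD breaking ties); scanning stops at
a premature stop codon in the scrambled frame.

Alignment depth is summarised by Fitch small parsimony per column (gaps
as missing data, contributing the universal state set), with the
alignment mean compared against the ≥ 3.0 substitutions-per-position
diversity criterion.

## Splice-damage calibration

Wild-type junction scores of each site kind (acceptor, donor) are pooled
into a calibration set — which junctions to pool is an *input*, since the
original calibration population is external to this package — and
variants are standardised as z = (s_variant − mean)/sd using the sample
sd (n−1). Only variants that reduce their own junction's score can be
damaging: z ≤ −2 → severe (damage probability 0.95), −2 < z ≤ −1 →
moderate (0.40), else innocuous. The boundary z = −2 is assigned to the
severe band: the bands are approximations, and the tie goes to the
stronger call. Graded severity is damage probability × 6, i.e. 5.7 and
2.4; this makes severity = 6 × p exactly, an invariant the tests check,
and is the arithmetic behind the two non-integer grades in the severity
scheme.

## Statistics

- Crude ORs are (a·d)/(b·c) with Woolf log-normal 95% CIs. Any zero cell
  switches the row to the two-sided Fisher exact p with an undefined OR —
  matching how the source tables report zero-control classes.
- Adjusted ORs and trend slopes come from statsmodels GLM/Binomial
  (IRLS), log-likelihood tolerance 1e−8, at most 100 iterations.
  Non-convergence or a coefficient diverging past |β| > 15 raises a
  separation diagnostic instead of returning a silent estimate. P-values
  are likelihood-ratio tests of the exposure term (χ², 1 df).
- The graded trend reports β (ln(OR) per grade), its Wald CI, the LRT p,
  the modeled OR at the top grade exp(6β) (a definitional identity), and
  an observed OR comparing carriers at grade ≥ cutoff (default: exactly
  the top grade) with all other subjects. The published grouping behind
  the observed-OR column is not fully specified, so the cutoff is
  configurable rather than hard-coded.
- The r×c exact heterogeneity test enumerates all tables with the
  observed margins and sums the probabilities of tables no more probable
  than the observed one (probability ordering; on 2×2 tables this is
  exactly two-sided Fisher). When the enumeration bound (2×10⁶ tables)
  is exceeded it falls back to seeded Monte-Carlo sampling of
  fixed-margin tables with the add-one correction; the replicate count
  and seed are arguments.
- Frequency-bin analyses assign each variant to one half-log-decade bin
  (1–0.32%, 0.32–0.1%, 0.1–0.032%, <0.032%) by its *maximum* frequency
  across reference populations — conservative, since a variant common
  anywhere is not rare. Pseudo-cases/pseudo-controls for clinical-testing
  data follow the definition: affected non-carriers of pathogenic
  variants in either gene versus affected carriers of a pathogenic
  variant in the partner gene.

## The simulator

`simulate_cohort` draws the study's conditions by default: 1,312 cases
and 1,121 controls; ethnicity margins Caucasian 848/967, East Asian
208/71, Latina 158/47, African ancestry 98/36; center margins Australia
593/522, Canada 302/463, Northern California 417/136; age bands matching
the frequency-matched design (generated, carried, but never adjusted
for). Ethnicity, center and age band are assigned independently within
each arm, so the margins are exact but the joint distribution is
product-form — adequate for exercising stratified adjustment, not a copy
of the real joint table.

Per-class carrier prevalences in controls default to the observed
control counts (e.g. 3/1,121 for truncating, 5/1,121 for key-domain
missense, 10/1,121 for silent) and per-class ORs to values near the
reported estimates (2.6 truncating/severe splice, 3.1 key-domain
missense, 1.0 for the innocuous classes). Carriage is drawn per stratum
with odds(carrier | case) = OR × odds(carrier | control), which makes
the configured OR the exact estimand of the logistic analysis stage;
ethnic-clustering weights multiply the control-arm odds in selected
strata to reproduce the confounding phenomenon discussed below. One
variant per carrier by default (`multi_variant_rate` adds second, silent
variants to exercise collapsing). Reference frequencies are drawn
log-uniform below the 0.1% threshold.

What the simulator does *not* emulate: linkage between variants, the
real joint ethnicity×center table, measurement error in mutation
screening (sensitivity/specificity of melt-curve scanning), and real
per-gene variant spectra. Passing end-to-end tests therefore demonstrate
that the *analysis machinery* recovers known truth under the modelled
sampling scheme, not that the biological findings would replicate.

`simulate_alignment` evolves a gapless protein alignment down a seeded
birth-death tree, with a per-column expected substitution-event count as
the conservation profile. Fitch parsimony slightly undercounts the
placed events (parallel and reverting events collapse), so a profile of
3.0 yields parsimony means a little below 3 — the scripts report the
realised value. `simulate_splice_scores` draws wild-type scores
Normal(8.5, 1.5²) — a plausible donor-score scale — and applies
configured additive effects, recording ground-truth categories from the
generating parameters.

## Adjustment behaviour

Two properties replace the unavailable per-subject covariate data of the
original cohort as acceptance checks. First, with carriers spread evenly
across strata, adjusted ≈ crude. Second, when carriers cluster in strata
whose case:control ratio is about 3:1 (as the East Asian and Latina
strata are), the crude OR is biased upward and adjustment shrinks it —
the phenomenon observed for the top-grade missense class. Third, the
Wald 95% CI of the adjusted OR covers a true OR of 3 at study size with
empirical coverage within binomial error of 95% over 200 seeded
replicates (replicates with complete separation — roughly 1 in 200 at
these carrier counts — are excluded as having no defined CI).

## Numerical and design choices

- Severity scheme, grade-severity map, splice band probabilities, rarity
  threshold (0.001) and population set are config values; the defaults
  are the study's scheme. The threshold is configurable because the
  empirical threshold differs by gene class (0.32% for a gene tolerant
  of biallelic loss).
- Domain coordinates are 1-based inclusive; an indel span overlapping a
  key domain by any amount counts as inside. Explicitly non-key domains
  (the second DNA-binding domain of MRE11A) are carried in the
  annotation table with `is_key = false`; the toy intervals shipped by
  the simulator are synthetic stand-ins, not curated boundaries.
- cDNA changes are opaque strings; no HGVS parsing. Structured fields
  (protein position, ref/alt residues, last-exon flag, splice-region
  kind) are explicit columns, validated on read with row-addressed
  errors.
- A splice-region variant that is also exonic takes the splice class
  only when predicted damaging; otherwise it keeps its exonic class —
  one class per variant.
- Desk-scale problem sizes throughout: the published-count re-analyses
  are instantaneous; simulation-based checks use 25–200 study-sized
  replicates, a few seconds each batch.

## Known limitations

- The default grade-boundary surface is a documented single-cutoff
  stand-in for the full published Align-GVGD surface; analyses that
  depend only on grade ordering and the C0 split (all of the statistics
  here) are insensitive to this, but per-variant grades in the C15–C55
  mid-range can differ from the published tool's.
- The exact heterogeneity test's Monte-Carlo fallback is an estimator;
  its add-one p never returns exactly the enumerated value, only a
  seeded approximation.
- `build_pseudo_cohort` expects per-gene pathogenicity flags already
  assigned; classifying pathogenicity of the partner-gene variants is
  out of scope.
- No meta-analysis, segregation analysis, or multiple-testing
  correction: reported p-values are nominal, as in the source analyses.
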