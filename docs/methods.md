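# Methods

This note documents the statistical models implemented in `famsubtype`,
the assumptions behind them, the conventions chosen where several were
defensible, and what the synthetic-data validation does and does not
establish.

## Cohort FRR estimation

### Data model and eligibility

The at-risk cohort consists of mothers and sisters of breast-cancer
probands (daughters are not modelled; probands contribute subtype labels
but no person-time). A relative enters follow-up at the later of the
cohort start (default 1 January 1960, below which reference rates are
unreliable) and her birth, and exits at the earliest of: breast-cancer
diagnosis, any other cancer diagnosis, death, the family's questionnaire
date, and her 85th birthday. Relatives born before 1890 are excluded, as
are relatives with no at-risk time (for example an event before cohort
entry). When two censoring events share a date, the tie is broken in the
order breast cancer > other cancer > death > questionnaire > age cap, so a
same-day diagnosis counts as an event; the order is a configurable
argument.

Missing birth dates are imputed from the proband: mothers 30 years before
her birth, sisters the same year. Dates are decimal years internally; ISO
dates convert exactly by day-count/365.25, and bare years in the TSV map
to exact mid-year (Y + 0.5), a convention chosen over literal July 1 so
that reading and writing are mutually inverse to the byte (July 1 falls on
day 182 or 183 depending on leap years; the difference is under 0.005
years).

Tumour subtypes follow the standard immunohistochemical grouping: luminal
when ER and/or PR is positive (split by HER2 where known), non-luminal
HER2-positive when ER and PR are negative with HER2 positive, triple
negative when all three are negative, and unclassifiable when the deciding
markers are unknown. The classification is total over all 27 status
combinations.

### Expected counts and the estimator

Reference incidence is a piecewise-constant surface on half-open
age x calendar-period rectangles; a table must tile its rectangle with no
gaps or overlaps, and rates are stored per woman-year. Each follow-up
interval is cut at every age-band and period crossing of the woman's
life-line (along which age and date advance together), so each segment
lies in exactly one cell and E = Σ person-years × rate. Person-years are
conserved to 1e-9 years, asserted by property tests. The production path
vectorizes this by iterating over grid cells rather than people; its exact
equality with the per-interval expansion is itself a test. Follow-up
outside the rate grid is an error by default; an opt-in `truncate` policy
clips to the grid edges (and drops an event whose exit is clipped away),
because silent truncation hides data problems.

The stratum estimate is the standardized incidence ratio λ = O/E. Because
relatives cluster in families, the variance treats families as independent
units: with per-family observed o_f and expected e_f, the cluster-score
(sandwich) variance of the one-parameter Poisson SIR model is
Var(log λ) = Σ_f (o_f − λ e_f)² / O², with 95% intervals computed on the
log scale and exponentiated. Strata with no events report λ = 0 with the
exact one-sided Poisson upper bound 3.69/E, avoiding log(0). Subtype
heterogeneity is a two-sided Wald test on the difference of log-FRRs with
summed robust variances, assuming disjoint families between strata (true
for marker-defined strata; the "all cases" stratum overlaps both and is
never tested against its own components). Nelson–Aalen curves use risk
sets honouring left truncation (at risk at t when entry < t ≤ exit), tied
events as a single d/n increment, and variance increments d/n².

When only aggregate O and E are available (published table rows), 
`frr_from_counts` falls back to the independent-Poisson variance 1/O on
the log scale; published confidence intervals are method-dependent and are
not reproduction targets.

## Locus-attributable familial relative risk

For a biallelic locus with listed-allele frequency p (taken as published,
whether or not it is minor) and genotypic risks (1, r1, r2) relative to
common homozygotes, λ* = E[r(proband)·r(relative)]/E[r]² over the joint
genotype distribution of the pair. The joint is constructed exactly:
Hardy–Weinberg parent plus one transmitted and one population allele for
parent–offspring pairs, and two shared Hardy–Weinberg parents with
independent transmissions for siblings. λ* ≥ 1 for any positive risks
(the kinship covariance of risk is non-negative), with equality only for a
null locus; protective alleles therefore still give λ* ≥ 1. The offspring
kinship is the default and is applied to all first-degree relatives, as is
conventional; sibling kinship is available and exceeds offspring whenever
r2 > r1² (dominance variance).

Percent attribution against an observed subtype FRR λ₀ is
100·ln(λ*)/ln(λ₀) under the multiplicative joint-effect model and
100·(λ*−1)/(λ₀−1) under the additive alternative. Panel totals sum the
per-locus percentages (the conventional presentation); the table also
carries the compounded product of λ* values for reference. Natural
logarithms are used; the ratio of logs makes the base immaterial.
Confidence intervals on λ* and linkage disequilibrium between loci are out
of scope.

## Major-gene model

A deliberately reduced single-locus model: one rare dominant allele
(frequency f ≤ 0.05), carrier status collapsing one and two copies, and
yearly subtype-specific hazards per carrier status on an age grid
(default 20–85). Cumulative incidence uses the discrete product
1 − Π(1 − h); subtype-specific cumulative incidences are survival-weighted
hazard sums and add exactly to the overall curve. The carrier-status joint
for a first-degree pair collapses the exact biallelic enumeration — no
rare-allele ½-kinship shortcut, which is instead available as a
cross-check in tests.

FRR(t) is the likelihood ratio of the relative's risk by age t given the
proband's diagnosis to the population risk by t. The proband's diagnosis
is conditioned through a per-genotype likelihood that averages the yearly
subtype-restricted incidence over a case-age weight distribution
(configurable to a fixed diagnosis age). The overall FRR averages FRR(t)
over the relative's attained ages 20–70 with case-incidence weights —
weighting by the relative's age was chosen over the proband's where the
convention is ambiguous; ages at which the population risk is still zero
carry no information and are dropped with weights renormalized. The
subtype-specific FRR restricts both members' disease to the subtype with
the population subtype risk as denominator; with a genotype-independent
subtype mix it provably collapses to the any-subtype FRR.

The packaged `brca1_like.yaml` and `demo_gene_spec()` are illustrative
parameterizations (rare allele, 15-/6-fold young/old carrier hazards,
ER-negative-shifted carrier tumours) in the published order of magnitude
for a BRCA1-like gene; they demonstrate the qualitative behaviour —
subtype-specific FRR ≥ any-subtype FRR ≥ 1 under carrier enrichment — and
are not a reproduction of any published penetrance analysis, whose inputs
are not public.

## Synthetic cohorts and what the validation shows

The generator emulates the emulated study's structure: questionnaires
uniform over 1996–2005, probands diagnosed at incidence-weighted ages
30–69 shortly before the questionnaire, one mother (born 20–40 years
before the proband, clipped to post-1890 births) and a Poisson(1) number
of sisters (born within ±8 years, truncated at five), and ER/PR/HER2
availability of 62%/34%/26%. Relatives' breast-cancer times are drawn by
exact inversion from the piecewise-constant cumulative hazard along the
life-line — multiplier λ times the reference rate in the constant-frailty
mode, or the genotype's relative risk normalized to unit population mean
in the locus and major-gene modes, with genotypes transmitted through
explicitly sampled parental genotypes so mothers and sisters are jointly
Mendelian-consistent. Censoring uses a Gompertz death hazard
(5e-5·e^{0.085·age}) and an independent constant other-cancer hazard
(1e-3/year from age 30). Identical configuration and seed give
byte-identical output.

In the constant-λ mode the estimand of O/E is exactly λ, which gives the
calibration its clean semantics: across 200 null replicates of 5000
families the mean FRR lies within 1.00 ± 0.02 and the robust intervals
cover 1.0 at 95% ± 3%; at λ = 2 the mean recovered FRR lies in
[1.9, 2.1]. In the genotype modes the truth record stores the
hazard-scale estimand E[r_relative | proband case, stratum]/E[r]; with
strong multipliers the O/E estimate sits slightly below it because
high-risk relatives deplete their own person-time — a real feature of
standardized-incidence-ratio estimation, kept mild in the loop-closure
test by using moderate genotypic risks.

What passing these tests shows: the estimator, the Lexis arithmetic, the
clustered variance, and the locus and major-gene algebra are internally
consistent and recover known truth under the generator's assumptions.
What they do not show: robustness to features of real family-history data
the generator omits — reporting error in relatives' cancers, marker
misclassification, secular screening trends, survival bias in prevalent
cases, and dependence between censoring and risk.

## Numerical conventions

Half-open intervals on both grid axes remove boundary ambiguity (a point
on a shared edge belongs to the upper cell). Segment person-years and
expected counts are accumulated in double precision; conservation is
asserted at 1e-9 years and oracle equalities at 1e-12. The λ ≥ 1
invariants tolerate 1e-9 of floating slack before rejecting an input. Test
problem sizes (replicate counts, pair counts of 10⁶ for the Monte-Carlo
cross-checks) were chosen so Monte-Carlo error is small against the
asserted tolerances while the whole suite runs in about a minute.
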