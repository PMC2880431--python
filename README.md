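# famsubtype

Familial relative risk (FRR) of breast cancer by tumour subtype: a cohort
FRR estimator against reference incidence rates, a susceptibility-locus
attribution calculator, a single-locus Mendelian major-gene model, and a
ground-truth cohort simulator.

## The scientific problem

First-degree relatives of breast-cancer patients face roughly twice the
general-population risk. Breast cancer is heterogeneous, however, and the
familial risk may depend on the tumour's immunohistochemical subtype
(ER/PR/HER2 status) of the index case. This package provides the analysis
machinery for that question, aimed at genetic epidemiologists working with
questionnaire-based family-history cohorts:

* **Cohort FRR estimation.** Relatives of probands form a retrospective
  cohort. Each woman's follow-up (entry at 1 January 1960 or birth,
  censoring at the first of any cancer, death, questionnaire completion or
  age 85) is split into age-band x calendar-period segments (a Lexis
  expansion), and the expected number of breast cancers is
  E = Σ person-years × reference rate. The stratum FRR is the
  standardized incidence ratio **λ = O/E**, with a family-clustered
  sandwich variance of log(O/E),
  `Var(log λ) = Σ_f (o_f − λ e_f)² / O²`, giving robust 95% intervals,
  Wald heterogeneity tests between subtypes, and Nelson–Aalen cumulative
  hazard curves with left truncation.

* **Locus contributions.** A biallelic susceptibility locus with risk-allele
  frequency *p* and genotypic relative risks (1, r₁, r₂) induces a
  first-degree familial relative risk

  λ\* = E[risk(proband)·risk(relative)] / E[risk]²,

  computed by exact enumeration over the Mendelian parent–offspring (or
  sibling) joint genotype distribution under Hardy–Weinberg frequencies.
  The locus explains `100·ln(λ*)/ln(λ₀)` percent of an observed FRR λ₀
  under a multiplicative joint-effect model, or `100·(λ*−1)/(λ₀−1)`
  percent under an additive one. A packaged table carries twelve published
  GWAS loci with ER-subtype-specific odds ratios.

* **Major-gene model.** For a rare dominant allele (a BRCA1-like gene) with
  genotype- and subtype-specific age penetrances, the age-specific FRR is
  the likelihood ratio
  `FRR(t) = P(relative affected by t | proband affected with subtype s) /
  P(affected by t)`, summed over the exact carrier-status joint
  distribution, averaged over ages 20–70 with case-age weights, including
  the subtype-specific variant in which pathology concordance arises only
  through genotype.

* **Synthetic cohorts.** Families (proband + mother + sisters) with
  genotype- or frailty-driven hazards proportional to the reference rates,
  the same censoring structure, and a serialized truth record — so every
  estimator is validated closed-loop without access to any original study
  data.

## Worked example

Per-locus FRR and percent attribution for the packaged twelve-locus panel,
against subtype FRRs λ₀ = 1.78 (ER−) and 1.82 (ER+):

```python
from famsubtype import read_locus_table, build_locus_table

table = build_locus_table(read_locus_table(),
                          {"ER-negative": 1.78, "ER-positive": 1.82})
```

The first rows and the totals (λ* to 4 dp, %FRR to 2 dp):

```
            name  lambda_ER-negative  pct_mult_ER-negative  lambda_ER-positive  pct_mult_ER-positive
     10q26/FGFR2              1.0016                  0.28              1.0186                  3.08
16q12/TNRC9-TOX3              1.0036                  0.63              1.0089                  1.48
     5q11/MAP3K1              1.0009                  0.16              1.0028                  0.46
TOTAL_multiplicative          1.0109                  1.88              1.0591                  9.59
```

FGFR2 alone accounts for 3.08% of the log familial relative risk for
ER-positive disease; the panel together explains ~1.9% (ER−) and ~9.6%
(ER+) multiplicatively (1.4% and 7.0% under the additive model).

A full cohort round trip on simulated data with a true familial relative
risk of 2:

```python
from famsubtype import (SimulationConfig, simulate_cohort,
                       simulate_rate_table, run_subtype_analysis)
from famsubtype.frr_estimation import round_report

table = simulate_rate_table()
families, truth = simulate_cohort(
    SimulationConfig(n_families=5000, seed=1, frr=2.0), table)
print(round_report(run_subtype_analysis(families, table, grouping="ER",
                                        by_role=False)).to_string(index=False))
```

```
      label window index_age role  observed  expected  frr  ci_lo  ci_hi  n_families
        all   full       any  all       693    340.63 2.03   1.89   2.19        5000
ER-negative   full       any  all        90     40.71 2.21   1.79   2.73         588
ER-positive   full       any  all       355    166.95 2.13   1.92   2.36        2464
```

The all-cases estimate (2.03, CI 1.89–2.19) recovers the generating λ = 2;
the ER strata cover fewer families because marker status is available for
only a realistic fraction of probands.

A command-line interface mirrors the library:
`famsubtype classify|frr|locus-contrib|major-gene|simulate --help`.

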