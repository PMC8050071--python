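# Methods

## Analysis model

The pipeline quantifies qPCR gene expression by the comparative-Ct method.
Within each sample, ΔCt = Ct(gene) − Ct(*RPL27*) removes the per-sample
loading/efficiency offset; subtracting the healthy-control median ΔCt per
gene (ΔΔCt) and exponentiating gives a fold change FC = 2^−ΔΔCt that is 1 at
the healthy-control median. No amplification-efficiency correction is
applied: the method assumes near-ideal doubling per cycle, which is the
convention the composite score was defined under.

The composite type I IFN score is the median fold change over a fixed IRG
panel (seven genes for whole blood; six for PBMC, where *IFIT1* is dropped).
The median makes the score robust to a single outlying gene and
scale-equivariant (scaling all of a sample's fold changes by k scales the
score by k). Positivity is called against mean + 2·SD of the healthy-control
scores, computed independently per specimen type — whole-blood and PBMC
analyses never share a calibration, because baseline ΔCt distributions
differ between specimen types. Under a normal null this calibration admits
≈ 2.3% of healthy controls; because fold-change distributions are
right-skewed, observed healthy-control positivity rates a little above that
are expected.

Group comparisons are nonparametric throughout (fold changes are lognormal,
and Shapiro–Wilk screening of such data rejects normality): Kruskal–Wallis
with tie correction for the omnibus test, then Dunn's z tests on the pooled
midranks for all pairwise comparisons. Spearman correlations quantify
association with clinical covariates; |r| > 0.5 is classified strong,
|r| < 0.3 weak, the boundaries inclusive to moderate. A correlation is
flagged only when it is both strong and significant (p < 0.05).

## Tunable parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `rin_min` / `yield_min` | 6 / 30 | RIN / ng·µl⁻¹ | RNA integrity and yield cut-offs; strict inequalities ("greater than") |
| panel (whole blood / PBMC) | 7 / 6 genes | — | IRG signatures; PBMC drops *IFIT1* |
| threshold SD denominator | n − 1 | — | sample SD; `ddof=0` exposed since the choice is material only at small n |
| Dunn adjustment | Bonferroni | — | the convention of mainstream prism-style software; Holm and Šidák available |
| α | 0.05 | — | two-sided throughout |
| power noncentrality | textbook | — | λ = n·Σ(μᵢ−μ̄)²/σ²; the between-variance convention (×k/(k−1)) is available as `convention="between-var"` |

With k = 4, α = 0.05, standardized means (0, 0.25, 0.5, 0.75), the textbook
convention gives power 0.846 at n = 40 and 0.866 at n = 42; the
between-variance convention gives 0.94–0.95. Both conventions are
implemented because power tools disagree silently on this point.

## Synthetic-data generator

The generator emulates a multi-cohort observational study. Ct values follow

    Ct(g, s) = refCt(s) + baselineΔCt(g) + shift(g, cohort(s)) + ε,

with refCt(s) ~ N(20, 0.5) shared by all genes of a sample (so it cancels
exactly in ΔCt, isolating the ΔΔCt arithmetic) and ε ~ N(0, σ) i.i.d. per
well, σ = 1 cycle by default. Fold changes are therefore lognormal with
ΔΔCt variance 2σ² (target and reference wells are both noisy) — the
analytic mean E[2^−ΔΔCt] = 2^−shift·exp((ln2)²·2σ²/2) is the oracle for the
parameter-recovery tests. Shifts are in cycles; negative shift = elevated
expression.

Default planted structure: IRG shift −3 (8-fold elevation before noise) in
SLE (whole blood) and pSS (PBMC) only; *MMP8*/*ANXA3* shift −1.5 in active
AAV only; serum CXCL10 log-mean raised by 0.9 (≈2.5-fold) in treatment-naive
active AAV only, with the healthy-control log-mean anchored so the median is
≈ 93 pg/ml; every other effect null. Cohort sizes default to the per-assay
arm sizes of a 217-participant study (whole blood 62/29/27/31/10/19, PBMC
5/4/6/6/9). BVAS is drawn uniformly on 3–32 for active disease and is 0
otherwise; CRP and creatinine are lognormal with cohort-independent
parameters inside AAV, so clinical covariates are independent of every
interferon measure by construction — the null the correlation analysis is
supposed to recover. A configurable 5% of samples is generated failing RNA
QC to exercise the filter.

What the generator does **not** emulate: amplification kinetics, primer
efficiencies, plate/batch effects, undetermined-Ct censoring at the
instrument limit, matched longitudinal samples, cell-type composition
effects, and correlations between clinical covariates and disease biology
beyond group membership. Passing recovery tests therefore demonstrates the
*procedures* are correct and calibrated, not that real cohorts behave this
way.

## Numerical and design choices

- Medians over even counts use the mean of the two central order statistics.
- Missing Ct propagates: a sample missing the reference Ct contributes no
  ΔCt; a sample enters the IFN score through its non-missing panel genes
  only, and is excluded (logged) when all are missing. No Ct-40 imputation
  by default.
- Samples with missing QC metadata pass the filter with a warning — real
  cohorts retain donors whose QC fields were never recorded.
- Positivity ties at the threshold are negative (strict "greater than").
- Positivity percentages use scored-sample denominators (post-QC), rounded
  to one decimal.
- Kruskal–Wallis on pooled-constant input returns H = 0, p = 1 rather than
  erroring; Dunn adjusted p-values are clipped at 1 and are monotone in the
  raw p-values.
- "Elevated" flagging in the report: a cohort is flagged when its Dunn
  comparison against the same-specimen healthy controls has adjusted
  p < 0.05 and its mean rank is higher. With the default 5-donor PBMC
  control arm this flag is deliberately underpowered (≈40% for an 8-fold
  pSS elevation after Bonferroni over 10 pairs); the recovery test suite
  therefore runs the property at 100 samples per cohort, where power is
  effectively 1.
- Power λ residue below 1e−12 is cleared to zero so power(λ=0) = α exactly.
- All randomness flows through explicit integer seeds; there is no global
  random state. Test simulation sizes (200 null datasets for calibration,
  50 replicate pipelines for recovery, 10⁵ Monte-Carlo ANOVA replicates)
  were chosen to bound the binomial noise of each asserted rate well below
  its tolerance.

## Limitations

- The assumed Ct noise (σ = 1 cycle) and per-gene baselines are stated
  defaults, not estimates from data; both are configurable in the design.
- The balanced-power calculation treats "mean samples per group" as the
  common n; an unbalanced exact calculation would differ slightly.
- The χ² approximation to the Kruskal–Wallis null is inaccurate for total
  N ≲ 8 (the test suite documents the gap against exact permutation).
- Serum proteins are generated for every sample, whereas a real study has
  partially overlapping assay subsets per participant.
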