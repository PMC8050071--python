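# ifnsig

Type I interferon gene-signature analysis for qPCR cohort studies.

Autoimmune conditions such as systemic lupus erythematosus (SLE) and primary
Sjögren's syndrome (pSS) are *type I interferonopathies*: their peripheral
blood shows constitutively elevated expression of interferon-regulated genes
(IRGs). Whether other autoimmune diseases — here, ANCA-associated vasculitis
(AAV) — share that signature is tested by scoring each patient sample against
healthy controls. `ifnsig` implements that analysis end to end for
quantitative PCR data, plus a synthetic multi-cohort generator so the whole
pipeline can be exercised and validated without patient data.

## The method

**Relative quantification (2^−ΔΔCt).** For each gene *g* and sample *s*,
with *RPL27* as endogenous control:

    ΔCt(g, s)  = Ct(g, s) − Ct(RPL27, s)
    ΔΔCt(g, s) = ΔCt(g, s) − median ΔCt(g) over healthy controls
    FC(g, s)   = 2^−ΔΔCt(g, s)

Samples first pass RNA quality control (RIN > 6 and yield > 30 ng/µl, strict
inequalities).

**IFN score.** The score of a sample is the median FC over a fixed IRG panel
— seven genes for whole blood (*ISG15, SIGLEC1, STAT1, RSAD2, IFI27, IFI44L,
IFIT1*), six for PBMC (dropping *IFIT1*). The positivity threshold is
calibrated per specimen type on healthy-control scores as **mean + 2 SD**; a
sample is IFN-positive iff its score strictly exceeds the threshold.

**Statistics.** Shapiro–Wilk normality screening; Kruskal–Wallis omnibus
tests with tie correction; Dunn's post hoc pairwise z tests (Bonferroni
adjustment by default, Holm/Šidák optional); Spearman correlations classified
weak (|r| < 0.3) / moderate / strong (|r| > 0.5); and balanced one-way ANOVA
power via the noncentral F distribution with λ = n·Σ(μᵢ − μ̄)²/σ².

## Worked example

```sh
ifnsig run-all --seed 1 --outdir run1
ifnsig report --manifest run1/manifest.json
```

runs simulate → quantify → score → stats on the default synthetic design
(208 samples: a whole-blood arm with HC/DC/AAV-remission/AAV-active/SLE and a
PBMC arm with HC/DC/AAV/pSS) and prints, among other tables:

| specimen | cohort | n | n_positive | pct_positive |
| --- | --- | --- | --- | --- |
| whole_blood | hc | 59 | 2 | 3.4 |
| whole_blood | aav_r | 26 | 1 | 3.8 |
| whole_blood | sle | 18 | 15 | 83.3 |
| pbmc | pss | 8 | 7 | 87.5 |

SLE and pSS — the planted interferonopathy cohorts — come out overwhelmingly
IFN-positive, while AAV and both control groups sit at the calibration's
nominal false-positive level; the AAV clinical-correlation matrix (BVAS, CRP,
creatinine) shows no strong or significant association (all |r| ≤ 0.23 in
this run), and the power table reports 0.83 and 0.85 for the two assays at
their post-QC mean group sizes (38 and 40). Every run writes a manifest with SHA-256 checksums of all
products; identical config + seed reproduces identical checksums.

The same stages are available as library functions (`ifnsig.generate_cohort`,
`ifnsig.qc_filter`, `ifnsig.relative_expression`, `ifnsig.ifn_score`,
`ifnsig.kruskal_wallis`, `ifnsig.anova_power`, ...) operating on pandas
DataFrames.

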