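# Methods

This note records the statistical models behind `grskit`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that matter for reproducing
results.

## Generating model (synthetic cohorts)

Individuals are drawn forward from a logistic disease model

```
eta = alpha + sum_h beta_h * dose_h + gamma(pair) + sum_j beta_j * dose_j
      + beta_sex * sex + sum_k beta_PCk * PC_k
P(case) = expit(eta)
```

* Two `DQA1-DQB1` haplotypes per individual are drawn i.i.d. from the
  configured pool; `dose_h` is the copy count. `gamma(pair)` is added
  only when the individual's unordered haplotype pair exactly matches a
  configured interaction.
* Non-HLA SNP dosages are Binomial(2, MAF) draws — loci are
  unlinked by construction.
* Sex is Bernoulli(1/2) coded 0/1; principal components are standard
  normal. Missing dosages are injected uniformly at random at the
  configured rate.
* Exact case/control quotas are met by rejection sampling: individuals
  are drawn until both quotas fill; the raw case fraction among draws is
  reported in the truth record. Sampling aborts with a diagnostic after
  `max_draw_factor` draws per requested individual (default 2000) when
  a quota is essentially unreachable.
* The intercept `alpha` is a free knob: a case-control design fixes the
  sampling fractions, not the population prevalence, so no canonical
  value exists. Only SNP/haplotype *slopes* are recoverable from the
  retained sample — the logistic intercept absorbs the outcome-dependent
  sampling — which is exactly the property the recovery tests exploit.

Default haplotype pool: eight `DQA1-DQB1` haplotypes with frequencies
summing to 1, shaped like an East Asian DQ distribution — DR9-like
(0.18, β=+1.1), DR3-like (0.10, +1.3) and DR4-like (0.10, +0.9) risk
haplotypes, a neutral DQ8 (0.06), strongly protective `01:02-06:02`
(0.04, −1.8) and protective `01:02-05:02` (0.10, −0.9), plus neutral
fillers. Default interactions: +0.8 for the DR3/DR9 heterozygote (the
classic trans-complementing diplotype) and −0.4 for the DR9 homozygote.
Default additive SNPs are the six replicated type 1 diabetes loci with
their published MAF and per-allele log-odds (rs231770 +0.273,
rs9274655 +1.323, rs10232170 −0.391, rs11256442 −0.245, rs689 +1.031,
rs773125 +0.301).

**Tag-SNP LD injection.** For a haplotype with frequency p, each
chromosome's tag allele is the haplotype indicator flipped with error
rate ε. Then D = p(1−p)(1−2ε) and

```
r^2(eps) = p(1-p) (1-2 eps)^2 / (p_B (1-p_B)),   p_B = p(1-eps) + (1-p) eps
```

which decreases strictly from 1 (ε=0) to 0 (ε=1/2); ε is solved from the
target r² by Brent bracketing. Symmetric flipping was chosen over
simulating recombination because it gives an analytic, monotone control
of exactly the quantity the tagging step consumes.

**What the generator does not emulate:** genome-wide LD structure and
recombination maps, imputation uncertainty (dosages are exact expected
counts), population stratification beyond supplied PC effects,
relatedness, and genotyping batch effects. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to confounding that real array data can carry.

## QC and association

* MAF is computed on non-missing dosages; Hardy-Weinberg uses the
  conditional exact test (two-sided by probability mass, enumerating all
  heterozygote counts consistent with the allele counts) on hard calls
  (dosage rounded to nearest integer), evaluated **in controls only** —
  in cases, true disease associations distort genotype proportions, so
  filtering on case HWE would remove signal. Defaults: MAF < 0.05,
  HWE p < 10⁻⁴, missingness > 0.05, all configurable; a variant is kept
  iff no filter fires.
* Association is maximum-likelihood logistic regression (statsmodels
  Newton/IRLS) of 1/0 status on dosage plus covariates screened
  marginally at p < 0.05. Perfect separation and non-convergence are
  flagged results, never silent numbers; |β̂| > 30 is treated as
  separation. Missing dosages are mean-imputed per variant, preserving
  the sample size while contributing no association signal.
* Wald statistics throughout (matching OR/CI reporting conventions);
  suggestive (10⁻⁵) and genome-wide (5×10⁻⁸) thresholds are annotations,
  not filters.
* λ (genomic inflation) = median observed χ²₁ / 0.4549364.
* Meta-analysis is inverse-variance fixed-effect — the standard choice
  for a two-cohort discovery/replication design, where a random-effects
  variance component cannot be usefully estimated. Swapped effect/other
  alleles flip the sign of β before pooling; any other allele pairing is
  an error.

## Haplotypes, LD and tags

* Inference from unphased typing: a two-locus genotype admits at most
  two phasings; the one maximising the product of pool frequencies wins
  (ties broken lexicographically and flagged). This is the two-locus
  special case of EM haplotype reconstruction; with no external
  frequency table, pool frequencies are first estimated by the EM
  itself (E-step weights phasings by current frequency products).
* Group frequencies are chromosome-level; a haplotype is kept when its
  frequency exceeds 0.5% in case *and* control chromosomes. The filter
  is applied to chromosome frequencies rather than carrier fractions:
  frequencies are the scale on which the downstream LD and dose
  calculations operate (a carrier-fraction reading would be about twice
  as permissive).
* r² and D′ follow the standard Lewontin definitions from the phased
  2×2 table (D′ = 0 when D = 0). When phased chromosomes are not
  available, `ld_r2_dosage` falls back to squared Pearson correlation of
  expected counts; D′ is undefined in that mode and the fallback is
  explicit in the API rather than silent.
* Tag selection maximises r² per haplotype (ties: larger |D′|, then
  smaller position, then identifier), with a minimum acceptance r² of
  0.7 (configurable); haplotypes with no adequate candidate are reported
  untagged.

## Interaction modelling

Candidate haplogenotypes are all unordered pairs (homozygotes included)
with ≥ 10 carriers (separation guard). Each pair is tested in its own
logistic model containing main-effect dose columns for every kept
haplotype (the most frequent control haplotype dropped as reference;
never-carried columns dropped as unidentifiable), screened covariates,
and the pair's interaction term:

* heterozygous pair: `dose_A * dose_B` (the multiplicative dose-product
  term);
* homozygous pair: indicator(dose = 2) — the raw product (4) would be
  collinear with the additive dose and conflate the two effects.

One-pair-at-a-time testing with full main effects was chosen over one
saturated model: with 15+ candidate pairs, a simultaneous model is
fragile (many near-empty cells). The cost, demonstrated in
`examples/04`, is that a strong omitted interaction is partly absorbed
by tests of other pairs. Multiplicity control is Bonferroni by default
(FDR and none available). The exported lookup score per significant
pair is the fitted **carrier log-odds** — main-effect contributions of
the pair plus γ — because that is the quantity a scored individual's DQ
component should represent; the bare γ is available as an option.

## Score assembly and scoring

β = ln(OR) for every retained term. Non-DQ HLA terms are kept at
p < 4.72×10⁻⁴ (Bonferroni for ~106 tested HLA alleles), non-HLA at
p < 5×10⁻⁸; both configurable. DQ haplotype weights come from the
per-haplotype marginal logistic fit and enter without a p filter — they
are the backbone of the score. The DQ component uses the interaction
lookup *in place of* the additive sum for carriers of a tabulated
haplogenotype (the lookup already contains the main effects, so adding
them would double-count). Missing model SNPs score as dose 0 with a
per-cohort count; the decomposition `total = dq + hla_other + non_hla`
holds exactly for every individual. Models serialize to
schema-versioned JSON (unknown fields preserved in metadata with a
warning) and to a flat weight TSV.

The incremental-AUC curve adds non-DQ SNPs to the DQ base in ascending
association-p order, recomputing AUC at each prefix; the plateau is the
first size where the next addition's paired DeLong p ≥ 0.05. AUC is not
forced monotone — observed dips are reported.

## Discrimination

* AUC is the Mann-Whitney concordance probability with ties counted
  1/2 (midranks); positive calls use `score > t`.
* PRAUC is average precision (step-wise recall integration), not
  trapezoidal, which overestimates PR curves.
* DeLong variance uses structural components with midranks; paired
  design subtracts the component covariances, unpaired sums the two
  samples' AUC variances. No small-sample correction is applied: the
  normal approximation is used in its asymptotic regime (the
  calibration tests run at 200 cases / 200 controls, where the empirical
  type-I rate is 0.050; at 100/100 it is measurably anticonservative).
  The implementation agrees with the pROC reference to ~10⁻¹⁰ on fixed
  data.
* Cutoffs: the threshold for a requested specificity is that centile of
  the negative group's scores, type-7 (linear-interpolation) quantiles —
  stated explicitly because centile cutoffs are sensitive to quantile
  convention. A `direction='less'` mode mirrors the rule for low-score
  calls of the other class. Tertiles use the same convention.

## Problem sizes used in the shipped checks

Recovery runs use 200 replicates of 1300/2200 cohorts per locus;
type-I calibration uses 1000 replicates each (Wald SNP test at n=3000,
interaction test at n=3000 on the pair of the two 0.18-frequency
default haplotypes, DeLong at 200/200); tag recovery uses 10⁵
chromosomes; the pipeline demonstration uses 3000 individuals. These
sizes put every asymptotic test comfortably in its regime while keeping
the whole suite quick to run. Monte-Carlo error bars in tests are
estimated from the replicates themselves (or from per-block estimates
for single large simulations) rather than from normal-theory formulas,
which understate the sampling variance of r² for binary indicators.

## Known limitations

* Haplotype inference handles exactly two loci; extended `DRB1`-included
  haplotypes enter only through the labels.
* The one-pair-at-a-time interaction design misattributes omitted
  interactions (see above); interpret per-pair tables jointly.
* The dosage-correlation LD fallback cannot produce D′ and can differ
  from phased r² under departures from Hardy-Weinberg.
* Scores are on the log-odds scale of the fitting cohort; applying a
  model across cohorts assumes shared effect sizes and allele coding,
  and no recalibration utility is provided.
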