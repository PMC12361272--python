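# grskit

Construction and evaluation of **interaction-aware genetic risk scores
(GRS)** for case-control cohorts, of the kind used to discriminate type 1
diabetes from controls and from type 2 diabetes in East Asian populations,
where HLA `DQA1-DQB1` haplotype effects are strongly non-additive.

## The problem and the model

A conventional GRS is the weighted sum of risk-allele dosages

&nbsp;&nbsp;&nbsp;&nbsp;GRS<sub>i</sub> = Σ<sub>j</sub> β<sub>j</sub> · d<sub>ij</sub>,&nbsp;&nbsp; β<sub>j</sub> = ln OR<sub>j</sub>,

with weights from case-control logistic regression. In the HLA `DR-DQ`
region this misses the fact that particular *haplogenotypes* — unordered
pairs of `DQA1-DQB1` haplotypes, e.g. the trans-complementing DR3/DR9
heterozygote — carry risk far from the sum of their per-copy effects.
`grskit` builds a three-component score:

1. **DQ component** — if the individual's haplogenotype has a fitted
   interaction, its score is the looked-up haplogenotype log-odds (main
   effects + interaction term γ from a logistic model with multiplicative
   dose-product interaction terms); otherwise the additive
   β<sub>h1</sub> + β<sub>h2</sub> of the two haplotypes. Haplotypes are
   inferred from unphased four-digit typing by frequency-product
   maximisation (with a two-locus EM frequency estimator) and mapped to
   tag SNPs chosen by phased LD (r², tie-broken by |D′| and position).
2. **Other HLA component** — additive ln(OR) terms for HLA-region SNPs
   outside `DR-DQ`, retained at a Bonferroni threshold (default
   p < 4.72×10⁻⁴).
3. **Non-HLA component** — additive terms for genome-wide-significant
   SNPs (default p < 5×10⁻⁸).

Around the score sit the standard pipeline stages: SNP QC (monomorphic /
MAF < 0.05 / Hardy-Weinberg exact p < 10⁻⁴ in controls / missingness
> 0.05), per-variant logistic association with covariate screening at
p < 0.05, genomic inflation λ, inverse-variance fixed-effect meta-analysis,
and discrimination analysis: Mann-Whitney ROC AUC, average-precision
PRAUC, paired/unpaired DeLong tests, centile-based cutoff tables and
tertile stratification.

A first-class **synthetic cohort generator** draws individuals from the
forward logistic disease model (haplotype pool with per-copy effects,
haplogenotype interactions, tag SNPs at configurable target r², additive
SNPs, sex/PC covariates) with rejection sampling to exact case/control
quotas, and keeps the ground truth for parameter-recovery testing.

## Worked example

```python
import grskit as gk

pool = gk.default_haplotype_pool()
cfg = gk.SimulationConfig(
    n_cases=1100, n_controls=1900,
    haplotype_pool=pool,
    interaction_effects=gk.default_interaction_effects(),
    tag_specs={pool[0].label: 1.0, pool[1].label: 0.9, pool[2].label: 0.8},
    nonhla_snps=[gk.SnpSpec(*t) for t in gk.T1D_SNP_EFFECTS],
    covariate_effects=(0.2, [0.3]),
    intercept=-2.2, missing_rate=0.02, seed=42,
)
cohort = gk.simulate_cohort(cfg)
res = gk.run_pipeline(cohort)
print(res.evaluation["auc_total"], res.evaluation["auc_components"])
```

prints

```
0.7989 {'dq': 0.7134, 'hla_other': 0.5, 'non_hla': 0.6895}
```

i.e. the combined score (AUC 0.799) discriminates better than the DQ
haplotype component alone (0.713) or the non-HLA SNPs alone (0.690); the
other-HLA component is empty in this small simulation (0.5 = chance).
The `examples/` directory walks through each stage — simulation, QC and
association (recovering the generating per-allele log-odds), haplotype
inference and tagging, interaction modelling, and score evaluation with
cutoff tables and the incremental SNP-addition AUC curve.

A thin CLI mirrors the pipeline stages:

```bash
grskit simulate --config sim.yaml --out cohort/ --seed 7
grskit qc --vcf cohort/genotypes.vcf --pheno cohort/phenotype.tsv --out qc.tsv
grskit assoc --vcf cohort/genotypes.vcf --pheno cohort/phenotype.tsv --qc-table qc.tsv --out assoc.tsv
grskit evaluate --scores scores.tsv --pheno cohort/phenotype.tsv --out eval.json
```

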