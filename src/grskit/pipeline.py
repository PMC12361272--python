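"""End-to-end orchestration: QC -> association -> haplotypes -> tags ->
interactions -> risk-score assembly -> scoring -> evaluation.

Glue over the per-step modules, operating on a
:class:`~grskit.cohort.SyntheticCohort` (or the same tables read from
disk).  Each intermediate product is kept in the returned
:class:`PipelineResult` so callers can inspect or re-run any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc as _assoc
from . import haplotypes as _hap
from . import interactions as _inter
from . import model as _model
from .cohort import SyntheticCohort, tag_snp_id
from .evaluate import cutoff_table, pr_auc, roc_auc
from .genotypes import GenotypeMatrix

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    qc: _assoc.QCReport
    covariates_selected: list[str]
    gwas: list[_assoc.AssociationResult]
    lambda_gc: float
    haplotype_freqs: list[_hap.DQHaplotype]
    tags: list[_hap.TagAssignment]
    interaction_results: list[_inter.InteractionResult]
    interaction_table: dict
    model: _model.GRSModel
    scores: pd.DataFrame
    evaluation: dict
    hap_pairs: list = field(default_factory=list)


def _dq_association(
    y: np.ndarray, hap_doses: pd.DataFrame, covariates: pd.DataFrame | None
) -> dict[str, float]:
    """Per-haplotype marginal logistic beta (= ln OR per copy)."""
    out: dict[str, float] = {}
    for label in hap_doses.columns:
        X = pd.DataFrame({"dose": hap_doses[label].to_numpy()})
        if covariates is not None:
            for c in covariates.columns:
                X[c] = np.asarray(covariates[c], dtype=float)
        try:
            fit = _assoc.fit_logistic(y, X)
        except ValueError:
            continue
        if fit.ok:
            out[label] = float(fit.table.loc["dose", "beta"])
    return out


def run_pipeline(
    cohort: SyntheticCohort,
    pool_freqs: dict[str, float] | None = None,
    min_tag_r2: float = 0.7,
    min_hap_freq: float = 0.005,
    min_carriers: int = 10,
    interaction_alpha: float = 0.05,
    interaction_correction: str = "bonferroni",
    hla_other_p: float = _model.HLA_OTHER_P,
    non_hla_p: float = _model.NON_HLA_P,
    specificity_grid=(0.90, 0.95, 0.99),
) -> PipelineResult:
    """Run the full risk-score construction and evaluation on one cohort.

    Haplotype inference uses ``pool_freqs`` when supplied (an external
    reference frequency table) and otherwise estimates frequencies from
    the cohort's own typing by two-locus EM.  Tag SNPs enter the score
    through the DQ haplotype dosages they mark; remaining SNPs are split
    into HLA-region (chromosome 6) and non-HLA groups for the additive
    components.
    """
    geno: GenotypeMatrix = cohort.genotypes
    y = np.asarray(cohort.phenotype)

    qc = _assoc.snp_qc(geno, y)
    selected = _assoc.screen_covariates(y, cohort.covariates)
    covars = cohort.covariates[selected] if selected else None

    gwas = _assoc.run_gwas(geno, y, covars, qc)
    pvals = [r.p for r in gwas if r.ok]
    lambda_gc = _assoc.genomic_inflation(pvals) if pvals else np.nan

    # --- HLA DQ haplotypes ---------------------------------------------
    if len(cohort.hla_typing):
        if pool_freqs is None:
            pool_freqs = _hap.estimate_pool_frequencies(cohort.hla_typing)
        inferred = _hap.infer_haplogenotypes(cohort.hla_typing, pool_freqs)
        hap_pairs = [
            (r.hap1, r.hap2) if r.resolved else None for r in inferred.itertuples(index=False)
        ]
    else:
        hap_pairs = [None] * geno.n_individuals
    resolved_pairs = [p for p in hap_pairs if p is not None]
    resolved_mask = np.array([p is not None for p in hap_pairs])
    freqs = (
        _hap.haplotype_frequencies(resolved_pairs, y[resolved_mask], min_hap_freq)
        if resolved_pairs
        else []
    )
    kept = [h.label for h in freqs if h.kept]

    # --- tag SNPs -------------------------------------------------------
    tags: list[_hap.TagAssignment] = []
    if kept and cohort.phased_tag_alleles:
        pos_by_id = {v.id: v.pos for v in geno.variants}
        candidates = {
            sid: (alleles, pos_by_id.get(sid, 0))
            for sid, alleles in cohort.phased_tag_alleles.items()
        }
        tags = _hap.select_tags(kept, candidates, cohort.phased_haplotypes, min_tag_r2)

    # --- interactions ---------------------------------------------------
    hap_doses = _hap.haplotype_dosages(hap_pairs, kept, index=cohort.individuals)
    complete = hap_doses.dropna()
    y_complete = y[resolved_mask]
    cov_complete = covars.loc[complete.index] if covars is not None else None
    inter_results: list[_inter.InteractionResult] = []
    inter_table: dict = {}
    if kept:
        cands = _inter.enumerate_haplogenotypes(complete, min_carriers)
        inter_results = [
            _inter.fit_interaction(y_complete, complete, c.pair, cov_complete) for c in cands
        ]
        inter_table = _inter.significant_interactions(
            inter_results, interaction_alpha, interaction_correction
        )

    # --- assemble and apply the score ----------------------------------
    dq_assoc = _dq_association(y_complete, complete, cov_complete) if kept else {}
    tag_ids = {t.snp for t in tags if t.tagged} | {tag_snp_id(h.label) for h in freqs}
    hla_other = [
        r for r in gwas if r.ok and r.chrom == "6" and r.id not in tag_ids
    ]
    non_hla = [r for r in gwas if r.ok and r.chrom != "6"]
    model = _model.build_model(dq_assoc, inter_table, hla_other, non_hla, hla_other_p, non_hla_p)
    scores = _model.score_cohort(model, hap_pairs, geno, list(cohort.individuals))

    total = scores["total"].to_numpy()
    evaluation = {
        "auc_total": roc_auc(total, y).auc,
        "prauc_total": pr_auc(total, y),
        "auc_components": {
            c: roc_auc(scores[c].to_numpy(), y).auc for c in ("dq", "hla_other", "non_hla")
        },
        "cutoffs": cutoff_table(total, y, specificity_grid),
        "lambda_gc": lambda_gc,
    }
    return PipelineResult(
        qc, selected, gwas, lambda_gc, freqs, tags, inter_results, inter_table,
        model, scores, evaluation, hap_pairs,
    )
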