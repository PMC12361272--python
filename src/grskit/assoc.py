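"""SNP-level quality control and case-control logistic association.

QC mirrors standard array-GWAS practice: variants are dropped when
monomorphic, rare (MAF below threshold), out of Hardy-Weinberg
equilibrium in controls (conditional exact test on hard calls), or too
often missing.  Association is per-variant logistic regression of
case/control status (coded 1/0) on the effect-allele dosage plus
pre-screened covariates, reporting per-allele log-odds, OR, 95% CI and
Wald p.  Cohorts are combined by inverse-variance fixed-effect
meta-analysis, and test-statistic calibration is summarised by the
genomic inflation factor lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .genotypes import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "LogisticFit",
    "AssociationResult",
    "MetaResult",
    "snp_qc",
    "hwe_exact_test",
    "fit_logistic",
    "screen_covariates",
    "run_gwas",
    "genomic_inflation",
    "meta_fixed",
    "results_to_frame",
]

CHI2_1_MEDIAN = 0.4549364231195724  # median of the chi-square(1) distribution
SUGGESTIVE_P = 1e-5
GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class QCThresholds:
    maf: float = 0.05
    hwe_p: float = 1e-4
    missing: float = 0.05


@dataclass
class QCReport:
    table: pd.DataFrame  # index variant id; columns kept, reasons, maf, hwe_p, missing_rate
    thresholds: QCThresholds

    @property
    def kept_ids(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed count (the standard exact formulation).
    Monomorphic samples return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotype calls")
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (relabel below if needed)
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # feasible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rr = (rare - hets) // 2
    n_cc = n - n_rr - hets
    logp = (
        gammaln(n + 1)
        - gammaln(n_rr + 1)
        - gammaln(hets + 1)
        - gammaln(n_cc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def snp_qc(
    geno: GenotypeMatrix,
    phenotype: np.ndarray | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Flag variants failing monomorphic / MAF / HWE / missingness filters.

    HWE is evaluated in controls only (phenotype == 0) on hard calls
    (dosage rounded to the nearest integer); with no phenotype given it
    falls back to the full sample.
    """
    if geno.n_variants == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    ctrl = np.ones(geno.n_individuals, dtype=bool)
    if phenotype is not None:
        phenotype = np.asarray(phenotype)
        ctrl = phenotype == 0
    rows = []
    for i, v in enumerate(geno.variants):
        col = geno.dosages[:, i]
        obs = col[~np.isnan(col)]
        miss = np.isnan(col).mean()
        reasons: list[str] = []
        if obs.size == 0 or np.all(obs == obs[0]):
            maf = 0.0 if obs.size == 0 else min(obs[0] / 2, 1 - obs[0] / 2)
            reasons.append("monomorphic")
            hwe_p = 1.0
        else:
            p = obs.mean() / 2.0
            maf = min(p, 1.0 - p)
            if maf < thresholds.maf:
                reasons.append("low_maf")
            hc = np.rint(col[ctrl & ~np.isnan(col)]).astype(int)
            counts = [(hc == 0).sum(), (hc == 1).sum(), (hc == 2).sum()]
            hwe_p = hwe_exact_test(*counts) if sum(counts) else 1.0
            if hwe_p < thresholds.hwe_p:
                reasons.append("hwe_fail")
        if miss > thresholds.missing:
            reasons.append("high_missing")
        rows.append(
            {
                "id": v.id,
                "kept": not reasons,
                "reasons": ",".join(reasons),
                "maf": maf,
                "hwe_p": hwe_p,
                "missing_rate": miss,
            }
        )
    table = pd.DataFrame(rows).set_index("id")
    return QCReport(table, thresholds)


@dataclass
class LogisticFit:
    """Coefficient table of a logistic fit, or a flagged failure."""

    table: pd.DataFrame | None  # index term; columns beta, se, z, p
    converged: bool
    separation: bool
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation


def fit_logistic(y: np.ndarray, X: pd.DataFrame | np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS via Newton steps).

    An intercept is always added.  Perfect separation and
    non-convergence are reported as flags with no coefficient table,
    never silently.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    if y.size != len(X):
        raise ValueError("y and X lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one case and one control")
    const = X.nunique() <= 1
    if const.any():
        raise ValueError(f"constant predictor column(s): {list(X.columns[const])}")
    design = sm.add_constant(X.astype(float), prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", RuntimeWarning)
            res = sm.Logit(y, design).fit(disp=0)
    except PerfectSeparationWarning as e:
        return LogisticFit(None, False, True, str(e))
    except Exception as e:  # noqa: BLE001 - any numerical failure is a flagged fit
        return LogisticFit(None, False, False, f"{type(e).__name__}: {e}")
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 30:
        return LogisticFit(None, False, np.abs(res.params).max() > 30, "did not converge")
    table = pd.DataFrame(
        {"beta": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
    )
    return LogisticFit(table, True, False)


def screen_covariates(
    y: np.ndarray, covariates: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Marginal logistic screen: retain covariates with Wald p < alpha.

    Constant or separation-flagged covariates are never selected (a
    warning is emitted for degenerate fits).  Column order is preserved.
    """
    selected: list[str] = []
    for name in covariates.columns:
        col = covariates[[name]]
        if col[name].nunique() <= 1:
            continue
        fit = fit_logistic(y, col)
        if not fit.ok:
            warnings.warn(f"covariate {name!r} excluded: {fit.message or 'degenerate fit'}")
            continue
        if fit.table.loc[name, "p"] < alpha:
            selected.append(name)
    return selected


@dataclass
class AssociationResult:
    """Per-variant case-control association summary (beta = per-allele
    log-odds of disease for the counted allele)."""

    id: str
    beta: float
    se: float
    p: float
    maf: float
    n_used: int
    effect_allele: str = "A"
    other_allele: str = "G"
    chrom: str = "1"
    pos: int = 0
    ok: bool = True
    message: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return float(lo), float(hi)

    @property
    def suggestive(self) -> bool:
        return self.ok and self.p < SUGGESTIVE_P

    @property
    def genome_wide(self) -> bool:
        return self.ok and self.p < GENOME_WIDE_P


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.ci95 if r.ok else (np.nan, np.nan)
        rows.append(
            {
                "chr": r.chrom,
                "pos": r.pos,
                "id": r.id,
                "a1": r.effect_allele,
                "a2": r.other_allele,
                "maf": r.maf,
                "beta": r.beta,
                "se": r.se,
                "or": r.odds_ratio if r.ok else np.nan,
                "ci_low": lo,
                "ci_high": hi,
                "p": r.p,
                "n": r.n_used,
                "ok": r.ok,
                "suggestive": r.suggestive,
                "genome_wide": r.genome_wide,
            }
        )
    return pd.DataFrame(rows)


def run_gwas(
    geno: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    qc: QCReport | None = None,
) -> list[AssociationResult]:
    """One logistic association per QC-kept variant.

    Missing dosages are mean-imputed per variant (sample size is
    preserved; the imputed value carries no association signal).  Fit
    failures propagate as flagged rows rather than omissions.
    """
    y = np.asarray(y)
    keep = set(qc.kept_ids) if qc is not None else None
    out: list[AssociationResult] = []
    for i, v in enumerate(geno.variants):
        if keep is not None and v.id not in keep:
            continue
        col = geno.dosages[:, i].copy()
        miss = np.isnan(col)
        obs = col[~miss]
        maf = float(min(obs.mean() / 2, 1 - obs.mean() / 2)) if obs.size else np.nan
        if miss.any() and obs.size:
            col[miss] = obs.mean()
        X = pd.DataFrame({"dose": col})
        if covariates is not None:
            for c in covariates.columns:
                X[c] = np.asarray(covariates[c], dtype=float)
        try:
            fit = fit_logistic(y, X)
        except ValueError as e:
            out.append(
                AssociationResult(v.id, np.nan, np.nan, np.nan, maf, len(y), v.a1, v.a2,
                                  v.chrom, v.pos, ok=False, message=str(e))
            )
            continue
        if not fit.ok:
            out.append(
                AssociationResult(v.id, np.nan, np.nan, np.nan, maf, len(y), v.a1, v.a2,
                                  v.chrom, v.pos, ok=False, message=fit.message)
            )
            continue
        row = fit.table.loc["dose"]
        out.append(
            AssociationResult(v.id, float(row["beta"]), float(row["se"]), float(row["p"]),
                              maf, len(y), v.a1, v.a2, v.chrom, v.pos)
        )
    return out


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed chi-square(1) statistic
    over the null chi-square(1) median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


@dataclass
class MetaResult:
    id: str
    beta: float
    se: float
    p: float
    inputs: list[AssociationResult] = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def meta_fixed(results_by_cohort: list[AssociationResult]) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis of one variant across
    cohorts.

    Effect alleles must be orientable: cohorts reporting the swapped
    allele pair enter with the sign of beta flipped; any other allele
    mismatch is rejected.
    """
    if len(results_by_cohort) < 2:
        raise ValueError("meta-analysis needs at least two cohorts")
    ref = results_by_cohort[0]
    betas, ws = [], []
    for r in results_by_cohort:
        if r.id != ref.id:
            raise ValueError(f"variant id mismatch: {r.id} vs {ref.id}")
        if (r.effect_allele, r.other_allele) == (ref.effect_allele, ref.other_allele):
            b = r.beta
        elif (r.effect_allele, r.other_allele) == (ref.other_allele, ref.effect_allele):
            b = -r.beta
        else:
            raise ValueError(
                f"{r.id}: alleles {r.effect_allele}/{r.other_allele} incompatible "
                f"with {ref.effect_allele}/{ref.other_allele}"
            )
        if not r.ok or not np.isfinite(r.se) or r.se <= 0:
            raise ValueError(f"{r.id}: unusable cohort result (se={r.se})")
        betas.append(b)
        ws.append(1.0 / r.se**2)
    betas, ws = np.array(betas), np.array(ws)
    beta = float((ws * betas).sum() / ws.sum())
    se = float(1.0 / np.sqrt(ws.sum()))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(ref.id, beta, se, p, list(results_by_cohort))
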