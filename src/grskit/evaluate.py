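"""Score discrimination: ROC / precision-recall AUC, DeLong tests,
centile-based cutoffs and group comparisons.

The AUC is computed as the Mann-Whitney concordance probability with
ties counted 1/2, which makes it exactly the probability that a random
case outscores a random control.  AUC differences are tested with
DeLong's structural-components variance estimator: paired when the two
scores are measured on the same individuals, unpaired (variances add)
when comparing AUCs from disjoint samples.  Clinical cutoffs are set at
empirical centiles of one group's score distribution (type-7 / linear
interpolation quantiles), the convention behind "the 95th centile of a
control population" style thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_curve

__all__ = [
    "ROCCurve",
    "DeLongResult",
    "roc_auc",
    "pr_auc",
    "delong_paired",
    "delong_unpaired",
    "cutoff_table",
    "stratify_and_compare",
    "tertile_assign",
]


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    var_diff: float
    z: float
    p: float
    design: str  # 'paired' | 'unpaired'


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size != labels.size:
        raise ValueError("scores and labels lengths differ")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative label")
    return scores, labels, pos, neg


def _mw_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (midranks)."""
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def roc_auc(scores, labels) -> ROCCurve:
    """Full ROC curve plus the Mann-Whitney AUC.

    Positive calls use the ``score > threshold`` rule; the returned curve
    includes the degenerate endpoints (sensitivity 0 / specificity 1 and
    sensitivity 1 / specificity 0).
    """
    scores, labels, pos, neg = _check_labels(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=_mw_auc(pos, neg),
        n_pos=pos.size,
        n_neg=neg.size,
    )


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve by the average-precision
    convention (step-wise sum over recall increments; trapezoids would
    systematically overestimate PR curves)."""
    scores, labels, _, _ = _check_labels(scores, labels)
    return float(average_precision_score(labels, scores))


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-observation structural components (V10 for cases,
    V01 for controls), midranks handling ties."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    r_all = rankdata(allv)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def _auc_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    auc, v10, v01 = _delong_components(pos, neg)
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_paired(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test of AUC_a - AUC_b for two scores on the same
    individuals; two-sided normal p-value.  Identical (or rank-identical)
    scores give z = 0, p = 1."""
    scores_a, labels, pos_a, neg_a = _check_labels(scores_a, labels)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_b.size != labels.size:
        raise ValueError("scores_b length mismatch")
    pos_b, neg_b = scores_b[labels == 1], scores_b[labels == 0]
    auc_a, v10_a, v01_a = _delong_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _delong_components(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if z == 0 else float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(max(var, 0.0)), float(z), p, "paired")


def delong_unpaired(scores_1, labels_1, scores_2, labels_2) -> DeLongResult:
    """DeLong comparison of AUCs estimated on disjoint samples; the
    variance of the difference is the sum of the per-sample DeLong AUC
    variances."""
    s1, l1, pos1, neg1 = _check_labels(scores_1, labels_1)
    s2, l2, pos2, neg2 = _check_labels(scores_2, labels_2)
    auc1 = _mw_auc(pos1, neg1)
    auc2 = _mw_auc(pos2, neg2)
    var = _auc_variance(pos1, neg1) + _auc_variance(pos2, neg2)
    diff = auc1 - auc2
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if z == 0 else float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc1, auc2, float(max(var, 0.0)), float(z), p, "unpaired")


def cutoff_table(
    scores,
    labels,
    specificity_grid=(0.90, 0.95, 0.99),
    direction: str = "greater",
) -> pd.DataFrame:
    """Centile-based cutoffs at requested specificities.

    ``direction='greater'``: the positive call is ``score > t`` and the
    threshold is the requested centile of the negative group (95%
    specificity -> 95th centile of controls).  ``direction='less'``
    mirrors this for a low-score rule (``score < t``, threshold at the
    lower tail of the negative group), the form used to call the
    *other* class.  Quantiles are type-7 (linear interpolation).
    Columns: threshold, sensitivity, specificity, centile_neg,
    centile_pos.
    """
    scores, labels, pos, neg = _check_labels(scores, labels)
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    rows = []
    for spec in specificity_grid:
        if not (0.0 < spec < 1.0):
            raise ValueError(f"requested specificity must be in (0,1), got {spec}")
        if direction == "greater":
            t = float(np.quantile(neg, spec))
            call_pos, call_neg = pos > t, neg > t
        else:
            t = float(np.quantile(neg, 1.0 - spec))
            call_pos, call_neg = pos < t, neg < t
        rows.append(
            {
                "threshold": t,
                "sensitivity": float(call_pos.mean()),
                "specificity": float(1.0 - call_neg.mean()),
                "centile_neg": float(stats.percentileofscore(neg, t, kind="mean")),
                "centile_pos": float(stats.percentileofscore(pos, t, kind="mean")),
            }
        )
    return pd.DataFrame(rows)


def tertile_assign(values) -> np.ndarray:
    """Tertile membership (0/1/2) by type-7 quantiles."""
    v = np.asarray(values, dtype=float)
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    return (v > q1).astype(int) + (v > q2).astype(int)


def stratify_and_compare(values, group_labels, mode: str = "nonparametric") -> dict:
    """Compare a continuous variable across groups.

    Two groups: t-test (``mode='parametric'``) or Mann-Whitney
    (``'nonparametric'``); more: one-way ANOVA or Kruskal-Wallis.
    Reports per-group n, median and IQR alongside the test.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    names = list(pd.unique(group_labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if mode not in ("parametric", "nonparametric"):
        raise ValueError("mode must be 'parametric' or 'nonparametric'")
    if len(groups) == 2:
        if mode == "parametric":
            stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
            test = "welch_t"
        else:
            stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            test = "mann_whitney"
    else:
        if mode == "parametric":
            stat, p = stats.f_oneway(*groups)
            test = "anova"
        else:
            stat, p = stats.kruskal(*groups)
            test = "kruskal_wallis"
    summary = {
        str(name): {
            "n": int(g.size),
            "median": float(np.median(g)),
            "iqr": [float(np.quantile(g, 0.25)), float(np.quantile(g, 0.75))],
        }
        for name, g in zip(names, groups)
    }
    return {"test": test, "statistic": float(stat), "p": float(p), "groups": summary}
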