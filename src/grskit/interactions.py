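"""Haplogenotype (diplotype) interaction modelling.

Whether two DQ haplotypes confer more (or less) risk in combination than
their per-copy effects predict is tested by logistic regression: main
effect dose columns for every kept haplotype (one reference dropped for
identifiability), screened covariates, plus a multiplicative interaction
term built from genotype dose values.  For a heterozygous pair the term
is the dose product; for a homozygous "pair" it is an indicator of
carrying two copies, since the raw product (4) would be collinear with
the additive dose.  Significant pairs are exported as a lookup table of
carrier scores consumed by the risk-score builder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import fit_logistic
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Haplogenotype",
    "InteractionResult",
    "canonical_pair",
    "enumerate_haplogenotypes",
    "interaction_term",
    "fit_interaction",
    "significant_interactions",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered haplotype pair, for stable lookups."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Haplogenotype:
    pair: tuple[str, str]  # canonical
    n_carriers: int

    @property
    def homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]


@dataclass
class InteractionResult:
    pair: tuple[str, str]
    gamma: float            # interaction log-odds
    se: float
    p: float
    n_carriers: int
    carrier_score: float    # full fitted log-odds of the haplogenotype (main effects + gamma)
    ok: bool = True
    message: str = ""
    p_adj: float = np.nan
    significant: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.gamma))


def interaction_term(dose_a: np.ndarray, dose_b: np.ndarray, homozygous: bool = False) -> np.ndarray:
    """Multiplicative interaction term from genotype doses.

    Heterozygous pair: ``dose_a * dose_b``.  Homozygous pair:
    ``1(dose == 2)``.
    """
    dose_a = np.asarray(dose_a, dtype=float)
    if homozygous:
        return (dose_a == 2).astype(float)
    return dose_a * np.asarray(dose_b, dtype=float)


def _carriers(hap_doses: pd.DataFrame, pair: tuple[str, str]) -> np.ndarray:
    a, b = pair
    if a == b:
        return interaction_term(hap_doses[a].to_numpy(), None, homozygous=True) > 0
    return interaction_term(hap_doses[a].to_numpy(), hap_doses[b].to_numpy()) >= 1


def enumerate_haplogenotypes(
    hap_doses: pd.DataFrame, min_carriers: int = 10
) -> list[Haplogenotype]:
    """All unordered haplotype pairs (homozygous included) carried by at
    least ``min_carriers`` individuals."""
    labels = list(hap_doses.columns)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i:]:
            pair = canonical_pair(a, b)
            n = int(_carriers(hap_doses, pair).sum())
            if n >= min_carriers:
                out.append(Haplogenotype(pair, n))
    return out


def fit_interaction(
    y: np.ndarray,
    hap_doses: pd.DataFrame,
    pair: tuple[str, str],
    covariates: pd.DataFrame | None = None,
    reference: str | None = None,
) -> InteractionResult:
    """Wald test of one haplogenotype's interaction coefficient.

    The model holds main-effect dose columns for every haplotype except
    the reference (default: the haplotype with the highest control-group
    dose, i.e. the most common control haplotype), screened covariates,
    and the pair's interaction term.  ``carrier_score`` is the fitted
    genetic log-odds of an individual carrying exactly that pair
    (main-effect contributions plus gamma), the quantity used as the
    lookup score in the risk model.
    """
    pair = canonical_pair(*pair)
    y = np.asarray(y)
    labels = list(hap_doses.columns)
    for h in pair:
        if h not in labels:
            raise ValueError(f"haplotype {h!r} not in dose matrix")
    if reference is None:
        ctrl = hap_doses.loc[np.asarray(y) == 0] if (np.asarray(y) == 0).any() else hap_doses
        reference = ctrl.mean().idxmax()
    homo = pair[0] == pair[1]
    term = interaction_term(
        hap_doses[pair[0]].to_numpy(),
        None if homo else hap_doses[pair[1]].to_numpy(),
        homozygous=homo,
    )
    n_car = int(_carriers(hap_doses, pair).sum())
    X = pd.DataFrame(index=hap_doses.index)
    for h in labels:
        # the reference and never-carried haplotypes are unidentifiable
        if h != reference and hap_doses[h].nunique() > 1:
            X[h] = hap_doses[h].to_numpy()
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    X["interaction"] = term
    try:
        fit = fit_logistic(y, X)
    except ValueError as e:
        return InteractionResult(pair, np.nan, np.nan, np.nan, n_car, np.nan, ok=False, message=str(e))
    if not fit.ok:
        return InteractionResult(pair, np.nan, np.nan, np.nan, n_car, np.nan, ok=False, message=fit.message)
    row = fit.table.loc["interaction"]
    gamma = float(row["beta"])
    main = 0.0
    for h in pair:
        if h != reference and h in fit.table.index:
            main += float(fit.table.loc[h, "beta"])  # dose 1 per copy; homozygous pair adds twice
    carrier_score = main + gamma
    return InteractionResult(pair, gamma, float(row["se"]), float(row["p"]), n_car, carrier_score)


def significant_interactions(
    results: list[InteractionResult],
    alpha: float = 0.05,
    correction: str = "bonferroni",
    score: str = "carrier",
) -> dict[tuple[str, str], float]:
    """Filter interaction fits by corrected p-value and emit the
    haplogenotype -> score lookup table.

    ``correction``: 'bonferroni' (default), 'fdr_bh' or 'none', applied
    over the successfully tested pairs.  ``score``: 'carrier' exports the
    full haplogenotype log-odds, 'gamma' the bare interaction
    coefficient.  Flagged (failed) fits never enter the table.
    """
    if score not in ("carrier", "gamma"):
        raise ValueError("score must be 'carrier' or 'gamma'")
    tested = [r for r in results if r.ok and np.isfinite(r.p)]
    if not tested:
        return {}
    pvals = np.array([r.p for r in tested])
    if correction == "none":
        rej, p_adj = pvals < alpha, pvals
    else:
        rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=correction)
    table: dict[tuple[str, str], float] = {}
    for r, keep, pa in zip(tested, rej, p_adj):
        r.p_adj = float(pa)
        r.significant = bool(keep)
        if keep:
            table[r.pair] = r.carrier_score if score == "carrier" else r.gamma
    return table
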