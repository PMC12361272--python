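"""DQA1-DQB1 haplotype inference, frequencies, LD and tag-SNP selection.

An individual's HLA typing gives two DQA1 and two DQB1 alleles without
phase.  Only two phasings are consistent with a two-locus unphased
genotype; the most likely one is chosen by maximising the product of
population haplotype frequencies (the two-locus special case of EM-style
haplotype reconstruction).  Haplotypes seen in more than 0.5% of case
and control chromosomes are retained, and for each a tag SNP is chosen
from candidate variants by phased linkage disequilibrium (r^2, with |D'|
and genomic position as tie-breaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import split_haplotype_label

__all__ = [
    "DQHaplotype",
    "TagAssignment",
    "make_label",
    "estimate_pool_frequencies",
    "infer_haplogenotypes",
    "haplotype_frequencies",
    "ld_stats",
    "ld_r2_dosage",
    "select_tags",
    "haplotype_dosages",
]


def make_label(dqa1: str, dqb1: str) -> str:
    return f"DQA1*{dqa1}-DQB1*{dqb1}"


@dataclass(frozen=True)
class DQHaplotype:
    label: str
    freq_cases: float
    freq_controls: float
    kept: bool

    def __post_init__(self) -> None:
        split_haplotype_label(self.label)


@dataclass(frozen=True)
class TagAssignment:
    haplotype: str
    snp: str | None     # None when no candidate clears the r^2 threshold
    r2: float | None
    dprime: float | None

    @property
    def tagged(self) -> bool:
        return self.snp is not None


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def estimate_pool_frequencies(typing: pd.DataFrame, n_iter: int = 100, tol: float = 1e-10) -> dict[str, float]:
    """Two-locus EM estimate of DQA1-DQB1 haplotype frequencies from
    unphased typing.

    Each individual is consistent with at most two phasings; the E-step
    weights them by the product of current haplotype frequencies and the
    M-step re-estimates frequencies from expected chromosome counts.
    Useful when no external reference frequency table is supplied.
    """
    phasings_per_ind: list[list[tuple[str, str]]] = []
    cand: set[str] = set()
    for rec in typing.itertuples(index=False):
        p1 = _canon(make_label(rec.dqa1_1, rec.dqb1_1), make_label(rec.dqa1_2, rec.dqb1_2))
        p2 = _canon(make_label(rec.dqa1_1, rec.dqb1_2), make_label(rec.dqa1_2, rec.dqb1_1))
        ph = [p1] if p1 == p2 else [p1, p2]
        phasings_per_ind.append(ph)
        for p in ph:
            cand.update(p)
    if not cand:
        return {}
    freqs = {h: 1.0 / len(cand) for h in sorted(cand)}
    n_chrom = 2 * len(phasings_per_ind)
    for _ in range(n_iter):
        counts = dict.fromkeys(freqs, 0.0)
        for ph in phasings_per_ind:
            ws = np.array([freqs[a] * freqs[b] for a, b in ph])
            tot = ws.sum()
            ws = ws / tot if tot > 0 else np.full(len(ph), 1.0 / len(ph))
            for w, (a, b) in zip(ws, ph):
                counts[a] += w
                counts[b] += w
        new = {h: c / n_chrom for h, c in counts.items()}
        delta = max(abs(new[h] - freqs[h]) for h in freqs)
        freqs = new
        if delta < tol:
            break
    return freqs


def infer_haplogenotypes(
    typing: pd.DataFrame, pool_freqs: dict[str, float]
) -> pd.DataFrame:
    """Resolve each individual's two DQA1-DQB1 haplotypes from unphased
    typing.

    ``typing`` columns: ``iid, dqa1_1, dqa1_2, dqb1_1, dqb1_2`` (four-digit
    allele strings, e.g. ``03:03``).  Of the two phase-consistent
    assignments, the one maximising the product of pool frequencies is
    returned (ties broken lexicographically and flagged ``ambiguous``);
    individuals whose every phasing involves a zero-frequency haplotype
    are flagged unresolved.
    """
    required = {"iid", "dqa1_1", "dqa1_2", "dqb1_1", "dqb1_2"}
    if not required <= set(typing.columns):
        raise ValueError(f"typing table must have columns {sorted(required)}")
    rows = []
    for rec in typing.itertuples(index=False):
        a1, a2, b1, b2 = rec.dqa1_1, rec.dqa1_2, rec.dqb1_1, rec.dqb1_2
        phasings = [
            _canon(make_label(a1, b1), make_label(a2, b2)),
            _canon(make_label(a1, b2), make_label(a2, b1)),
        ]
        scored = []
        for pair in phasings:
            f1 = pool_freqs.get(pair[0], 0.0)
            f2 = pool_freqs.get(pair[1], 0.0)
            scored.append((f1 * f2, pair))
        scored.sort(key=lambda t: (-t[0], t[1]))
        best_score, best = scored[0]
        distinct = phasings[0] != phasings[1]
        ambiguous = distinct and abs(scored[0][0] - scored[1][0]) <= 1e-300
        rows.append(
            {
                "iid": rec.iid,
                "hap1": best[0] if best_score > 0 else None,
                "hap2": best[1] if best_score > 0 else None,
                "resolved": best_score > 0,
                "ambiguous": bool(ambiguous and best_score > 0),
                "likelihood": best_score,
            }
        )
    return pd.DataFrame(rows)


def haplotype_frequencies(
    pairs: list[tuple[str, str]],
    phenotype: np.ndarray,
    min_freq: float = 0.005,
) -> list[DQHaplotype]:
    """Chromosome-level haplotype frequencies per group.

    A haplotype is kept iff its frequency exceeds ``min_freq`` in case
    chromosomes AND in control chromosomes.
    """
    phenotype = np.asarray(phenotype)
    if len(pairs) != phenotype.size:
        raise ValueError("pairs and phenotype lengths differ")
    counts: dict[str, np.ndarray] = {}
    group_chroms = np.array([2 * (phenotype == 1).sum(), 2 * (phenotype == 0).sum()], dtype=float)
    for pair, y in zip(pairs, phenotype):
        for h in pair:
            c = counts.setdefault(h, np.zeros(2))
            c[0 if y == 1 else 1] += 1
    out = []
    for label in sorted(counts):
        fc = counts[label][0] / group_chroms[0] if group_chroms[0] else 0.0
        fk = counts[label][1] / group_chroms[1] if group_chroms[1] else 0.0
        out.append(DQHaplotype(label, fc, fk, kept=(fc > min_freq and fk > min_freq)))
    return out


def ld_stats(hap_indicator, snp_allele) -> tuple[float, float]:
    """Phased r^2 and Lewontin D' from two binary chromosome vectors.

    ``D = p11 - pA*pB``; ``r^2 = D^2 / (pA(1-pA) pB(1-pB))``;
    ``D' = D / Dmax`` with ``Dmax = min(pA(1-pB), (1-pA)pB)`` for D > 0
    and ``min(pA*pB, (1-pA)(1-pB))`` for D < 0; D' = 0 when D = 0.
    """
    a = np.asarray(hap_indicator).ravel().astype(float)
    b = np.asarray(snp_allele).ravel().astype(float)
    if a.size != b.size or a.size == 0:
        raise ValueError("chromosome vectors must be non-empty and equal length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic input")
    p11 = (a * b).mean()
    d = p11 - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return float(r2), 0.0
    return float(r2), float(d / dmax)


def ld_r2_dosage(hap_dose, snp_dose) -> float:
    """Squared Pearson correlation of expected counts — the unphased
    fallback for tag r^2 when phased chromosomes are unavailable.  D'
    is undefined in this mode."""
    a = np.asarray(hap_dose, dtype=float)
    b = np.asarray(snp_dose, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate dosage vectors")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def select_tags(
    kept_haplotypes: list[str],
    candidates: dict[str, tuple[np.ndarray, int]],
    phased_haplotypes: np.ndarray,
    min_r2: float = 0.7,
) -> list[TagAssignment]:
    """Pick, per haplotype, the candidate SNP with maximal phased r^2.

    ``candidates`` maps SNP id to (phased 0/1 allele array over the same
    chromosomes, genomic position).  Ties are broken by larger |D'|, then
    smaller position.  A haplotype whose best candidate falls below
    ``min_r2`` is reported untagged rather than silently dropped.
    """
    out = []
    for label in kept_haplotypes:
        ind = (np.asarray(phased_haplotypes) == label).astype(int)
        best = None
        for snp_id in sorted(candidates):
            alleles, pos = candidates[snp_id]
            try:
                r2, dp = ld_stats(ind, alleles)
            except ValueError:
                continue
            key = (-r2, -abs(dp), pos, snp_id)
            if best is None or key < best[0]:
                best = (key, snp_id, r2, dp)
        if best is None or best[2] < min_r2:
            out.append(TagAssignment(label, None, None, None))
        else:
            out.append(TagAssignment(label, best[1], best[2], best[3]))
    return out


def haplotype_dosages(
    pairs: list[tuple[str, str] | None],
    labels: list[str] | None = None,
    index=None,
) -> pd.DataFrame:
    """Per-individual copy counts (0/1/2) of each haplotype.

    ``None`` entries (unresolved individuals) yield all-NaN rows; the
    count of such rows is stored in ``DataFrame.attrs['n_unresolved']``.
    """
    if labels is None:
        seen: set[str] = set()
        for p in pairs:
            if p is not None:
                seen.update(p)
        labels = sorted(seen)
    mat = np.zeros((len(pairs), len(labels)))
    pos = {lab: j for j, lab in enumerate(labels)}
    n_unresolved = 0
    for i, p in enumerate(pairs):
        if p is None or p[0] is None:
            mat[i, :] = np.nan
            n_unresolved += 1
            continue
        for h in p:
            if h in pos:
                mat[i, pos[h]] += 1
    df = pd.DataFrame(mat, columns=labels, index=index)
    df.attrs["n_unresolved"] = n_unresolved
    return df
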