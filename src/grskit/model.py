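"""Interaction-aware genetic risk score: assembly, scoring, persistence.

The score integrates three term groups: (1) HLA DQ haplotypes, entering
either through a haplogenotype lookup score — individuals whose pair of
haplotypes has a fitted interaction take that pair's score directly —
or, for everyone else, through additive per-copy ln(OR) weights; (2)
other HLA-region SNPs; and (3) non-HLA SNPs.  Additive contributions are
the familiar GRS sum: effect-allele dosage times beta, with
beta = ln(OR) from case-control logistic regression.  The total score is
the sum of the three components and the decomposition is reported per
individual.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssociationResult
from .evaluate import delong_paired, roc_auc
from .interactions import canonical_pair

__all__ = [
    "GRSModel",
    "ScoreResult",
    "build_model",
    "score_individual",
    "score_cohort",
    "incremental_auc",
    "save_model",
    "load_model",
    "load_weight_tsv",
]

SCHEMA_VERSION = 1
HLA_OTHER_P = 4.72e-4   # Bonferroni threshold for non-DQ HLA alleles
NON_HLA_P = 5e-8        # genome-wide significance for non-HLA SNPs


@dataclass
class GRSModel:
    dq_additive: dict[str, float] = field(default_factory=dict)        # haplotype label -> beta
    dq_interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    hla_other: dict[str, float] = field(default_factory=dict)          # snp id -> beta
    non_hla: dict[str, float] = field(default_factory=dict)            # snp id -> beta
    effect_allele: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dq_interactions = {canonical_pair(*k): float(v) for k, v in self.dq_interactions.items()}
        labels = set(self.dq_additive)
        for pair in self.dq_interactions:
            labels.update(pair)  # pairs may involve haplotypes with no additive term
        for d in (self.dq_additive, self.hla_other, self.non_hla):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite weight for {k!r}")

    @property
    def snp_terms(self) -> dict[str, float]:
        return {**self.hla_other, **self.non_hla}

    def __eq__(self, other) -> bool:
        if not isinstance(other, GRSModel):
            return NotImplemented
        return (
            self.dq_additive == other.dq_additive
            and self.dq_interactions == other.dq_interactions
            and self.hla_other == other.hla_other
            and self.non_hla == other.non_hla
            and self.effect_allele == other.effect_allele
        )


@dataclass
class ScoreResult:
    iid: str
    total: float
    dq: float
    hla_other: float
    non_hla: float
    dq_path: str            # 'interaction_lookup' | 'additive' | 'missing'
    n_missing_snps: int = 0


def _retain(results: list[AssociationResult], p_max: float) -> dict[str, tuple[float, float, str]]:
    out = {}
    for r in results:
        if not r.ok:
            continue
        if r.odds_ratio <= 0:
            raise ValueError(f"{r.id}: OR must be positive")
        if r.p < p_max:
            out[r.id] = (float(np.log(r.odds_ratio)), r.p, r.effect_allele)
    return out


def build_model(
    dq_assoc: dict[str, float] | list[AssociationResult],
    interaction_table: dict[tuple[str, str], float],
    hla_other_assoc: list[AssociationResult],
    non_hla_assoc: list[AssociationResult],
    hla_other_p: float = HLA_OTHER_P,
    non_hla_p: float = NON_HLA_P,
) -> GRSModel:
    """Assemble a GRS from association and interaction outputs.

    ``dq_assoc`` may be per-haplotype association results (beta taken as
    ln OR, no p filter: the DQ terms are the backbone of the score) or a
    ready haplotype -> beta map.  Other HLA terms are retained at the
    Bonferroni threshold for the tested HLA alleles and non-HLA SNPs at
    genome-wide significance; both thresholds are configurable.
    """
    if isinstance(dq_assoc, dict):
        dq = {k: float(v) for k, v in dq_assoc.items()}
        dq_meta = {}
    else:
        dq, dq_meta = {}, {}
        for r in dq_assoc:
            if not r.ok:
                continue
            if r.odds_ratio <= 0:
                raise ValueError(f"{r.id}: OR must be positive")
            dq[r.id] = float(np.log(r.odds_ratio))
            dq_meta[r.id] = r.p
    hla = _retain(hla_other_assoc, hla_other_p)
    non = _retain(non_hla_assoc, non_hla_p)
    model = GRSModel(
        dq_additive=dq,
        dq_interactions={canonical_pair(*k): float(v) for k, v in interaction_table.items()},
        hla_other={k: b for k, (b, _, _) in hla.items()},
        non_hla={k: b for k, (b, _, _) in non.items()},
        effect_allele={k: a for k, (_, _, a) in {**hla, **non}.items()},
        metadata={
            "p_values": {**dq_meta, **{k: p for k, (_, p, _) in {**hla, **non}.items()}},
            "thresholds": {"hla_other_p": hla_other_p, "non_hla_p": non_hla_p},
        },
    )
    return model


def score_individual(
    model: GRSModel,
    hap_pair: tuple[str, str] | None,
    dosages: dict[str, float],
) -> ScoreResult:
    """Score one individual; components always sum to the total.

    DQ component: the interaction lookup score when the individual's
    canonical haplogenotype appears in the model's interaction table,
    otherwise the sum of the two haplotypes' additive betas (unknown
    haplotypes contribute 0).  SNP components: sum of beta times dosage;
    missing model SNPs score as dose 0 and are counted.
    """
    iid = str(dosages.get("iid", ""))
    if hap_pair is not None and hap_pair[0] is not None:
        pair = canonical_pair(*hap_pair)
        if pair in model.dq_interactions:
            dq, path = model.dq_interactions[pair], "interaction_lookup"
        else:
            dq = sum(model.dq_additive.get(h, 0.0) for h in pair)
            path = "additive"
    else:
        dq, path = 0.0, "missing"
    n_missing = 0
    comp = {}
    for name, terms in (("hla_other", model.hla_other), ("non_hla", model.non_hla)):
        s = 0.0
        for snp, beta in terms.items():
            d = dosages.get(snp)
            if d is None or (isinstance(d, float) and np.isnan(d)):
                n_missing += 1
                continue
            s += beta * float(d)
        comp[name] = s
    total = dq + comp["hla_other"] + comp["non_hla"]
    return ScoreResult(iid, total, dq, comp["hla_other"], comp["non_hla"], path, n_missing)


def score_cohort(
    model: GRSModel,
    hap_pairs: list[tuple[str, str] | None],
    geno,
    individuals: list[str] | None = None,
) -> pd.DataFrame:
    """Score every individual; returns one row per individual with the
    component decomposition, plus distribution summaries in ``attrs``.

    ``geno`` is a :class:`~grskit.genotypes.GenotypeMatrix` (or a
    dosage DataFrame indexed by individual).
    """
    if hasattr(geno, "to_frame"):
        dose_df = geno.to_frame()
    else:
        dose_df = geno
    if individuals is None:
        individuals = list(dose_df.index)
    if len(hap_pairs) != len(individuals):
        raise ValueError("hap_pairs and individuals lengths differ")
    model_snps = list(model.snp_terms)
    present = [s for s in model_snps if s in dose_df.columns]
    absent = set(model_snps) - set(present)
    if absent:
        warnings.warn(f"{len(absent)} model SNPs absent from genotypes; scored as dose 0")
    rows = []
    for iid, pair in zip(individuals, hap_pairs):
        d = {s: dose_df.at[iid, s] for s in present}
        d["iid"] = iid
        rows.append(score_individual(model, pair, d))
    df = pd.DataFrame(
        {
            "iid": [r.iid for r in rows],
            "total": [r.total for r in rows],
            "dq": [r.dq for r in rows],
            "hla_other": [r.hla_other for r in rows],
            "non_hla": [r.non_hla for r in rows],
            "dq_path": [r.dq_path for r in rows],
            "n_missing_snps": [r.n_missing_snps for r in rows],
        }
    )
    t = df["total"]
    df.attrs["summary"] = {
        "median": float(t.median()),
        "iqr": [float(t.quantile(0.25)), float(t.quantile(0.75))],
        "tertiles": [float(t.quantile(1 / 3)), float(t.quantile(2 / 3))],
    }
    return df


def incremental_auc(
    model: GRSModel,
    scores: pd.DataFrame,
    geno,
    y: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """AUC as SNPs outside the DQ region are added one at a time in
    ascending association p-value order (DQ component always the base).

    The returned frame has one row per prefix size with the AUC and the
    paired DeLong p-value against the previous prefix;
    ``attrs['plateau']`` is the first size where adding the next SNP no
    longer gives a significant AUC change (NaN if none).  AUC is not
    forced to be monotone; observed plateaus and dips are reported as-is.
    """
    y = np.asarray(y)
    dose_df = geno.to_frame() if hasattr(geno, "to_frame") else geno
    pvals = model.metadata.get("p_values", {})
    snps = [s for s in model.snp_terms if s in dose_df.columns]
    snps.sort(key=lambda s: (pvals.get(s, 1.0), s))
    base = scores["dq"].to_numpy(dtype=float)
    running = base.copy()
    prev = running.copy()
    rows = [{"n_snps": 0, "snp": None, "auc": roc_auc(base, y).auc, "p_vs_prev": np.nan}]
    for k, s in enumerate(snps, start=1):
        dose = dose_df[s].reindex(scores["iid"]).to_numpy(dtype=float)
        dose = np.nan_to_num(dose, nan=0.0)
        running = running + model.snp_terms[s] * dose
        dl = delong_paired(running, prev, y)
        rows.append({"n_snps": k, "snp": s, "auc": dl.auc1, "p_vs_prev": dl.p})
        prev = running.copy()
    df = pd.DataFrame(rows)
    plateau = np.nan
    for k in range(len(df) - 1):
        if df.loc[k + 1, "p_vs_prev"] >= alpha:
            plateau = int(df.loc[k, "n_snps"])
            break
    df.attrs["plateau"] = plateau
    return df


def _pair_key(pair: tuple[str, str]) -> str:
    return f"{pair[0]}|{pair[1]}"


def save_model(model: GRSModel, path: str, weight_tsv: str | None = None) -> None:
    """Persist the model as schema-versioned JSON (and optionally a flat
    TSV weight sheet: ``term_type id effect_allele beta``)."""
    doc = {
        "version": SCHEMA_VERSION,
        "dq_additive": [{"id": k, "beta": v} for k, v in model.dq_additive.items()],
        "dq_interactions": [
            {"pair": list(k), "score": v} for k, v in model.dq_interactions.items()
        ],
        "hla_other": [
            {"id": k, "beta": v, "effect_allele": model.effect_allele.get(k)}
            for k, v in model.hla_other.items()
        ],
        "non_hla": [
            {"id": k, "beta": v, "effect_allele": model.effect_allele.get(k)}
            for k, v in model.non_hla.items()
        ],
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    if weight_tsv:
        rows = []
        for k, v in model.dq_additive.items():
            rows.append({"term_type": "dq_additive", "id": k, "effect_allele": ".", "beta": v})
        for k, v in model.dq_interactions.items():
            rows.append({"term_type": "dq_interaction", "id": _pair_key(k), "effect_allele": ".", "beta": v})
        for group, terms in (("hla_other", model.hla_other), ("non_hla", model.non_hla)):
            for k, v in terms.items():
                rows.append({"term_type": group, "id": k,
                             "effect_allele": model.effect_allele.get(k, "."), "beta": v})
        pd.DataFrame(rows).to_csv(weight_tsv, sep="\t", index=False)


def load_model(path: str) -> GRSModel:
    """Inverse of :func:`save_model` (JSON).  Unknown top-level fields are
    preserved under ``metadata['extra_fields']`` with a warning; a
    schema-version mismatch is an explicit error."""
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.pop("version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r} (expected {SCHEMA_VERSION})")
    known = {"dq_additive", "dq_interactions", "hla_other", "non_hla", "metadata"}
    extra = {k: doc[k] for k in set(doc) - known}
    metadata = doc.get("metadata", {})
    if extra:
        warnings.warn(f"unknown model fields preserved in metadata: {sorted(extra)}")
        metadata = {**metadata, "extra_fields": extra}
    eff = {}
    for group in ("hla_other", "non_hla"):
        for e in doc.get(group, []):
            if e.get("effect_allele"):
                eff[e["id"]] = e["effect_allele"]
    return GRSModel(
        dq_additive={e["id"]: float(e["beta"]) for e in doc.get("dq_additive", [])},
        dq_interactions={tuple(e["pair"]): float(e["score"]) for e in doc.get("dq_interactions", [])},
        hla_other={e["id"]: float(e["beta"]) for e in doc.get("hla_other", [])},
        non_hla={e["id"]: float(e["beta"]) for e in doc.get("non_hla", [])},
        effect_allele=eff,
        metadata=metadata,
    )


def load_weight_tsv(path: str) -> GRSModel:
    """Re-import a flat weight sheet written by :func:`save_model`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    model = GRSModel()
    for rec in df.itertuples(index=False):
        beta = float(rec.beta)
        if rec.term_type == "dq_additive":
            model.dq_additive[rec.id] = beta
        elif rec.term_type == "dq_interaction":
            a, b = rec.id.split("|")
            model.dq_interactions[canonical_pair(a, b)] = beta
        elif rec.term_type == "hla_other":
            model.hla_other[rec.id] = beta
        elif rec.term_type == "non_hla":
            model.non_hla[rec.id] = beta
        else:
            raise ValueError(f"unknown term_type {rec.term_type!r}")
        if getattr(rec, "effect_allele", ".") not in (".", None) and rec.term_type in ("hla_other", "non_hla"):
            model.effect_allele[rec.id] = rec.effect_allele
    return model
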