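"""Synthetic case-control cohort generation.

Emulates the structure of a two-stage type 1 diabetes case-control study:
a pool of HLA ``DQA1-DQB1`` haplotypes with per-copy log-odds effects,
non-additive haplogenotype (diplotype) interaction effects, tag SNPs held
in configurable linkage disequilibrium with the haplotypes, additive
non-HLA risk SNPs, and a logistic disease model with sex and
principal-component covariates.  Disease status is generated forward from
the logistic model and individuals are retained by rejection sampling
until the exact case and control quotas are filled, mirroring the
fixed-size cohorts of a case-control design.

The module also records ground truth (phased haplotypes, generating
parameters, realized frequencies) so that downstream estimators can be
tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .genotypes import GenotypeMatrix, Variant, read_vcf, write_vcf

__all__ = [
    "HaplotypeSpec",
    "SnpSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "emit_tag_snps",
    "solve_tag_epsilon",
    "tag_r2",
    "write_cohort",
    "read_cohort",
    "default_haplotype_pool",
    "default_interaction_effects",
    "T1D_SNP_EFFECTS",
    "split_haplotype_label",
    "tag_snp_id",
]


# Per-allele effects (MAF, log-odds) of replicated genome-wide-significant
# type 1 diabetes loci in Chinese case-control cohorts; used as realistic
# defaults for the additive part of the generator.
T1D_SNP_EFFECTS: list[tuple[str, float, float]] = [
    ("rs231770", 0.322, 0.273),    # CTLA4
    ("rs9274655", 0.411, 1.323),   # MHC
    ("rs10232170", 0.280, -0.391), # BMPER
    ("rs11256442", 0.493, -0.245), # IL2RA
    ("rs689", 0.035, 1.031),       # INS-IGF2
    ("rs773125", 0.264, 0.301),    # SUOX-RPS26-SH2B3-ATXN2
]


@dataclass(frozen=True)
class HaplotypeSpec:
    label: str          # "DQA1*xx:xx-DQB1*yy:yy"
    freq: float         # population (chromosome) frequency
    beta: float         # per-copy log-odds


@dataclass(frozen=True)
class SnpSpec:
    id: str
    maf: float          # effect-allele frequency in (0, 0.5]
    beta: float         # per-allele log-odds


_LABEL_RE = re.compile(r"^DQA1\*(\d{2}:\d{2,3}[A-Z]?)-DQB1\*(\d{2}:\d{2,3}[A-Z]?)$")


def split_haplotype_label(label: str) -> tuple[str, str]:
    """Split ``DQA1*aa:aa-DQB1*bb:bb`` into its two four-digit alleles."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"not a DQA1-DQB1 haplotype label: {label!r}")
    return m.group(1), m.group(2)


def tag_snp_id(label: str) -> str:
    """Deterministic tag-SNP identifier for a haplotype label."""
    return "tag_" + label.replace("DQA1*", "A").replace("-DQB1*", "_B").replace(":", "")


def default_haplotype_pool() -> list[HaplotypeSpec]:
    """A realistic East Asian DQA1-DQB1 pool with case-enriched risk
    haplotypes (DR3/DR9/DR4-like), protective haplotypes and neutral
    fillers.  Frequencies sum to 1."""
    return [
        HaplotypeSpec("DQA1*03:02-DQB1*03:03", 0.18, 1.1),   # DR9-like risk
        HaplotypeSpec("DQA1*05:01-DQB1*02:01", 0.10, 1.3),   # DR3-like risk
        HaplotypeSpec("DQA1*03:03-DQB1*04:01", 0.10, 0.9),   # DR4-like risk
        HaplotypeSpec("DQA1*03:01-DQB1*03:02", 0.06, 0.0),   # DQ8, neutral here
        HaplotypeSpec("DQA1*01:02-DQB1*06:02", 0.04, -1.8),  # strongly protective
        HaplotypeSpec("DQA1*01:02-DQB1*05:02", 0.10, -0.9),  # protective
        HaplotypeSpec("DQA1*01:01-DQB1*05:01", 0.18, 0.0),
        HaplotypeSpec("DQA1*06:01-DQB1*03:01", 0.24, -0.3),
    ]


def default_interaction_effects() -> dict[tuple[str, str], float]:
    """Non-additive haplogenotype effects layered on the default pool:
    the classic trans-complementing DR3/DR9 heterozygote excess risk and
    a sub-additive DR9 homozygote."""
    return {
        ("DQA1*03:02-DQB1*03:03", "DQA1*05:01-DQB1*02:01"): 0.8,
        ("DQA1*03:02-DQB1*03:03", "DQA1*03:02-DQB1*03:03"): -0.4,
    }


def _canon(pair) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class SimulationConfig:
    """Generating parameters of the logistic disease model.

    ``eta = intercept + sum beta_h * dose_h + gamma(pair)
           + sum beta_snp * dose_snp + sex_beta * sex + sum pc_beta * PC``
    and ``P(case) = expit(eta)``.
    """

    n_cases: int
    n_controls: int
    haplotype_pool: list[HaplotypeSpec] = field(default_factory=list)
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    tag_specs: dict[str, float] = field(default_factory=dict)  # label -> target r^2
    nonhla_snps: list[SnpSpec] = field(default_factory=list)
    covariate_effects: tuple[float, list[float]] = (0.0, [])
    intercept: float = -1.0
    missing_rate: float = 0.0
    seed: int = 0
    max_draw_factor: int = 2000  # abort after this many draws per requested individual

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.haplotype_pool:
            tot = sum(h.freq for h in self.haplotype_pool)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"haplotype frequencies sum to {tot}, not 1")
            labels = {h.label for h in self.haplotype_pool}
            for h in self.haplotype_pool:
                split_haplotype_label(h.label)  # raises on malformed labels
            for pair in self.interaction_effects:
                if not set(pair) <= labels:
                    raise ValueError(f"interaction pair {pair} references unknown haplotype")
            for lab, r2 in self.tag_specs.items():
                if lab not in labels:
                    raise ValueError(f"tag spec references unknown haplotype {lab!r}")
                if not (0.0 < r2 <= 1.0):
                    raise ValueError(f"target r^2 must be in (0, 1], got {r2}")
        elif self.interaction_effects or self.tag_specs:
            raise ValueError("interaction/tag specs require a haplotype pool")
        for s in self.nonhla_snps:
            if not (0.0 < s.maf <= 0.5):
                raise ValueError(f"MAF must be in (0, 0.5], got {s.maf} for {s.id}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interaction_effects"] = [
            {"pair": list(p), "gamma": g} for p, g in self.interaction_effects.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["haplotype_pool"] = [HaplotypeSpec(**h) for h in d.get("haplotype_pool", [])]
        d["nonhla_snps"] = [SnpSpec(**s) for s in d.get("nonhla_snps", [])]
        d["interaction_effects"] = {
            _canon(tuple(e["pair"])): e["gamma"] for e in d.get("interaction_effects", [])
        }
        sx, pcs = d.get("covariate_effects", (0.0, []))
        d["covariate_effects"] = (float(sx), list(pcs))
        return cls(**d)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phased_haplotypes: np.ndarray       # (n, 2) array of labels ('' if no pool)
    hla_typing: pd.DataFrame            # iid, dqa1_1, dqa1_2, dqb1_1, dqb1_2
    phenotype: np.ndarray               # 1 = case, 0 = control
    covariates: pd.DataFrame            # iid-indexed: sex, PC1..PCk
    truth: dict
    phased_tag_alleles: dict[str, np.ndarray] = field(default_factory=dict)  # snp id -> (n, 2) 0/1

    @property
    def individuals(self) -> list[str]:
        return self.genotypes.individuals

    def haplotype_pairs(self) -> list[tuple[str, str]]:
        return [_canon(tuple(row)) for row in self.phased_haplotypes]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw individuals from the generating model until the case and
    control quotas are both filled (rejection sampling); deterministic
    given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    labels = [h.label for h in config.haplotype_pool]
    freqs = np.array([h.freq for h in config.haplotype_pool])
    hap_beta = np.array([h.beta for h in config.haplotype_pool])
    inter = {_canon(p): g for p, g in config.interaction_effects.items()}
    mafs = np.array([s.maf for s in config.nonhla_snps])
    snp_beta = np.array([s.beta for s in config.nonhla_snps])
    sex_beta, pc_betas = config.covariate_effects
    pc_betas = np.asarray(pc_betas, dtype=float)
    n_pc = len(pc_betas)

    n_total = config.n_cases + config.n_controls
    max_draws = config.max_draw_factor * n_total
    batch = max(1024, 2 * n_total)

    need = {1: config.n_cases, 0: config.n_controls}
    kept_hap: list[np.ndarray] = []
    kept_dose: list[np.ndarray] = []
    kept_sex: list[np.ndarray] = []
    kept_pc: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    drawn = 0
    cases_drawn = 0

    while need[1] > 0 or need[0] > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"rejection sampling drew {drawn} individuals without filling the "
                f"quotas (still need {need[1]} cases, {need[0]} controls); the "
                "intercept/effects make one group essentially unreachable"
            )
        B = batch
        eta = np.full(B, config.intercept)
        if labels:
            hap_idx = rng.choice(len(labels), size=(B, 2), p=freqs)
            eta += hap_beta[hap_idx[:, 0]] + hap_beta[hap_idx[:, 1]]
            if inter:
                for (ha, hb), g in inter.items():
                    ia, ib = labels.index(ha), labels.index(hb)
                    lo = np.minimum(hap_idx[:, 0], hap_idx[:, 1])
                    hi = np.maximum(hap_idx[:, 0], hap_idx[:, 1])
                    eta += g * ((lo == min(ia, ib)) & (hi == max(ia, ib)))
        else:
            hap_idx = np.full((B, 2), -1)
        if len(mafs):
            dose = rng.binomial(2, mafs, size=(B, len(mafs))).astype(float)
            eta += dose @ snp_beta
        else:
            dose = np.empty((B, 0))
        sex = rng.integers(0, 2, size=B)
        pcs = rng.standard_normal((B, n_pc)) if n_pc else np.empty((B, 0))
        eta += sex_beta * sex
        if n_pc:
            eta += pcs @ pc_betas
        y = (rng.random(B) < expit(eta)).astype(int)
        drawn += B
        cases_drawn += int(y.sum())

        # keep at most the still-needed number from each group, in draw order
        sel = np.zeros(B, dtype=bool)
        for g in (1, 0):
            idx = np.flatnonzero(y == g)[: need[g]]
            sel[idx] = True
            need[g] -= len(idx)
        kept_hap.append(hap_idx[sel])
        kept_dose.append(dose[sel])
        kept_sex.append(sex[sel])
        kept_pc.append(pcs[sel])
        kept_y.append(y[sel])

    hap_idx = np.concatenate(kept_hap)
    dose = np.concatenate(kept_dose)
    sex = np.concatenate(kept_sex)
    pcs = np.concatenate(kept_pc)
    y = np.concatenate(kept_y)
    # cases first, controls after, stable within group
    order = np.argsort(-y, kind="stable")
    hap_idx, dose, sex, pcs, y = hap_idx[order], dose[order], sex[order], pcs[order], y[order]

    if config.missing_rate > 0 and dose.size:
        dose[rng.random(dose.shape) < config.missing_rate] = np.nan

    iids = [f"ind{i:05d}" for i in range(n_total)]
    variants = [
        Variant(s.id, chrom="1", pos=1000 * (i + 1), a1="A", a2="G")
        for i, s in enumerate(config.nonhla_snps)
    ]
    geno = GenotypeMatrix(variants, iids, dose)

    if labels:
        lab_arr = np.array(labels, dtype=object)
        phased = lab_arr[hap_idx]
        alleles = {lab: split_haplotype_label(lab) for lab in labels}
        dqa = np.array([[alleles[h][0] for h in row] for row in phased], dtype=object)
        dqb = np.array([[alleles[h][1] for h in row] for row in phased], dtype=object)
        dqa.sort(axis=1)
        dqb.sort(axis=1)
        typing = pd.DataFrame(
            {
                "iid": iids,
                "dqa1_1": dqa[:, 0],
                "dqa1_2": dqa[:, 1],
                "dqb1_1": dqb[:, 0],
                "dqb1_2": dqb[:, 1],
            }
        )
    else:
        phased = np.full((n_total, 2), "", dtype=object)
        typing = pd.DataFrame(columns=["iid", "dqa1_1", "dqa1_2", "dqb1_1", "dqb1_2"])

    cov = pd.DataFrame({"sex": sex}, index=pd.Index(iids, name="iid"))
    for k in range(n_pc):
        cov[f"PC{k + 1}"] = pcs[:, k]

    truth = {
        "config": config.to_dict(),
        "realized": {
            "haplotype_freq": {
                lab: float(np.mean(hap_idx == k)) for k, lab in enumerate(labels)
            },
            "snp_allele_freq": {
                s.id: float(np.nanmean(dose[:, i]) / 2.0)
                for i, s in enumerate(config.nonhla_snps)
            },
            "draws_used": drawn,
            "raw_case_fraction": cases_drawn / drawn,
        },
        "phased_haplotypes": phased.tolist(),
    }

    cohort = SyntheticCohort(geno, phased, typing, y, cov, truth)
    if config.tag_specs:
        cohort.genotypes = emit_tag_snps(cohort, config.tag_specs, rng=rng)
    return cohort


def tag_r2(hap_freq: float, eps: float) -> float:
    """Analytic phased r^2 between a haplotype indicator (frequency p) and
    a tag allele obtained by flipping the indicator with per-chromosome
    error rate eps.  D = p(1-p)(1-2 eps)."""
    p = hap_freq
    pb = p * (1 - eps) + (1 - p) * eps
    if pb <= 0 or pb >= 1:
        return 0.0
    d = p * (1 - p) * (1 - 2 * eps)
    return d * d / (p * (1 - p) * pb * (1 - pb))


def solve_tag_epsilon(hap_freq: float, target_r2: float) -> float:
    """Flip rate eps in [0, 0.5) achieving the target phased r^2.

    r^2 is strictly decreasing in eps on [0, 0.5) (from 1 down to 0), so
    the root is unique; found by Brent bracketing.
    """
    if not (0.0 < target_r2 <= 1.0):
        raise ValueError(f"target r^2 must be in (0, 1], got {target_r2}")
    if target_r2 == 1.0:
        return 0.0
    return float(brentq(lambda e: tag_r2(hap_freq, e) - target_r2, 0.0, 0.5 - 1e-12))


def emit_tag_snps(
    cohort: SyntheticCohort,
    tag_specs: dict[str, float],
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Append one tag SNP per haplotype at the requested phased r^2.

    Each chromosome's tag allele is the haplotype indicator flipped with
    the error rate solved from the analytic r^2 relation; the individual's
    tag dosage is the sum over its two chromosomes.  Phased tag alleles
    are retained on the cohort for LD ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(int(cohort.truth["config"]["seed"]) + 1)
    phased = cohort.phased_haplotypes
    n = phased.shape[0]
    new_vars: list[Variant] = []
    cols: list[np.ndarray] = []
    for k, (label, r2) in enumerate(tag_specs.items()):
        freq = cohort.truth["realized"]["haplotype_freq"].get(label)
        pool = {h["label"]: h["freq"] for h in cohort.truth["config"]["haplotype_pool"]}
        if label not in pool:
            raise ValueError(f"tag spec references unknown haplotype {label!r}")
        eps = solve_tag_epsilon(pool[label], r2)
        ind = (phased == label).astype(int)
        if eps > 0:
            flip = rng.random(ind.shape) < eps
            ind = ind ^ flip
        sid = tag_snp_id(label)
        cohort.phased_tag_alleles[sid] = ind
        new_vars.append(Variant(sid, chrom="6", pos=32_600_000 + 1000 * (k + 1), a1="T", a2="C"))
        cols.append(ind.sum(axis=1).astype(float))
    tags = GenotypeMatrix(new_vars, list(cohort.individuals), np.column_stack(cols))
    return cohort.genotypes.append(tags)


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> dict[str, str]:
    """Write VCF + phenotype/covariate TSV + HLA typing TSV + truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "pheno": os.path.join(out_dir, "phenotype.tsv"),
        "hla": os.path.join(out_dir, "hla_typing.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    pheno = cohort.covariates.copy()
    pheno.insert(0, "status", cohort.phenotype)
    pheno.reset_index().to_csv(paths["pheno"], sep="\t", index=False)
    cohort.hla_typing.to_csv(paths["hla"], sep="\t", index=False)
    truth = dict(cohort.truth)
    truth["phased_tag_alleles"] = {k: v.tolist() for k, v in cohort.phased_tag_alleles.items()}
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def read_cohort(out_dir: str) -> SyntheticCohort:
    """Round-trip reader for :func:`write_cohort` output."""
    geno = read_vcf(os.path.join(out_dir, "genotypes.vcf"))
    pheno = pd.read_csv(os.path.join(out_dir, "phenotype.tsv"), sep="\t", dtype={"iid": str})
    pheno = pheno.set_index("iid").loc[geno.individuals]
    typing = pd.read_csv(os.path.join(out_dir, "hla_typing.tsv"), sep="\t", dtype=str)
    with open(os.path.join(out_dir, "truth.json")) as fh:
        truth = json.load(fh)
    phased = np.array(truth.pop("phased_haplotypes"), dtype=object)
    tag_alleles = {
        k: np.array(v, dtype=int) for k, v in truth.pop("phased_tag_alleles", {}).items()
    }
    y = pheno["status"].to_numpy(dtype=int)
    cov = pheno.drop(columns=["status"])
    return SyntheticCohort(geno, phased, typing, y, cov, truth, tag_alleles)
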