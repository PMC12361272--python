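"""Dosage genotype container and VCF / TSV input-output.

Genotypes are stored as expected effect-allele counts ("dosages") in
``[0, 2]``, one row per individual and one column per variant, with
``NaN`` marking missing calls.  Dosages rather than hard calls are the
substrate of every downstream step (QC, association, scoring) because
imputed data arrive as fractional expected counts.

On disk the matrix is a VCF 4.2 file with a ``DS`` FORMAT field (one
biallelic record per variant, A1 stored as ALT so that the dosage counts
the effect allele); parsing is delegated to :mod:`pysam`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = ["Variant", "GenotypeMatrix", "read_vcf", "write_vcf"]


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; ``a1`` is the counted (effect) allele."""

    id: str
    chrom: str = "1"
    pos: int = 0
    a1: str = "A"
    a2: str = "G"


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with missingness as NaN."""

    variants: list[Variant]
    individuals: list[str]
    dosages: np.ndarray  # float, shape (n_individuals, n_variants)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2] where non-missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]

    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency on non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, keep_ids) -> "GenotypeMatrix":
        keep = set(keep_ids)
        idx = [i for i, v in enumerate(self.variants) if v.id in keep]
        return GenotypeMatrix(
            [self.variants[i] for i in idx],
            list(self.individuals),
            self.dosages[:, idx].copy(),
        )

    def append(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if other.individuals != self.individuals:
            raise ValueError("individual lists differ")
        return GenotypeMatrix(
            self.variants + other.variants,
            list(self.individuals),
            np.hstack([self.dosages, other.dosages]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.individuals, columns=self.variant_ids)


def _format_ds(x: float) -> str:
    if np.isnan(x):
        return "."
    if x == int(x):
        return str(int(x))
    return format(x, "g")


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with a DS FORMAT field.

    A1 (the counted allele) is stored as ALT so the dosage is the ALT
    expected count, the convention of most imputation pipelines.
    """
    chroms = sorted({v.chrom for v in geno.variants}, key=str)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected effect (ALT) allele dosage">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.individuals)
    )
    order = sorted(range(geno.n_variants), key=lambda i: (str(geno.variants[i].chrom), geno.variants[i].pos))
    for i in order:
        v = geno.variants[i]
        ds = "\t".join(_format_ds(x) for x in geno.dosages[:, i])
        lines.append(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.a2}\t{v.a1}\t.\t.\t.\tDS\t{ds}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a DS-dosage VCF back into a :class:`GenotypeMatrix`."""
    vf = pysam.VariantFile(path)
    individuals = list(vf.header.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        alt = rec.alts[0] if rec.alts else "."
        variants.append(Variant(rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos, alt, rec.ref))
        col = np.full(len(individuals), np.nan)
        for j, s in enumerate(individuals):
            ds = rec.samples[s].get("DS")
            if ds is not None:
                col[j] = float(ds)
        rows.append(col)
    vf.close()
    dosages = np.column_stack(rows) if rows else np.empty((len(individuals), 0))
    return GenotypeMatrix(variants, individuals, dosages)
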