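"""Shared genomic data model.

All coordinates are 1-based inclusive (VCF/GFF3 convention). Half-open
arithmetic, where needed, is confined to interval-overlap helpers in
:mod:`slopescan.integrate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "GenotypeMatrix",
    "HaplotypeSet",
    "GeneAnnotation",
    "GeneticMap",
]


@dataclass
class VariantTable:
    """Biallelic variant records ordered by (chromosome, position).

    Positions are strictly increasing within each chromosome; exactly two
    alleles per record.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    vid: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.vid = np.asarray(self.vid, dtype=object)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_mask(self, c) -> np.ndarray:
        return np.asarray(self.chrom == c)

    def subset(self, idx) -> "VariantTable":
        return VariantTable(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx], self.vid[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "id": self.vid,
            }
        )


@dataclass
class GenotypeMatrix:
    """Per-sample alt-allele dosages, shape (n_samples, n_variants).

    Dosage is 0, 1 or 2; missing genotypes are NaN.
    """

    samples: list
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage row count does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.dosages[:, idx])

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes, shape (2 * n_samples, n_variants).

    Haplotypes 2*i and 2*i+1 belong to sample i, so haplotype dosage sums
    reproduce the genotype dosage at every site.
    """

    samples: list
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype count must be exactly 2 per sample")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def sample_of(self, hap_index: int) -> str:
        return self.samples[hap_index // 2]

    def to_dosages(self) -> GenotypeMatrix:
        d = self.haplotypes[0::2].astype(np.float64) + self.haplotypes[1::2]
        return GenotypeMatrix(self.samples, d)

    def subset_variants(self, idx) -> "HaplotypeSet":
        return HaplotypeSet(self.samples, self.haplotypes[:, idx])


@dataclass
class GeneAnnotation:
    """Gene features with 1-based inclusive spans and unique identifiers."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(t.columns):
            raise ValueError(f"gene table must have columns {sorted(required)}")
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene ID: {dup}")
        if (t["start"] > t["end"]).any():
            raise ValueError("gene with start > end")

    @property
    def n_genes(self) -> int:
        return len(self.table)


@dataclass
class GeneticMap:
    """Physical→genetic coordinate anchors per chromosome.

    ``cum_cM`` is non-decreasing in physical position; intervals whose local
    rate is missing contribute exactly zero genetic distance.
    """

    table: pd.DataFrame  # columns: chrom, pos, rate_cM_per_Mb (may be NaN), cum_cM

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "cum_cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table must have columns {sorted(required)}")
        for c, grp in self.table.groupby("chrom", sort=False):
            if np.any(np.diff(grp["cum_cM"].to_numpy()) < 0):
                raise ValueError(f"cumulative cM decreasing on chromosome {c}")

    def interpolate(self, chrom, positions: np.ndarray) -> np.ndarray:
        """Genetic positions (cM) at physical coordinates by linear interpolation.

        Beyond the outermost anchors the map is extended flat (rate zero).
        """
        grp = self.table[self.table["chrom"] == chrom]
        if grp.empty:
            raise ValueError(f"no map anchors for chromosome {chrom}")
        return np.interp(
            np.asarray(positions, dtype=float),
            grp["pos"].to_numpy(dtype=float),
            grp["cum_cM"].to_numpy(dtype=float),
        )
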