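"""Core data containers shared across the pipeline.

Conventions used throughout:

* Coordinates are 1-based inclusive (VCF convention). BED input is 0-based
  half-open and converted at the parsing boundary.
* SNP alleles are coded 0 (reference) / 1 (alternate).
* STR alleles are signed length offsets in bp from the locus reference
  length; 0 is the reference allele. Stepwise mutation and PCR stutter act
  in whole repeat units, i.e. in multiples of the motif period.
* Missing alleles are encoded with the ``MISSING`` sentinel in integer
  matrices; genotype-level missingness is tracked in boolean masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for a missing allele in integer allele matrices.
MISSING: int = np.iinfo(np.int32).min


@dataclass(frozen=True)
class StrLocus:
    """A short tandem repeat locus: a 1-6 bp motif repeated in tandem."""

    chrom: str
    start: int
    end: int
    motif: str
    reference_length: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if not self.motif or set(self.motif.upper()) - set("ACGT"):
            raise ValueError(f"motif must be a non-empty string over ACGT, got {self.motif!r}")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif period must be in 1..6, got {len(self.motif)}")

    @property
    def period(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class QuadFamily:
    """Two parents and two children; the unit of transmission phasing."""

    father: str
    mother: str
    child1: str
    child2: str

    def __post_init__(self) -> None:
        members = (self.father, self.mother, self.child1, self.child2)
        if len(set(members)) != 4:
            raise ValueError(f"quad members must be four distinct identifiers: {members}")

    @property
    def members(self) -> tuple[str, str, str, str]:
        return (self.father, self.mother, self.child1, self.child2)

    @property
    def children(self) -> tuple[str, str]:
        return (self.child1, self.child2)


@dataclass(frozen=True)
class DiploidStrGenotype:
    """Unordered pair of STR allele length offsets (bp); possibly missing."""

    allele_a: int
    allele_b: int
    missing: bool = False

    def alleles(self) -> tuple[int, int]:
        """Alleles in a canonical (sorted) order."""
        if self.missing:
            raise ValueError("missing genotype has no alleles")
        return tuple(sorted((self.allele_a, self.allele_b)))  # type: ignore[return-value]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiploidStrGenotype):
            return NotImplemented
        if self.missing or other.missing:
            return self.missing and other.missing
        return self.alleles() == other.alleles()

    def __hash__(self) -> int:
        if self.missing:
            return hash((None, None))
        return hash(self.alleles())

    @property
    def dosage(self) -> int:
        """Sum of the two allele length offsets."""
        if self.missing:
            raise ValueError("dosage undefined for a missing genotype")
        return self.allele_a + self.allele_b


class HaplotypePanel:
    """Phased haplotypes over a region's SNP sites plus one STR site.

    The allele matrix is sites x haplotypes.  When the panel is bound to
    samples, haplotype columns ``2*i`` and ``2*i + 1`` belong to
    ``samples[i]``.
    """

    def __init__(
        self,
        chrom: str,
        positions: np.ndarray,
        is_str: np.ndarray,
        alleles: np.ndarray,
        str_locus: StrLocus,
        samples: Sequence[str] | None = None,
    ) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        is_str = np.asarray(is_str, dtype=bool)
        alleles = np.asarray(alleles, dtype=np.int32)
        if alleles.shape[0] != positions.shape[0] or is_str.shape[0] != positions.shape[0]:
            raise ValueError("positions, is_str and allele matrix must agree on the number of sites")
        if int(is_str.sum()) != 1:
            raise ValueError("a panel region must contain exactly one STR site")
        if np.any(np.diff(positions) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if samples is not None and 2 * len(samples) != alleles.shape[1]:
            raise ValueError("need exactly two haplotypes per sample")
        self.chrom = chrom
        self.positions = positions
        self.is_str = is_str
        self.alleles = alleles
        self.str_locus = str_locus
        self.samples = list(samples) if samples is not None else None

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def str_index(self) -> int:
        return int(np.flatnonzero(self.is_str)[0])

    @property
    def snp_positions(self) -> np.ndarray:
        return self.positions[~self.is_str]

    @property
    def snp_alleles(self) -> np.ndarray:
        return self.alleles[~self.is_str]

    @property
    def str_alleles(self) -> np.ndarray:
        return self.alleles[self.str_index]

    def haplotype_columns(self, sample: str) -> tuple[int, int]:
        if self.samples is None:
            raise ValueError("panel is not bound to samples")
        i = self.samples.index(sample)
        return 2 * i, 2 * i + 1

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            self.chrom,
            self.positions.copy(),
            self.is_str.copy(),
            self.alleles.copy(),
            self.str_locus,
            list(self.samples) if self.samples is not None else None,
        )

    def subset_samples(self, samples: Sequence[str]) -> "HaplotypePanel":
        """Panel restricted to the given samples, in the given order."""
        cols = [c for s in samples for c in self.haplotype_columns(s)]
        return HaplotypePanel(
            self.chrom, self.positions, self.is_str, self.alleles[:, cols], self.str_locus, list(samples)
        )

    def drop_sample(self, sample: str) -> "HaplotypePanel":
        """Panel with one sample's two haplotype columns removed."""
        c0, c1 = self.haplotype_columns(sample)
        keep = [c for c in range(self.n_haplotypes) if c not in (c0, c1)]
        samples = [s for s in self.samples if s != sample]  # type: ignore[union-attr]
        return HaplotypePanel(
            self.chrom, self.positions, self.is_str, self.alleles[:, keep], self.str_locus, samples
        )


class GenotypeTable:
    """Unphased diploid genotypes over the same site layout as a panel.

    ``allele_a``/``allele_b`` carry the two alleles per site x sample; the
    pair is unordered.  ``missing`` marks genotype-level missingness.
    """

    def __init__(
        self,
        chrom: str,
        positions: np.ndarray,
        is_str: np.ndarray,
        allele_a: np.ndarray,
        allele_b: np.ndarray,
        missing: np.ndarray,
        str_locus: StrLocus,
        samples: Sequence[str],
    ) -> None:
        self.chrom = chrom
        self.positions = np.asarray(positions, dtype=np.int64)
        self.is_str = np.asarray(is_str, dtype=bool)
        self.allele_a = np.asarray(allele_a, dtype=np.int32)
        self.allele_b = np.asarray(allele_b, dtype=np.int32)
        self.missing = np.asarray(missing, dtype=bool)
        self.str_locus = str_locus
        self.samples = list(samples)
        n_sites, n_samples = self.allele_a.shape
        if self.allele_b.shape != (n_sites, n_samples) or self.missing.shape != (n_sites, n_samples):
            raise ValueError("allele and missing matrices must share one shape")
        if len(self.samples) != n_samples:
            raise ValueError("sample list must match matrix width")

    @property
    def n_sites(self) -> int:
        return self.allele_a.shape[0]

    @property
    def n_samples(self) -> int:
        return self.allele_a.shape[1]

    @property
    def str_index(self) -> int:
        return int(np.flatnonzero(self.is_str)[0])

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def str_genotype(self, sample: str) -> DiploidStrGenotype:
        i = self.str_index
        j = self.sample_index(sample)
        if self.missing[i, j]:
            return DiploidStrGenotype(0, 0, missing=True)
        return DiploidStrGenotype(int(self.allele_a[i, j]), int(self.allele_b[i, j]))

    def str_genotypes(self) -> list[DiploidStrGenotype]:
        return [self.str_genotype(s) for s in self.samples]

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            self.chrom,
            self.positions.copy(),
            self.is_str.copy(),
            self.allele_a.copy(),
            self.allele_b.copy(),
            self.missing.copy(),
            self.str_locus,
            list(self.samples),
        )


def str_allele_counts(genotypes: Iterable[DiploidStrGenotype]) -> dict[int, int]:
    """Cohort-level allele counts over non-missing diploid genotypes."""
    counts: dict[int, int] = {}
    for g in genotypes:
        if g.missing:
            continue
        for a in (g.allele_a, g.allele_b):
            counts[a] = counts.get(a, 0) + 1
    return counts


def str_allele_freqs(genotypes: Iterable[DiploidStrGenotype]) -> dict[int, float]:
    """Cohort-level allele frequencies over non-missing genotypes."""
    counts = str_allele_counts(genotypes)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no called genotypes")
    return {a: c / total for a, c in counts.items()}
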