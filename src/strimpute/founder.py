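"""Founder-haplotype analysis for repeat-expansion loci.

Pathogenic repeat expansions typically arose once, on a specific SNP
haplotype background (the founder haplotype).  Comparing present-day
phased SNP haplotypes to the founder by Hamming distance, and relating
that distance to the repeat length carried on each haplotype, tests
whether long alleles cluster on the founder background: a negative
length-vs-distance correlation supports a single founder origin.

The bundled DRPLA definition covers the nine-marker founder haplotype of
the pathogenic CAG expansion in *ATN1*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FounderHaplotype:
    """Ordered marker ids and the risk allele carried at each marker."""

    markers: tuple[str, ...]
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.alleles):
            raise ValueError("one allele per marker required")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker ids must be unique")
        object.__setattr__(self, "alleles", tuple(a.upper() for a in self.alleles))

    def __len__(self) -> int:
        return len(self.markers)


#: Founder SNP haplotype of the ATN1 CAG expansion implicated in DRPLA.
DRPLA_FOUNDER = FounderHaplotype(
    markers=(
        "rs4963516",
        "rs1007924",
        "rs7310941",
        "rs7303722",
        "rs2239167",
        "rs34199021",
        "rs2071075",
        "rs2071076",
        "rs2159887",
    ),
    alleles=("G", "A", "G", "T", "A", "A", "T", "C", "C"),
)


def hamming_to_founder(haplotype: Mapping[str, str], founder: FounderHaplotype) -> int:
    """Number of founder markers at which the haplotype differs.

    The haplotype must provide an allele at every founder marker; missing
    markers raise rather than being imputed.  Bases are compared
    uppercase.
    """
    mismatches = 0
    for marker, risk in zip(founder.markers, founder.alleles):
        if marker not in haplotype:
            raise KeyError(f"haplotype is missing founder marker {marker!r}")
        if haplotype[marker].upper() != risk:
            mismatches += 1
    return mismatches


def hamming_matrix_to_founder(marker_matrix: np.ndarray) -> np.ndarray:
    """Distances for 0/1-coded haplotypes (0 = risk allele at each marker)."""
    m = np.asarray(marker_matrix)
    return m.sum(axis=1).astype(np.int64)


@dataclass(frozen=True)
class FounderCorrelation:
    r: float
    p_value: float
    n: int
    lengths_by_distance: dict[int, np.ndarray]


def length_distance_correlation(
    str_lengths: Sequence[float], distances: Sequence[int]
) -> FounderCorrelation:
    """Pearson correlation of repeat length vs Hamming distance to founder.

    Also returns the per-distance length distributions for plotting.  A
    significantly negative r indicates that long alleles sit on
    haplotypes close to the founder background.
    """
    x = np.asarray(str_lengths, dtype=float)
    d = np.asarray(distances, dtype=float)
    if x.shape != d.shape:
        raise ValueError("lengths and distances must align")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 haplotypes")
    if x.std() == 0 or d.std() == 0:
        raise ValueError("zero variance in lengths or distances")
    res = stats.pearsonr(x, d)
    by_distance = {
        int(k): np.sort(x[d == k]) for k in np.unique(d)
    }
    return FounderCorrelation(float(res.statistic), float(res.pvalue), x.shape[0], by_distance)
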