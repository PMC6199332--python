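"""Locus-level STR quality control.

Five filters are applied to each STR: overlap with segmental duplications,
homopolymer-containing penta/hexanucleotide motifs, call rate < 80%,
expected heterozygosity < 0.095 (the bi-allelic 5% MAF equivalent), and
departure of the heterozygote count from its Hardy-Weinberg expectation
(exact two-sided binomial, p < 0.01).  Mendelian inheritance over quad
families is evaluated alongside as an orthogonal accuracy check.

All heterozygosity computations treat alleles of identical length as a
single allele: sequence-level variants of the same length are collapsed
before frequencies are formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .containers import DiploidStrGenotype, GenotypeTable, QuadFamily, StrLocus

logger = logging.getLogger(__name__)

FILTER_SEGDUP = "SEGDUP"
FILTER_HOMOPOLYMER = "HOMOPOLYMER"
FILTER_CALLRATE = "CALLRATE"
FILTER_LOWHET = "LOWHET"
FILTER_HWE = "HWE"


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; comparisons are strict (< fails)."""

    min_call_rate: float = 0.80
    min_het: float = 0.095
    hwe_alpha: float = 0.01


@dataclass
class LocusQcReport:
    locus: StrLocus
    call_rate: float
    expected_het: float
    hwe_p: float
    mendelian_rate: float | None
    filter_flags: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.filter_flags


def collapse_length_alleles(
    lengths: Sequence[float], freqs: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse same-length alleles into one, summing their frequencies.

    Returns sorted unique lengths and the corresponding summed
    frequencies; an already length-keyed input round-trips unchanged.
    """
    lengths = np.asarray(lengths)
    freqs = np.asarray(freqs, dtype=float)
    if lengths.shape != freqs.shape:
        raise ValueError("lengths and freqs must be the same length")
    uniq, inverse = np.unique(lengths, return_inverse=True)
    summed = np.bincount(inverse, weights=freqs, minlength=uniq.shape[0])
    return uniq, summed


def expected_heterozygosity(
    allele_freqs: Sequence[float], lengths: Sequence[float] | None = None
) -> float:
    """Expected heterozygosity H = 1 - sum(p_i^2).

    If ``lengths`` is given, same-length alleles are collapsed first.
    Frequencies must be nonnegative and sum to 1 within 1e-9.
    """
    freqs = np.asarray(allele_freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(freqs < 0):
        raise ValueError("allele frequencies must be nonnegative")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1, got {freqs.sum()!r}")
    if lengths is not None:
        _, freqs = collapse_length_alleles(lengths, freqs)
    return float(1.0 - np.sum(freqs**2))


def hwe_het_test(n_het: int, n_hom: int, allele_freqs: Sequence[float]) -> float:
    """Exact two-sided binomial test of the heterozygote count vs HWE.

    Under Hardy-Weinberg the probability a genotype is heterozygous is the
    expected heterozygosity H; the observed heterozygote count among
    ``n_het + n_hom`` calls is compared against Binomial(n, H).  A
    monomorphic locus returns p = 1.
    """
    n = n_het + n_hom
    if n < 1:
        raise ValueError("need at least one call")
    h = expected_heterozygosity(allele_freqs)
    if h <= 0.0:
        return 1.0
    return float(stats.binomtest(n_het, n, h, alternative="two-sided").pvalue)


def _consistent(child: DiploidStrGenotype, father: DiploidStrGenotype, mother: DiploidStrGenotype) -> bool:
    ca, cb = child.allele_a, child.allele_b
    f = (father.allele_a, father.allele_b)
    m = (mother.allele_a, mother.allele_b)
    return (ca in f and cb in m) or (cb in f and ca in m)


def mendelian_rate(
    quads: Iterable[QuadFamily], genotypes: Mapping[str, DiploidStrGenotype]
) -> float | None:
    """Fraction of child calls consistent with Mendelian transmission.

    A child call is consistent if one allele can be drawn from the
    father's pair and the other from the mother's.  Families where all
    four members are homozygous for the reference allele are excluded.
    Families with any missing member are not counted.  Returns ``None``
    (not 0) when no child call is countable.
    """
    consistent = 0
    total = 0
    for quad in quads:
        try:
            gts = {m: genotypes[m] for m in quad.members}
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} in pedigree has no genotype") from e
        if any(g.missing for g in gts.values()):
            continue
        if all(g.allele_a == 0 and g.allele_b == 0 for g in gts.values()):
            continue  # uninformative: hom-ref across the whole family
        for child in quad.children:
            total += 1
            if _consistent(gts[child], gts[quad.father], gts[quad.mother]):
                consistent += 1
    if total == 0:
        return None
    return consistent / total


def _has_homopolymer(sequence: str, run: int) -> bool:
    seq = sequence.upper()
    count = 0
    prev = ""
    for base in seq:
        count = count + 1 if base == prev else 1
        prev = base
        if count >= run:
            return True
    return False


def homopolymer_flagged(locus: StrLocus, reference_sequence: str | None = None) -> bool:
    """Penta/hexanucleotide loci containing homopolymer runs.

    Period-5 motifs with a run of >= 5 identical bases (and period-6 with
    a run of >= 6) are prone to indel artifacts.  The motif is checked
    over two tandem copies so runs spanning the motif boundary count; a
    reference sequence, if supplied, is checked directly.
    """
    if locus.period not in (5, 6):
        return False
    run = locus.period
    if _has_homopolymer(locus.motif * 2, run):
        return True
    return reference_sequence is not None and _has_homopolymer(reference_sequence, run)


def overlaps_any(locus: StrLocus, bed_intervals: Sequence[tuple[str, int, int]]) -> bool:
    """>= 1 bp overlap between the STR and 0-based half-open BED intervals."""
    s0 = locus.start - 1  # 1-based inclusive -> 0-based half-open
    e0 = locus.end
    for chrom, b_start, b_end in bed_intervals:
        if chrom == locus.chrom and b_start < e0 and b_end > s0:
            return True
    return False


def locus_qc(
    locus: StrLocus,
    genotypes: Sequence[DiploidStrGenotype],
    segdup_bed: Sequence[tuple[str, int, int]] = (),
    thresholds: QcThresholds = QcThresholds(),
    quads: Sequence[QuadFamily] | None = None,
    sample_genotypes: Mapping[str, DiploidStrGenotype] | None = None,
    reference_sequence: str | None = None,
) -> LocusQcReport:
    """Assemble the QC report for one STR locus."""
    n_total = len(genotypes)
    called = [g for g in genotypes if not g.missing]
    call_rate = len(called) / n_total if n_total else 0.0

    if called:
        counts: dict[int, int] = {}
        for g in called:
            for a in (g.allele_a, g.allele_b):
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        freqs = np.array([c / total for c in counts.values()])
        het = expected_heterozygosity(freqs)
        n_het = sum(1 for g in called if g.allele_a != g.allele_b)
        hwe_p = hwe_het_test(n_het, len(called) - n_het, freqs)
    else:
        het, hwe_p = 0.0, 1.0

    mend = None
    if quads is not None and sample_genotypes is not None:
        mend = mendelian_rate(quads, sample_genotypes)

    flags: set[str] = set()
    if overlaps_any(locus, segdup_bed):
        flags.add(FILTER_SEGDUP)
    if homopolymer_flagged(locus, reference_sequence):
        flags.add(FILTER_HOMOPOLYMER)
    if call_rate < thresholds.min_call_rate:
        flags.add(FILTER_CALLRATE)
    if het < thresholds.min_het:
        flags.add(FILTER_LOWHET)
    if hwe_p < thresholds.hwe_alpha:
        flags.add(FILTER_HWE)
    return LocusQcReport(locus, call_rate, het, hwe_p, mend, flags)


def apply_locus_filters(
    loci_genotypes: Sequence[tuple[StrLocus, Sequence[DiploidStrGenotype]]],
    segdup_bed: Sequence[tuple[str, int, int]] = (),
    thresholds: QcThresholds = QcThresholds(),
) -> list[LocusQcReport]:
    """Run the five-filter QC over a list of (locus, genotypes) pairs."""
    return [locus_qc(locus, gts, segdup_bed, thresholds) for locus, gts in loci_genotypes]


def table_qc(
    genotypes: GenotypeTable,
    quads: Sequence[QuadFamily] | None = None,
    segdup_bed: Sequence[tuple[str, int, int]] = (),
    thresholds: QcThresholds = QcThresholds(),
) -> LocusQcReport:
    """QC the STR locus of a genotype table, with Mendelian evaluation."""
    gts = genotypes.str_genotypes()
    sample_map = dict(zip(genotypes.samples, gts)) if quads is not None else None
    return locus_qc(
        genotypes.str_locus,
        gts,
        segdup_bed=segdup_bed,
        thresholds=thresholds,
        quads=quads,
        sample_genotypes=sample_map,
    )
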