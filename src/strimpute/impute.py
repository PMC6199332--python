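"""Phased SNP+STR reference panels and STR imputation.

The panel is built from quad families in three steps: (1) parental
haplotypes are phased by Mendelian transmission — at each site the allele
a parent transmitted to the first child anchors one haplotype, with
ambiguous heterozygous sites oriented afterwards by majority linkage with
the nearest already-phased heterozygous site across the cohort; (2) the
phased parents (children are excluded, keeping the panel unrelated) are
assembled into a haplotype matrix; (3) residual missing STR alleles are
filled from the haplotypes sharing the longest exact SNP match walking
outward from the STR.

Imputation into a phased SNP target haplotype scores every panel
haplotype by a distance-weighted SNP mismatch count over a +/-50 kb
window (weight 1/(1 + distance-to-STR in kb), so nearby SNPs dominate,
mirroring the decay of SNP-STR LD with distance) and copies the STR
allele of the best-matching haplotype.  Diploid genotypes are imputed one
haplotype at a time.  Everything is deterministic given panel and target.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .containers import (
    MISSING,
    DiploidStrGenotype,
    GenotypeTable,
    HaplotypePanel,
    QuadFamily,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 50_000


class PhasedParents(NamedTuple):
    """Parental haplotypes plus bookkeeping about how sites were resolved."""

    panel: HaplotypePanel  # may still contain MISSING alleles
    transmission_resolved: np.ndarray  # (n_sites, n_parents) bool
    n_inconsistent_sites: int


def _transmitted_candidates(
    parent: tuple[int, int], other: tuple[int, int] | None, child: tuple[int, int] | None
) -> set[int]:
    """Parent alleles that could have been transmitted to this child."""
    if child is None:
        return set(parent)
    if other is None:
        # without the mate's genotype any child allele the parent carries works
        return {a for a in parent if a in child}
    out = set()
    for t in set(parent):
        for q in set(other):
            if Counter((t, q)) == Counter(child):
                out.add(t)
    return out


def phase_quads_by_transmission(
    genotypes: GenotypeTable, quads: Sequence[QuadFamily]
) -> PhasedParents:
    """Phase parental genotypes using transmission to the two children.

    At each site, haplotype 1 of a parent carries the allele transmitted
    to child 1 (haplotype 2 the remaining allele) whenever Mendelian
    logic pins it down uniquely.  Sites left ambiguous are oriented by
    majority linkage with the nearest transmission-phased heterozygous
    site, using cohort-wide two-site haplotype counts.  Mendelian
    inconsistencies set the family's site missing and are logged.
    """
    n_sites = genotypes.n_sites
    parents: list[str] = []
    for q in quads:
        parents.extend([q.father, q.mother])
    n_parents = len(parents)
    H = np.full((n_sites, 2 * n_parents), MISSING, dtype=np.int32)
    resolved = np.zeros((n_sites, n_parents), dtype=bool)
    ambiguous: list[tuple[int, int, int, int]] = []  # (site, parent_idx, allele_a, allele_b)
    n_inconsistent = 0

    a_mat, b_mat, miss = genotypes.allele_a, genotypes.allele_b, genotypes.missing

    def gt(sample_idx: int, s: int) -> tuple[int, int] | None:
        if miss[s, sample_idx]:
            return None
        return int(a_mat[s, sample_idx]), int(b_mat[s, sample_idx])

    for qi, quad in enumerate(quads):
        f_idx = genotypes.sample_index(quad.father)
        m_idx = genotypes.sample_index(quad.mother)
        c1_idx = genotypes.sample_index(quad.child1)
        c2_idx = genotypes.sample_index(quad.child2)
        for role, (p_idx, o_idx) in enumerate(((f_idx, m_idx), (m_idx, f_idx))):
            parent_col = 2 * qi + role
            for s in range(n_sites):
                pg = gt(p_idx, s)
                if pg is None:
                    continue
                a, b = pg
                if a == b:
                    H[s, 2 * parent_col] = a
                    H[s, 2 * parent_col + 1] = a
                    resolved[s, parent_col] = True
                    continue
                og = gt(o_idx, s)
                c1 = gt(c1_idx, s)
                c2 = gt(c2_idx, s)
                cand1 = _transmitted_candidates((a, b), og, c1)
                cand2 = _transmitted_candidates((a, b), og, c2)
                if (c1 is not None and not cand1) or (c2 is not None and not cand2):
                    n_inconsistent += 1
                    logger.debug(
                        "Mendelian inconsistency at site %d (pos %d) in family %s; set missing",
                        s,
                        genotypes.positions[s],
                        quad.father.rsplit("_", 1)[0],
                    )
                    continue
                if len(cand1) == 1:
                    t1 = next(iter(cand1))
                    H[s, 2 * parent_col] = t1
                    H[s, 2 * parent_col + 1] = b if t1 == a else a
                    resolved[s, parent_col] = True
                else:
                    ambiguous.append((s, parent_col, a, b))

    # Second pass: orient ambiguous het sites by majority linkage with the
    # nearest transmission-phased het site, counted over cohort haplotypes.
    positions = genotypes.positions
    for s, parent_col, a, b in ambiguous:
        het_rows = [
            r
            for r in range(n_sites)
            if r != s
            and resolved[r, parent_col]
            and H[r, 2 * parent_col] != H[r, 2 * parent_col + 1]
        ]
        choice = (min(a, b), max(a, b))
        if het_rows:
            r = min(het_rows, key=lambda r: abs(int(positions[r]) - int(positions[s])))
            anchor1 = H[r, 2 * parent_col]
            anchor2 = H[r, 2 * parent_col + 1]
            ok = (H[r] != MISSING) & (H[s] != MISSING)
            pairs = Counter(zip(H[r, ok].tolist(), H[s, ok].tolist()))
            score_ab = pairs[(anchor1, a)] + pairs[(anchor2, b)]
            score_ba = pairs[(anchor1, b)] + pairs[(anchor2, a)]
            if score_ab > score_ba:
                choice = (a, b)
            elif score_ba > score_ab:
                choice = (b, a)
        H[s, 2 * parent_col] = choice[0]
        H[s, 2 * parent_col + 1] = choice[1]

    if n_inconsistent:
        logger.warning(
            "%d Mendelian-inconsistent family-sites set missing during phasing", n_inconsistent
        )
    panel = HaplotypePanel(
        genotypes.chrom, genotypes.positions, genotypes.is_str, H, genotypes.str_locus, parents
    )
    return PhasedParents(panel, resolved, n_inconsistent)


def _distance_order(panel: HaplotypePanel) -> np.ndarray:
    """SNP site indices ordered by distance from the STR start, nearest first."""
    snp_rows = np.flatnonzero(~panel.is_str)
    d = np.abs(panel.positions[snp_rows] - panel.str_locus.start)
    return snp_rows[np.argsort(d, kind="stable")]


def _fill_missing_str(panel: HaplotypePanel) -> None:
    """Fill missing STR alleles from the longest exact SNP match outward."""
    str_row = panel.str_index
    order = _distance_order(panel)
    alleles = panel.alleles
    holes = np.flatnonzero(alleles[str_row] == MISSING)
    donors = np.flatnonzero(alleles[str_row] != MISSING)
    if holes.size == 0:
        return
    if donors.size == 0:
        raise ValueError("no haplotype carries an observed STR allele")
    for h in holes:
        depth = np.zeros(donors.size, dtype=np.int64)
        alive = np.ones(donors.size, dtype=bool)
        for r in order:
            if alleles[r, h] == MISSING:
                continue
            match = alive & (alleles[r, donors] == alleles[r, h])
            if not match.any():
                break
            depth[match] += 1
            alive = match
        best = donors[depth == depth.max()]
        counts = Counter(int(alleles[str_row, d]) for d in best)
        top = max(counts.values())
        alleles[str_row, h] = min(a for a, c in counts.items() if c == top)


def build_reference_panel(phased: PhasedParents | HaplotypePanel) -> HaplotypePanel:
    """Finish the phased-parent panel: no missing alleles remain.

    Residual missing SNP alleles (from Mendelian-inconsistent sites) are
    filled with the site's major allele; missing STR alleles are copied
    from the haplotypes sharing the longest exact SNP match walking
    outward from the STR, taking the most frequent STR allele among the
    best matches (ties toward the smaller allele).
    """
    panel = (phased.panel if isinstance(phased, PhasedParents) else phased).copy()
    str_row = panel.str_index
    for r in range(panel.n_sites):
        if r == str_row:
            continue
        row = panel.alleles[r]
        holes = row == MISSING
        if holes.any():
            observed = row[~holes]
            if observed.size == 0:
                raise ValueError(f"site {r} has no observed alleles")
            values, counts = np.unique(observed, return_counts=True)
            row[holes] = values[np.argmax(counts)]
    _fill_missing_str(panel)
    return panel


@dataclass(frozen=True)
class ImputedAllele:
    """Result of haploid STR imputation for one target haplotype."""

    allele: int | None
    mismatches: int | None  # raw SNP mismatch count of the chosen haplotype
    score: float | None  # weighted mismatch score
    missing: bool = False


@dataclass(frozen=True)
class ImputedCall:
    """Diploid imputed STR genotype with per-haplotype match quality."""

    genotype: DiploidStrGenotype
    hap1: ImputedAllele
    hap2: ImputedAllele

    @property
    def dosage(self) -> int:
        return self.genotype.dosage


def impute_str(
    target_snp_alleles: np.ndarray,
    panel: HaplotypePanel,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> ImputedAllele:
    """Impute one STR allele for a phased SNP target haplotype.

    ``target_snp_alleles`` is aligned to ``panel.snp_positions``; MISSING
    entries are ignored.  Panel haplotypes are scored by the weighted SNP
    mismatch count over the window (weight 1/(1 + distance-to-STR in
    kb)); the minimum-score haplotype donates its STR allele.  Ties go to
    the most frequent STR allele among the tied haplotypes, then the
    smallest allele.  Returns a missing result when no SNP overlaps.
    """
    target = np.asarray(target_snp_alleles)
    snp_pos = panel.snp_positions
    if target.shape[0] != snp_pos.shape[0]:
        raise ValueError("target must be aligned to the panel's SNP sites")
    dist = np.abs(snp_pos - panel.str_locus.start)
    use = (dist <= window_bp) & (target != MISSING)
    if not use.any():
        return ImputedAllele(None, None, None, missing=True)
    weights = 1.0 / (1.0 + dist[use] / 1000.0)
    panel_snps = panel.snp_alleles[use]
    mism = panel_snps != target[use, None]
    scores = weights @ mism
    raw = mism.sum(axis=0)
    best = scores.min()
    tied = np.flatnonzero(scores <= best + 1e-12)
    str_alleles = panel.str_alleles[tied]
    counts = Counter(int(a) for a in str_alleles)
    top = max(counts.values())
    allele = min(a for a, c in counts.items() if c == top)
    chosen = tied[np.flatnonzero(panel.str_alleles[tied] == allele)[0]]
    return ImputedAllele(int(allele), int(raw[chosen]), float(scores[chosen]))


def impute_diploid(
    target_hap1: np.ndarray,
    target_hap2: np.ndarray,
    panel: HaplotypePanel,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> ImputedCall:
    """Impute a diploid STR genotype, one target haplotype at a time."""
    r1 = impute_str(target_hap1, panel, window_bp)
    r2 = impute_str(target_hap2, panel, window_bp)
    if r1.missing or r2.missing:
        return ImputedCall(DiploidStrGenotype(0, 0, missing=True), r1, r2)
    return ImputedCall(DiploidStrGenotype(r1.allele, r2.allele), r1, r2)


class LooPair(NamedTuple):
    sample: str
    observed: DiploidStrGenotype
    imputed: DiploidStrGenotype


def leave_one_out(panel: HaplotypePanel, window_bp: int = DEFAULT_WINDOW_BP) -> list[LooPair]:
    """Leave-one-out imputation over every sample in the panel.

    Each sample's two haplotypes are removed from the panel, its STR
    genotype is masked, and the STR is re-imputed from its own phased
    SNPs against the reduced panel.
    """
    if panel.samples is None:
        raise ValueError("leave-one-out requires a sample-bound panel")
    if len(panel.samples) < 3:
        raise ValueError("leave-one-out needs a panel of at least 3 samples")
    str_row = panel.str_index
    snp_mask = ~panel.is_str
    out: list[LooPair] = []
    for sample in panel.samples:
        c0, c1 = panel.haplotype_columns(sample)
        observed = DiploidStrGenotype(
            int(panel.alleles[str_row, c0]), int(panel.alleles[str_row, c1])
        )
        reduced = panel.drop_sample(sample)
        call = impute_diploid(
            panel.alleles[snp_mask, c0], panel.alleles[snp_mask, c1], reduced, window_bp
        )
        out.append(LooPair(sample, observed, call.genotype))
    return out
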