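"""SNP-STR linkage disequilibrium metrics.

Two genotype-level r² flavours are used throughout:

* length r² — squared Pearson correlation between STR dosages (the sum of
  the two allele length offsets) and another variant's dosage vector;
* allelic r² — one STR length allele at a time treated as a bi-allelic
  locus: squared Pearson correlation of per-sample copy counts (0/1/2)
  between two genotype sets.

The best tag SNP for an STR is the SNP within a +/-50 kb window with the
highest length r² against the STR dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DiploidStrGenotype


def str_dosage(g: DiploidStrGenotype) -> int:
    """Sum of the two STR allele length offsets."""
    return g.dosage


def dosage_vector(genotypes) -> np.ndarray:
    """Dosages as floats with NaN at missing genotypes."""
    out = np.empty(len(genotypes))
    for i, g in enumerate(genotypes):
        out[i] = np.nan if g.missing else g.dosage
    return out


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation with pairwise-complete deletion.

    Returns ``None`` (undefined, not 0) if fewer than two complete pairs
    remain or either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return None
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return None
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(cov * cov / (vx * vy))


def length_r2(x_dosages, y_dosages) -> float | None:
    """Squared Pearson correlation of two dosage vectors."""
    return _pearson_r2(np.asarray(x_dosages, dtype=float), np.asarray(y_dosages, dtype=float))


def allele_counts(genotypes, allele: int) -> np.ndarray:
    """Copies (0/1/2) of one allele per sample; NaN at missing genotypes."""
    out = np.empty(len(genotypes))
    for i, g in enumerate(genotypes):
        if g.missing:
            out[i] = np.nan
        else:
            out[i] = (g.allele_a == allele) + (g.allele_b == allele)
    return out


def allelic_r2(true_genotypes, imputed_genotypes, allele: int) -> float | None:
    """Per-allele r²: the allele treated as a bi-allelic locus.

    Counts copies of ``allele`` in each sample's true and imputed
    genotype and returns the squared Pearson correlation of the two count
    vectors; undefined if either has zero variance.
    """
    xa = allele_counts(true_genotypes, allele)
    ya = allele_counts(imputed_genotypes, allele)
    return _pearson_r2(xa, ya)


@dataclass(frozen=True)
class TagSnp:
    """Best tag SNP for an STR: id, distance to the STR start, length r²."""

    snp_id: str
    position: int
    distance: int
    length_r2: float


def minor_allele_dosage(allele_a: np.ndarray, allele_b: np.ndarray) -> np.ndarray:
    """SNP dosage as minor-allele copy count (0/1/2) per sample."""
    d = np.asarray(allele_a, dtype=float) + np.asarray(allele_b, dtype=float)
    if np.nanmean(d) > 1.0:  # alt is the major allele: flip the coding
        d = 2.0 - d
    return d


def best_tag_snp(
    str_start: int,
    str_dosages: np.ndarray,
    snp_positions: np.ndarray,
    snp_dosages: np.ndarray,
    snp_ids: list[str] | None = None,
    window_bp: int = 50_000,
) -> TagSnp | None:
    """The SNP within the window maximising length r² with the STR dosage.

    Window membership and distance are measured from the STR start.  Ties
    break toward the smaller distance, then the lower genomic position.
    Returns ``None`` when no SNP lies in the window or no r² is defined.
    """
    snp_positions = np.asarray(snp_positions, dtype=np.int64)
    snp_dosages = np.asarray(snp_dosages, dtype=float)
    if snp_ids is None:
        snp_ids = [f"snp_{p}" for p in snp_positions]
    distances = np.abs(snp_positions - str_start)
    in_window = distances <= window_bp
    best: tuple[float, int, int, int] | None = None  # (-r2, distance, position, index)
    for idx in np.flatnonzero(in_window):
        r2 = _pearson_r2(np.asarray(str_dosages, dtype=float), snp_dosages[idx])
        if r2 is None:
            continue
        key = (-r2, int(distances[idx]), int(snp_positions[idx]), int(idx))
        if best is None or key < best:
            best = key
    if best is None:
        return None
    _, dist, pos, idx = best
    return TagSnp(snp_ids[idx], pos, dist, -best[0])
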