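"""Imputation performance metrics with random and naive null models.

Per-sample genotype concordance scores 1 when the imputed unordered
allele pair equals the truth, 0.5 when exactly one imputed allele can be
matched one-to-one to a true allele, and 0 when neither can.  Cohort
metrics compare observed concordance, length r² and per-allele allelic r²
against two null imputers: the *random* model draws alleles independently
from cohort frequencies, the *naive* model always outputs the most
frequent diploid genotype.  Genotypes containing alleles seen fewer than
three times in the cohort are excluded before computing any metric.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import DiploidStrGenotype, str_allele_counts, str_allele_freqs
from .ld import allelic_r2, length_r2

COMMON_ALLELE_FREQ = 0.05
MIN_COHORT_COUNT = 3


def genotype_concordance(x: DiploidStrGenotype, y: DiploidStrGenotype) -> float:
    """Concordance score in {0, 0.5, 1} between unordered allele pairs.

    1 if both pairs match as multisets; 0 if no one-to-one matching links
    any imputed allele to a true allele; 0.5 otherwise.
    """
    if x.missing or y.missing:
        raise ValueError("concordance requires two non-missing genotypes")
    x1, x2 = x.allele_a, x.allele_b
    y1, y2 = y.allele_a, y.allele_b
    # size of the best one-to-one matching between the two pairs
    straight = (x1 == y1) + (x2 == y2)
    crossed = (x1 == y2) + (x2 == y1)
    return max(straight, crossed) / 2.0


def filter_rare_alleles(
    pairs: Sequence[tuple[DiploidStrGenotype, DiploidStrGenotype]],
    cohort_counts: dict[int, int] | None = None,
    min_count: int = MIN_COHORT_COUNT,
) -> list[tuple[DiploidStrGenotype, DiploidStrGenotype]]:
    """Drop pairs where either genotype carries a cohort-rare allele.

    Cohort counts default to counts over the observed (truth) genotypes;
    an imputed allele never observed in the cohort counts as rare.
    """
    if cohort_counts is None:
        cohort_counts = str_allele_counts(g for g, _ in pairs)
    out = []
    for obs, imp in pairs:
        alleles = []
        for g in (obs, imp):
            if not g.missing:
                alleles.extend((g.allele_a, g.allele_b))
        if all(cohort_counts.get(a, 0) >= min_count for a in alleles):
            out.append((obs, imp))
    return out


def _genotype_score_table(freqs: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotype probabilities and pairwise concordance over ordered pairs."""
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles])
    genos = list(product(range(len(alleles)), repeat=2))
    probs = np.array([p[i] * p[j] for i, j in genos])
    gts = [DiploidStrGenotype(alleles[i], alleles[j]) for i, j in genos]
    C = np.array([[genotype_concordance(a, b) for b in gts] for a in gts])
    return probs, C


def random_model_concordance(allele_freqs: dict[int, float] | Sequence[float]) -> float:
    """Expected concordance when genotypes are imputed by random allele draws.

    Exact expectation E = sum_{ij} f_i f_j sum_{kl} f_k f_l C(ij, kl)
    over ordered genotype pairs, with HWE genotype probabilities on both
    the truth and the imputation side.
    """
    if not isinstance(allele_freqs, dict):
        allele_freqs = {i: float(f) for i, f in enumerate(allele_freqs)}
    if not allele_freqs:
        raise ValueError("empty frequency vector")
    total = sum(allele_freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {total!r}")
    probs, C = _genotype_score_table(allele_freqs)
    return float(probs @ C @ probs)


def modal_genotype(genotypes: Iterable[DiploidStrGenotype]) -> DiploidStrGenotype:
    """Most frequent unordered diploid genotype.

    Ties break toward the smaller dosage, then lexicographically on the
    sorted allele pair.
    """
    counts = Counter(g.alleles() for g in genotypes if not g.missing)
    if not counts:
        raise ValueError("no called genotypes")
    top = max(counts.values())
    best = min((pair for pair, c in counts.items() if c == top), key=lambda p: (p[0] + p[1], p))
    return DiploidStrGenotype(*best)


def naive_model_concordance(genotypes: Sequence[DiploidStrGenotype]) -> float:
    """Expected concordance when every sample is imputed to the modal genotype."""
    modal = modal_genotype(genotypes)
    called = [g for g in genotypes if not g.missing]
    return float(np.mean([genotype_concordance(g, modal) for g in called]))


def random_genotypes(
    freqs: dict[int, float], n: int, seed: int
) -> list[DiploidStrGenotype]:
    """Draw n diploid genotypes by independent allele draws from freqs."""
    rng = np.random.default_rng(seed)
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles])
    p = p / p.sum()
    draws = rng.choice(alleles, size=(n, 2), p=p)
    return [DiploidStrGenotype(int(a), int(b)) for a, b in draws]


def random_model_r2(
    observed: Sequence[DiploidStrGenotype], seed: int = 0, common_freq: float = COMMON_ALLELE_FREQ
) -> tuple[float | None, dict[int, float | None]]:
    """Length and allelic r² of a single random imputation against truth.

    One random genotype is drawn per sample from the observed allele
    frequencies (fixed seed); metrics with zero variance are ``None``.
    """
    called = [g for g in observed if not g.missing]
    if len(called) < 2:
        raise ValueError("need at least two called genotypes")
    freqs = str_allele_freqs(called)
    imputed = random_genotypes(freqs, len(called), seed)
    lr2 = length_r2([g.dosage for g in called], [g.dosage for g in imputed])
    common = [a for a, f in freqs.items() if f >= common_freq]
    ar2 = {a: allelic_r2(called, imputed, a) for a in common}
    return lr2, ar2


@dataclass
class LocusEvalReport:
    """Per-locus imputation evaluation against observed genotypes."""

    n_samples: int
    concordance: float | None
    length_r2: float | None
    allelic_r2: dict[int, float | None] = field(default_factory=dict)
    naive_concordance: float | None = None
    random_concordance: float | None = None
    random_length_r2: float | None = None
    random_allelic_r2: dict[int, float | None] = field(default_factory=dict)
    multi_allelic: bool = False

    def mean_allelic_r2(self) -> float | None:
        vals = [v for v in self.allelic_r2.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    def mean_random_allelic_r2(self) -> float | None:
        vals = [v for v in self.random_allelic_r2.values() if v is not None]
        return float(np.mean(vals)) if vals else None


def evaluate_locus(
    pairs: Sequence[tuple[DiploidStrGenotype, DiploidStrGenotype]],
    seed: int = 0,
    common_freq: float = COMMON_ALLELE_FREQ,
    min_count: int = MIN_COHORT_COUNT,
) -> LocusEvalReport:
    """Full per-locus evaluation of imputed vs observed genotype pairs.

    Rare-allele carriers are excluded first; allelic r² is reported for
    common alleles (observed frequency >= 5%); the locus is flagged
    multi-allelic when it has three or more common alleles.  Fewer than
    two evaluable pairs yields a report with missing metrics.
    """
    complete = [(o, i) for o, i in pairs if not o.missing and not i.missing]
    kept = filter_rare_alleles(complete, min_count=min_count)
    if len(kept) < 2:
        return LocusEvalReport(n_samples=len(kept), concordance=None, length_r2=None)
    obs = [o for o, _ in kept]
    imp = [i for _, i in kept]
    freqs = str_allele_freqs(obs)
    common = sorted(a for a, f in freqs.items() if f >= common_freq)

    concordance = float(np.mean([genotype_concordance(o, i) for o, i in kept]))
    lr2 = length_r2([o.dosage for o in obs], [i.dosage for i in imp])
    ar2 = {a: allelic_r2(obs, imp, a) for a in common}
    rand_lr2, rand_ar2 = random_model_r2(obs, seed=seed, common_freq=common_freq)
    return LocusEvalReport(
        n_samples=len(kept),
        concordance=concordance,
        length_r2=lr2,
        allelic_r2=ar2,
        naive_concordance=naive_model_concordance(obs),
        random_concordance=random_model_concordance(freqs),
        random_length_r2=rand_lr2,
        random_allelic_r2=rand_ar2,
        multi_allelic=len(common) >= 3,
    )


def summarize_reports(reports: Sequence[LocusEvalReport]) -> pd.DataFrame:
    """Cohort summary: metric means over all loci and the multi-allelic stratum."""

    def _mean(values: Iterable[float | None]) -> float | None:
        vals = [v for v in values if v is not None]
        return float(np.mean(vals)) if vals else None

    def _row(rs: Sequence[LocusEvalReport]) -> dict:
        return {
            "n_loci": len(rs),
            "observed_concordance": _mean(r.concordance for r in rs),
            "naive_concordance": _mean(r.naive_concordance for r in rs),
            "random_concordance": _mean(r.random_concordance for r in rs),
            "observed_length_r2": _mean(r.length_r2 for r in rs),
            "random_length_r2": _mean(r.random_length_r2 for r in rs),
            "observed_allelic_r2": _mean(r.mean_allelic_r2() for r in rs),
            "random_allelic_r2": _mean(r.mean_random_allelic_r2() for r in rs),
        }

    rows = {"all": _row(reports), "multi_allelic": _row([r for r in reports if r.multi_allelic])}
    return pd.DataFrame.from_dict(rows, orient="index")
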