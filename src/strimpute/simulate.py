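"""Synthetic cohorts: phased SNP-STR haplotypes, quad families, genotyping
errors, and expression tables.

The generator emulates the statistical structure that SNP-STR imputation
relies on: a multi-allelic STR whose length alleles arose by stepwise
mutation on SNP haplotype backgrounds, so that haplotype identity is
informative about repeat length.  Haplotypes are produced sequentially by
copying a previously generated haplotype with per-site template switching
(tunable linkage decay), per-site SNP mutation, and stepwise STR mutation
(geometric step size in repeat units, sign symmetric).  Families are quads:
two parents drawn from the haplotype pool and two children receiving one
recombined haplotype from each parent.  Genotyping noise follows the PCR
error mechanism for STRs: stutter shifts a called allele by one repeat
unit, and dropout removes the genotype entirely.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .containers import GenotypeTable, HaplotypePanel, QuadFamily, StrLocus

_PROB_FIELDS = (
    "snp_mutation_rate",
    "recomb_switch_rate",
    "str_mutation_rate",
    "stutter_up",
    "stutter_down",
    "dropout_rate",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic SNP-STR cohort.

    Defaults describe a single ~100 kb region around one polymorphic
    dinucleotide STR with moderate SNP-STR linkage: a few stepwise
    mutations scattered over the copying genealogy of 200 founder
    haplotypes, occasional template switches eroding LD, and low-level
    stutter/dropout noise.
    """

    n_founder_haplotypes: int = 200
    n_snps: int = 50
    region_length: int = 100_000
    snp_mutation_rate: float = 0.002
    recomb_switch_rate: float = 0.01
    str_mutation_rate: float = 0.05
    str_step_geom_p: float = 0.7
    stutter_up: float = 0.01
    stutter_down: float = 0.02
    dropout_rate: float = 0.02
    seed: int = 0
    n_seed_haplotypes: int = 2
    motif: str = "AC"
    reference_length: int = 40

    def __post_init__(self) -> None:
        if self.n_founder_haplotypes < 2:
            raise ValueError(
                f"n_founder_haplotypes must be >= 2, got {self.n_founder_haplotypes}"
            )
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")
        if not 0 < self.str_step_geom_p <= 1:
            raise ValueError(f"str_step_geom_p must be in (0, 1], got {self.str_step_geom_p}")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if not 2 <= self.n_seed_haplotypes <= self.n_founder_haplotypes:
            raise ValueError("n_seed_haplotypes must be in [2, n_founder_haplotypes]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


class SimulatedQuads(NamedTuple):
    """Output of :func:`simulate_quads`: genotypes, pedigree and phased truth."""

    genotypes: GenotypeTable
    families: list[QuadFamily]
    truth: HaplotypePanel


def _site_layout(config: SimulationConfig, rng: np.random.Generator):
    """SNP positions plus one STR at the region centre; strictly increasing."""
    str_start = config.region_length // 2
    str_end = str_start + config.reference_length - 1
    forbidden = set(range(str_start, str_end + 1))
    candidates = np.setdiff1d(
        np.arange(1, config.region_length + 1), np.fromiter(forbidden, dtype=np.int64)
    )
    snp_pos = np.sort(rng.choice(candidates, size=config.n_snps, replace=False))
    positions = np.sort(np.append(snp_pos, str_start))
    is_str = positions == str_start
    return positions, is_str, StrLocus("chr1", str_start, str_end, config.motif, config.reference_length)


def _stepwise_mutation(offset: int, period: int, rng: np.random.Generator, geom_p: float) -> int:
    """One stepwise mutation: +/- k repeat units, k ~ Geometric(p), k >= 1."""
    k = int(rng.geometric(geom_p))
    sign = 1 if rng.random() < 0.5 else -1
    return offset + sign * k * period


def simulate_founder_haplotypes(config: SimulationConfig) -> HaplotypePanel:
    """Generate a pool of phased SNP-STR founder haplotypes.

    The first ``n_seed_haplotypes`` haplotypes are drawn independently
    (uniform SNP alleles; STR offsets a few repeat units around the
    reference).  Each subsequent haplotype copies a uniformly chosen
    earlier haplotype, switching template at each site with probability
    ``recomb_switch_rate``, flipping SNP alleles at ``snp_mutation_rate``
    and mutating the STR stepwise at ``str_mutation_rate``.  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    positions, is_str, locus = _site_layout(config, rng)
    n_sites = positions.shape[0]
    str_idx = int(np.flatnonzero(is_str)[0])
    period = locus.period

    H = np.zeros((n_sites, config.n_founder_haplotypes), dtype=np.int32)
    for h in range(config.n_seed_haplotypes):
        H[:, h] = rng.integers(0, 2, size=n_sites)
        H[str_idx, h] = int(rng.integers(-2, 3)) * period

    for h in range(config.n_seed_haplotypes, config.n_founder_haplotypes):
        template = int(rng.integers(0, h))
        hap = np.empty(n_sites, dtype=np.int32)
        switch = rng.random(n_sites) < config.recomb_switch_rate
        for s in range(n_sites):
            if switch[s]:
                template = int(rng.integers(0, h))
            hap[s] = H[s, template]
        flip = rng.random(n_sites) < config.snp_mutation_rate
        flip[str_idx] = False
        hap[flip] = 1 - hap[flip]
        if rng.random() < config.str_mutation_rate:
            hap[str_idx] = _stepwise_mutation(int(hap[str_idx]), period, rng, config.str_step_geom_p)
        H[:, h] = hap

    return HaplotypePanel("chr1", positions, is_str, H, locus)


def decouple_str(panel: HaplotypePanel, seed: int, fraction: float = 1.0) -> HaplotypePanel:
    """Weaken SNP-STR LD by permuting STR alleles across haplotypes.

    A random ``fraction`` of haplotypes have their STR alleles shuffled
    among themselves; marginal allele frequencies are preserved.  At
    ``fraction=1`` the STR becomes independent of every SNP (zero-LD
    negative control); intermediate fractions give a tunable LD-strength
    grid on an otherwise identical panel.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    n = out.n_haplotypes
    k = int(round(fraction * n))
    cols = rng.choice(n, size=k, replace=False)
    row = out.alleles[out.str_index]
    row[cols] = row[rng.permutation(cols)]
    return out


def _recombine(
    h1: np.ndarray, h2: np.ndarray, switch_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """One gamete: copy along the sites, switching parental template."""
    n = h1.shape[0]
    current = int(rng.integers(0, 2))
    out = np.empty(n, dtype=np.int32)
    switch = rng.random(n) < switch_rate
    for s in range(n):
        if switch[s]:
            current = 1 - current
        out[s] = h1[s] if current == 0 else h2[s]
    return out


def simulate_quads(
    panel: HaplotypePanel,
    n_families: int,
    seed: int,
    recomb_switch_rate: float = 0.01,
) -> SimulatedQuads:
    """Draw quad families from a founder haplotype pool.

    Each parent receives two haplotypes drawn with replacement from the
    pool; each child one recombined gamete from each parent.  Returns the
    unphased diploid genotype table, the pedigree, and the phased truth
    haplotypes of every sample (for validating phasing and imputation).
    """
    if n_families < 1:
        raise ValueError(f"n_families must be >= 1, got {n_families}")
    if panel.n_haplotypes < 4:
        raise ValueError("panel must contain at least 4 haplotypes")
    rng = np.random.default_rng(seed)

    samples: list[str] = []
    families: list[QuadFamily] = []
    hap_cols: list[np.ndarray] = []
    for f in range(n_families):
        names = {role: f"fam{f:04d}_{role}" for role in ("father", "mother", "child1", "child2")}
        families.append(QuadFamily(**names))
        parent_haps = {}
        for role in ("father", "mother"):
            i, j = rng.integers(0, panel.n_haplotypes, size=2)
            parent_haps[role] = (panel.alleles[:, i].copy(), panel.alleles[:, j].copy())
        child_haps = {}
        for role in ("child1", "child2"):
            paternal = _recombine(*parent_haps["father"], recomb_switch_rate, rng)
            maternal = _recombine(*parent_haps["mother"], recomb_switch_rate, rng)
            child_haps[role] = (paternal, maternal)
        for role in ("father", "mother"):
            samples.append(names[role])
            hap_cols.extend(parent_haps[role])
        for role in ("child1", "child2"):
            samples.append(names[role])
            hap_cols.extend(child_haps[role])

    H = np.column_stack(hap_cols)
    truth = HaplotypePanel(panel.chrom, panel.positions, panel.is_str, H, panel.str_locus, samples)
    a = H[:, 0::2]
    b = H[:, 1::2]
    missing = np.zeros(a.shape, dtype=bool)
    genotypes = GenotypeTable(
        panel.chrom, panel.positions, panel.is_str, a, b, missing, panel.str_locus, samples
    )
    return SimulatedQuads(genotypes, families, truth)


def inject_genotyping_errors(
    genotypes: GenotypeTable, config: SimulationConfig, seed: int | None = None
) -> GenotypeTable:
    """Apply PCR stutter and dropout to the STR genotypes.

    Independently per called allele, with probability ``stutter_up``
    (resp. ``stutter_down``) the allele shifts by +1 (resp. -1) repeat
    unit; with probability ``dropout_rate`` the whole genotype is set
    missing.  SNP sites are untouched.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = genotypes.copy()
    i = out.str_index
    period = out.str_locus.period
    n = out.n_samples
    for mat in (out.allele_a, out.allele_b):
        u = rng.random(n)
        up = u < config.stutter_up
        down = (u >= config.stutter_up) & (u < config.stutter_up + config.stutter_down)
        mat[i, up] += period
        mat[i, down] -= period
    drop = rng.random(n) < config.dropout_rate
    out.missing[i, drop] = True
    return out


def simulate_expression(
    dosage: np.ndarray,
    beta: float,
    covariates: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    gamma: np.ndarray | None = None,
) -> np.ndarray:
    """Expression from an STR dosage effect: Y = beta * scaled(X) + C @ gamma + eps.

    The dosage is standardised to mean 0 / variance 1 before applying the
    effect; noise is independent normal with standard deviation
    ``noise_sd``.  ``gamma`` defaults to a vector of ones.
    """
    dosage = np.asarray(dosage, dtype=float)
    if not np.all(np.isfinite(dosage)):
        raise ValueError("dosage vector must be finite")
    sd = dosage.std()
    x = (dosage - dosage.mean()) / sd if sd > 0 else np.zeros_like(dosage)
    rng = np.random.default_rng(seed)
    y = beta * x + rng.normal(0.0, noise_sd, size=dosage.shape[0])
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != dosage.shape[0]:
            C = C.T
        if C.shape[0] != dosage.shape[0]:
            raise ValueError("covariate rows must match the number of samples")
        g = np.ones(C.shape[1]) if gamma is None else np.asarray(gamma, dtype=float)
        if g.shape[0] != C.shape[1]:
            raise ValueError("gamma must have one coefficient per covariate")
        y = y + C @ g
    return y


def simulate_founder_cohort(
    n_haplotypes: int,
    n_markers: int = 9,
    founder_length: int = 54,
    marker_mutation_rate: float = 0.05,
    str_contraction_rate: float = 0.6,
    str_step_units: int = 1,
    period: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Haplotypes diverging from a pathogenic founder background.

    Models the classic repeat-expansion history: an expanded STR allele
    arose once on a specific SNP haplotype.  Haplotypes are generated by
    sequential copying starting from the founder; each copy flips founder
    markers at ``marker_mutation_rate`` and, with probability
    ``str_contraction_rate``, steps the repeat length down by
    ``str_step_units`` repeat units.  Divergence therefore accumulates
    jointly in marker mismatches and repeat contraction, producing the
    negative length-vs-Hamming-distance relationship seen at founder loci.

    Returns ``(marker_matrix, lengths)`` where ``marker_matrix`` is
    ``n_haplotypes x n_markers`` with 0 = founder (risk) allele, 1 = other
    allele, and ``lengths`` are STR lengths in bp.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = np.random.default_rng(seed)
    markers = np.zeros((n_haplotypes, n_markers), dtype=np.int8)
    lengths = np.full(n_haplotypes, founder_length, dtype=np.int64)
    for h in range(1, n_haplotypes):
        t = int(rng.integers(0, h))
        m = markers[t].copy()
        flip = rng.random(n_markers) < marker_mutation_rate
        m[flip] = 1 - m[flip]
        L = int(lengths[t])
        if rng.random() < str_contraction_rate:
            L = max(period, L - str_step_units * period)
        markers[h] = m
        lengths[h] = L
    return markers, lengths
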