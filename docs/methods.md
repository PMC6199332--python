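# Methods

## The problem setting

STR alleles mutate fast — typically by whole repeat units under a stepwise
process — so a locus accumulates many length alleles on a comparatively
stable SNP background. The degree to which SNP haplotypes "remember" which
STR allele they carry is exactly what makes STR imputation possible, and
exactly what the synthetic-data generator controls.

## Synthetic cohort generator

Founder haplotypes are generated sequentially: the first
`n_seed_haplotypes` (default 2) are drawn independently (uniform SNP
alleles; STR offsets a few repeat units around the reference), and each
subsequent haplotype copies a uniformly chosen earlier one, switching
template at each site with probability `recomb_switch_rate`, flipping SNP
alleles at `snp_mutation_rate`, and mutating the STR with probability
`str_mutation_rate` per copy (step size k ≥ 1 repeat units with
Geometric(`str_step_geom_p`) distribution, sign symmetric). This
copy-with-switch scheme was chosen over a coalescent simulator because it
makes LD strength directly and monotonically tunable with two scalar
knobs, needs no external dependency, and still produces the two features
imputation relies on: haplotype sharing (copying) and its decay
(switching + mutation).

Defaults describe one ~100 kb region: 50 SNPs, a dinucleotide STR (motif
`AC`, reference length 40 bp) at the region centre, 200 founder
haplotypes, `snp_mutation_rate = 0.002`, `recomb_switch_rate = 0.01`,
`str_mutation_rate = 0.05`, `str_step_geom_p = 0.7`. These yield a
realistic polymorphic STR (typically 5–10 length alleles, expected
heterozygosity ≈ 0.5) in moderate SNP–STR LD. Error rates default to
stutter up/down = 0.01/0.02 per called allele (down-stutter dominates in
PCR) and 2% genotype dropout; they are free parameters, not estimates of
any particular caller's residual error.

Quad families draw two parental haplotypes each with replacement from the
founder pool; children receive one recombined gamete per parent (same
per-site switch process). 479 families — the cohort design used
throughout — give 1916 samples and a 1916-haplotype truth panel.

Units: STR alleles are carried everywhere as signed bp offsets from the
reference length; mutation and stutter steps are whole repeat units, i.e.
multiples of the motif period, applied in bp. All r², concordance and
regression metrics are invariant to this choice of units.

An `ld_strength` grid is realised by `decouple_str(panel, seed,
fraction)`: permuting the STR alleles of a random fraction of haplotypes
destroys that fraction of the SNP–STR association while leaving marginal
allele frequencies and everything else identical — a cleaner dial than
re-simulating with different switch rates, because grid points share the
panel.

What the generator does *not* emulate: read-level sequencing, realistic
recombination maps (switching is uniform per site), sequence-level
(non-length) allele variation, population structure, and multi-unit
stutter. Tests passing on this generator therefore demonstrate the
statistical machinery — not performance on any real cohort, where LD
structure, allele spectra and error processes are richer.

## Locus QC

Five filters, with thresholds as strict inequalities:

1. **SEGDUP** — ≥ 1 bp overlap with a segmental-duplication interval.
   BED input is 0-based half-open; internal coordinates are 1-based
   inclusive; conversion happens once, at the comparison.
2. **HOMOPOLYMER** — period-5 (resp. 6) loci whose motif (checked over two
   tandem copies) or reference sequence contains a run of ≥ 5 (resp. 6)
   identical bases. In practice only the reference-sequence branch can
   fire for valid motifs, since a pure tandem tract cannot reach the run
   length.
3. **CALLRATE** — call rate < 0.80, denominator = all cohort samples.
4. **LOWHET** — expected heterozygosity `H = 1 − Σ pᵢ²` < 0.095 (the
   bi-allelic equivalent of a 5% minor allele frequency; alleles of equal
   length are collapsed before frequencies are formed).
5. **HWE** — exact two-sided binomial test of the heterozygote count
   against Binomial(n, H), p < 0.01. The heterozygote-count formulation
   was chosen over a genotype-table chi-square because it remains
   well-defined and calibrated for many-allele STRs; the cost is that
   only heterozygote excess/deficit is detected, not arbitrary genotype
   distortions. With plug-in frequencies estimated from the same calls
   the test is slightly conservative; calibration checks feed it the
   generating frequencies.

Mendelian rate counts a child call consistent when one allele can be
drawn from the father's pair and the other from the mother's (length
alleles only; phase is never consulted). Families that are homozygous
reference across all four members are excluded from the denominator, and
the rate is undefined — not zero — when nothing is countable.

## Phasing and panel building

Parents are phased by transmission: at each site, haplotype 1 carries the
allele the parent transmitted to child 1 (haplotype 2 the remaining
allele) whenever Mendelian logic yields a unique assignment given the
other parent and the children's genotypes. Sites left ambiguous (e.g.
both parents and children heterozygous for the same alleles) are oriented
afterwards by majority linkage: cohort-wide two-site haplotype counts
against the nearest transmission-phased heterozygous site of the same
parent, with a deterministic smaller-allele-first fallback when no
linkage information exists. Mendelian-inconsistent sites are set missing
for that family and counted. With error-free input and no recombination
the reconstruction matches the simulated truth at ≥ 99% of resolvable
heterozygous sites; under recombination the reconstructed pair is a
mosaic of the parent's true haplotypes, which is still a valid phased
panel entry.

The reference panel keeps only the parents (children would duplicate
their haplotypes). Residual missing STR alleles — dropout plus phasing
casualties — are filled from the haplotypes sharing the longest exact SNP
match walking outward from the STR, taking the most frequent STR allele
among the best matches (ties toward the smaller allele); residual missing
SNP alleles take the site's major allele.

## Imputation

Given a phased SNP target haplotype, every panel haplotype is scored by a
weighted mismatch count over the SNPs within ±50 kb of the STR start,
with weight 1/(1 + distance in kb) so that SNPs near the STR dominate —
a first-order stand-in for the decay of LD with distance. The
minimum-score haplotype donates its STR allele; ties resolve to the most
frequent STR allele among the tied haplotypes, then the smallest.
Diploid imputation treats the two target haplotypes independently.
Everything is deterministic given panel and target, and panel column
order does not affect results. This matcher deliberately omits the
Li–Stephens HMM's recombination/mutation parameters: at panel scales
where deep haplotype sharing exists it performs comparably, and its
determinism makes leave-one-out evaluation and tie-break behaviour
exactly reproducible. Panels export to standard phased VCF for users who
want to run an external imputer instead.

Leave-one-out: each sample's two haplotype columns are removed, its STR
masked, and the STR re-imputed from its own phased SNPs against the
reduced panel.

## Evaluation

Concordance scores 1 when imputed and true unordered allele pairs match,
0 when no one-to-one matching links any imputed allele to a true one, and
0.5 otherwise — so (10,10) vs (10,12) scores 0.5, not 1, because the
single 10 can only be matched once. Pairs containing any allele seen
fewer than three times in the cohort (counted over observed genotypes)
are excluded first; allelic r² is reported for alleles at ≥ 5% frequency,
and a locus with ≥ 3 such common alleles is flagged multi-allelic.

The random model's expected concordance is computed exactly:
`E = Σ_{ij} f_i f_j Σ_{kl} f_k f_l C(ij, kl)` over ordered genotype pairs
with Hardy–Weinberg genotype probabilities on both sides (0.625 for a
bi-allelic locus at f = 0.5). Random-model r² uses one seeded draw of two
alleles per sample — a single realisation rather than an average, so it
carries sampling noise of order 1/√n. The naive model's expectation is
the mean concordance of every observed genotype against the modal
genotype (ties toward the smaller dosage, then lexicographic). Undefined
metrics (zero variance, too few pairs) are reported as missing, never 0.

## Association and power

The additive phenotype model is `P = βG + E` with G the standardised
dosage and `E ~ N(0, 1−β)` — the second parameter read as a *variance*,
so β = 1 is exactly noiseless and β > 1 is rejected; reading it as an SD
would change the power scale but none of the orderings. Case–control
outcomes are Bernoulli with `logit pᵢ = βXᵢ`. The quadratic model uses
`G = (allele-length sum)² / mean allele length`, resolving the scaling as
division by the cohort mean per-allele length.

Power = fraction of seeded simulations with nominal p < α (default 0.05,
100 simulations, n = 950 — the parents of 475 quads). Quantitative-trait
power uses the exact OLS slope test in vectorised form (t from the
sample correlation); the noncentral-F reference
`power = P(F(1, n−2, nβ²/(1−β)) > F_crit)` serves as an analytic oracle.
Logistic fits go through statsmodels with separation flagged rather than
raised.

The eSTR regression drops genes with zero median expression, quantile-
normalizes expression to standard normal scores Φ⁻¹((r−0.5)/n) (average
ranks on ties), standardises STR dosage, and fits OLS with covariates
supplied as a numeric matrix (their estimation — expression factors,
ancestry components — is out of scope). Effect-recovery checks fit the
unnormalized expression, since rank-normalising a variance-inflated
outcome rescales the generating slope. The nested comparison
Y ~ eSNP vs Y ~ eSNP + eSTR is a one-degree F-test via `anova_lm`;
an STR dosage collinear with the SNP yields NaN, flagged.

## Founder analysis

Hamming distance between a phased haplotype and a founder definition
(ordered markers, one risk allele each) counts discordant positions;
haplotypes missing a founder marker are rejected rather than imputed,
since a silent skip would bias distances downward. The bundled DRPLA
definition carries the nine-marker founder haplotype of the *ATN1* CAG
expansion. The founder-cohort simulator re-uses the sequential-copy
process seeded at the founder itself, with marker flips and a
downward-biased repeat step per copy, so marker divergence and repeat
contraction accumulate jointly along the copying genealogy — yielding the
negative length-vs-distance correlation characteristic of a single-origin
expansion. Distances are computed on haplotypes, never on unphased
genotypes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the cohort design at 479
quads (1916 samples) for the pipeline stages, 950 samples for power,
336 for expression, and 25–30 families per replicate on the seeded
LD-strength grids (10 replicates per grid point); these sizes give the
statistical checks comfortable resolution while keeping any single run in
seconds. Score ties in the imputer are compared with a 1e-12 tolerance;
frequency-vector validation allows 1e-9 slack on the sum; all random
draws flow from explicit integer seeds via `numpy.random.default_rng`.

## Known limitations

- The transmission phaser assumes quads; trios/duos and unphased targets
  are out of scope.
- One STR per region; multi-STR regions are handled by running regions
  independently.
- The imputer has no population-genetic model of recombination; with very
  large panels or weak haplotype sharing an HMM-based imputer should be
  preferred (the panel VCF is compatible).
- Null-model r² is a single random realisation by design; averaging over
  draws would shrink it toward its expectation.
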