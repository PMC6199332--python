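# strimpute

Short tandem repeats (STRs) — 1–6 bp motifs repeated in tandem — are among
the most polymorphic variants in the human genome, but genotyping arrays
only assay SNPs, so STRs are invisible to standard GWAS. If STR alleles sit
on identifiable SNP haplotype backgrounds, a phased SNP+STR reference panel
lets you *impute* STR genotypes into any SNP dataset and test them for
association directly.

`strimpute` implements that workflow end to end for researchers working on
repeat variation and association studies:

- **Synthetic cohorts** — phased SNP haplotypes carrying a linked
  multi-allelic STR whose alleles arose by stepwise mutation (geometric
  step size, in repeat units) on haplotype backgrounds, with tunable
  SNP–STR LD, quad families (two parents, two children), PCR-stutter
  genotyping errors and dropout.
- **Locus QC** — the five classic STR filters (segmental-duplication
  overlap, homopolymer-containing penta/hexanucleotide motifs, call rate
  < 80%, expected heterozygosity `H = 1 − Σ pᵢ²` < 0.095, and an exact
  two-sided binomial test of the heterozygote count against its
  Hardy–Weinberg expectation at p < 0.01), plus Mendelian-inheritance
  evaluation over quads.
- **Panel building and imputation** — transmission phasing of parents,
  a phased reference panel over the unrelated parents, and a deterministic
  window-matching imputer: panel haplotypes are scored by distance-weighted
  SNP mismatches in a ±50 kb window around the STR and the best match
  donates its STR allele. Leave-one-out (LOO) evaluation is built in.
- **Evaluation metrics** — per-sample genotype concordance (1 / 0.5 / 0
  for both / one / neither allele matched), length *r*² (squared Pearson
  correlation of dosages, where dosage = sum of the two allele length
  offsets), per-allele allelic *r*², and two null imputers: *random*
  (alleles drawn from cohort frequencies) and *naive* (always the modal
  diploid genotype).
- **Association and power** — phenotype simulation under additive
  (`P = βG + E`, `E ~ N(0, 1−β)`), case–control (`logit pᵢ = βXᵢ`) and
  quadratic models; OLS/logistic/per-allele tests; power as the fraction
  of simulations with p < 0.05 compared across the causal STR, the imputed
  STR and the best tag SNP; a cis-eSTR regression
  (`qnorm(Y) ~ scaled dosage + covariates`) with nested-model ANOVA.
- **Founder haplotypes** — Hamming distance of phased SNP haplotypes to a
  pathogenic founder haplotype (the DRPLA nine-marker definition is
  bundled) correlated with repeat length.

## Worked example

Simulate a 479-quad cohort (1916 samples) with genotyping noise, QC the
STR, build the reference panel from the phased parents, and evaluate
leave-one-out imputation against the null models:

```python
import strimpute as si

cfg = si.SimulationConfig(seed=1)
pool = si.simulate_founder_haplotypes(cfg)
sim = si.simulate_quads(pool, 479, seed=2)
noisy = si.inject_genotyping_errors(sim.genotypes, cfg)

qc = si.table_qc(noisy, quads=sim.families)
print(f"call rate {qc.call_rate:.3f}, H {qc.expected_het:.3f}, "
      f"Mendelian {qc.mendelian_rate:.3f}, pass: {qc.passed}")

phased = si.phase_quads_by_transmission(noisy, sim.families)
panel = si.build_reference_panel(phased)
pairs = [(p.observed, p.imputed) for p in si.leave_one_out(panel)]
report = si.evaluate_locus(pairs, seed=0)
print(f"LOO concordance {report.concordance:.3f} "
      f"(naive {report.naive_concordance:.3f}, random {report.random_concordance:.3f}); "
      f"length r2 {report.length_r2:.3f}")
```

prints

```
call rate 0.979, H 0.498, Mendelian 0.924, pass: True
LOO concordance 0.933 (naive 0.675, random 0.606); length r2 0.906
```

So at this noisy, highly polymorphic locus the haplotype-matching imputer
recovers 93.3% of diploid genotypes, far above what always guessing the
modal genotype (67.5%) or drawing alleles at random (60.6%) would achieve,
and the imputed dosages explain ~91% of the variance in the observed ones.

A `strimpute` console script exposes the same stages as subcommands
(`simulate`, `qc`, `ld`, `impute --loo`, `evaluate`, `power`, `estr`,
`founder`) over VCF/PED/BED/TSV files; run `strimpute --help`.

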