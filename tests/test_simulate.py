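"""Synthetic-cohort generator: determinism, copying fidelity, error model."""

import numpy as np
import pytest

import strimpute as si


class TestFounderHaplotypes:
    def test_fixed_seed_is_bit_identical(self):
        cfg = si.SimulationConfig(seed=1)
        a = si.simulate_founder_haplotypes(cfg)
        b = si.simulate_founder_haplotypes(cfg)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)

    def test_no_str_mutation_gives_monomorphic_str(self):
        cfg = si.SimulationConfig(seed=2, str_mutation_rate=0.0, n_seed_haplotypes=2)
        panel = si.simulate_founder_haplotypes(cfg)
        # seeds may start on different alleles, but copies never mutate:
        # every allele must be one of the two seed alleles
        seeds = set(panel.str_alleles[:2].tolist())
        assert set(panel.str_alleles.tolist()) <= seeds

    def test_perfect_copying_reproduces_the_seeds(self):
        cfg = si.SimulationConfig(
            seed=3, snp_mutation_rate=0.0, recomb_switch_rate=0.0, str_mutation_rate=0.0
        )
        panel = si.simulate_founder_haplotypes(cfg)
        seed_cols = [panel.alleles[:, 0], panel.alleles[:, 1]]
        for h in range(panel.n_haplotypes):
            col = panel.alleles[:, h]
            assert any(np.array_equal(col, s) for s in seed_cols)

    def test_perfect_copying_with_distinct_seed_strs_gives_r2_one(self):
        # find a seed whose two founder haplotypes carry distinct STR alleles
        for seed in range(50):
            cfg = si.SimulationConfig(
                seed=seed, snp_mutation_rate=0.0, recomb_switch_rate=0.0, str_mutation_rate=0.0
            )
            panel = si.simulate_founder_haplotypes(cfg)
            if panel.str_alleles[0] != panel.str_alleles[1]:
                break
        else:
            pytest.fail("no config with distinct seed STR alleles found")
        # any SNP differing between the two seeds is in perfect LD with the STR
        snp = panel.snp_alleles
        diff = np.flatnonzero(snp[:, 0] != snp[:, 1])
        assert diff.size > 0
        r2 = si.length_r2(snp[diff[0]].astype(float), panel.str_alleles.astype(float))
        assert r2 == pytest.approx(1.0)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError, match="n_founder_haplotypes"):
            si.SimulationConfig(n_founder_haplotypes=1)
        with pytest.raises(ValueError, match="probability"):
            si.SimulationConfig(stutter_up=1.5)

    def test_allele_count_nondecreasing_in_mutation_rate(self):
        """Mean number of distinct STR length alleles grows with the mutation rate."""
        rates = [0.0, 0.02, 0.1, 0.4]
        means = []
        for rate in rates:
            counts = [
                len(
                    set(
                        si.simulate_founder_haplotypes(
                            si.SimulationConfig(seed=100 + r, str_mutation_rate=rate)
                        ).str_alleles.tolist()
                    )
                )
                for r in range(20)
            ]
            means.append(np.mean(counts))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


class TestQuads:
    def test_children_inherit_parent_haplotypes_without_recombination(self, founder_panel):
        sim = si.simulate_quads(founder_panel, 10, seed=5, recomb_switch_rate=0.0)
        t = sim.truth
        for quad in sim.families:
            f0, f1 = t.haplotype_columns(quad.father)
            m0, m1 = t.haplotype_columns(quad.mother)
            for child in quad.children:
                c_pat, c_mat = t.haplotype_columns(child)
                assert any(
                    np.array_equal(t.alleles[:, c_pat], t.alleles[:, p]) for p in (f0, f1)
                )
                assert any(
                    np.array_equal(t.alleles[:, c_mat], t.alleles[:, p]) for p in (m0, m1)
                )

    def test_479_families_give_1916_samples(self, founder_panel):
        sim = si.simulate_quads(founder_panel, 479, seed=6)
        assert sim.genotypes.n_samples == 1916
        assert len(sim.families) == 479

    def test_error_free_output_is_fully_mendelian(self, quad_sim):
        gts = dict(zip(quad_sim.genotypes.samples, quad_sim.genotypes.str_genotypes()))
        assert si.mendelian_rate(quad_sim.families, gts) == 1.0

    def test_rejects_empty_cohort(self, founder_panel):
        with pytest.raises(ValueError, match="n_families"):
            si.simulate_quads(founder_panel, 0, seed=1)


class TestGenotypingErrors:
    def test_zero_rates_are_identity(self, quad_sim, base_config):
        cfg = base_config.replace(stutter_up=0.0, stutter_down=0.0, dropout_rate=0.0)
        out = si.inject_genotyping_errors(quad_sim.genotypes, cfg)
        assert np.array_equal(out.allele_a, quad_sim.genotypes.allele_a)
        assert np.array_equal(out.allele_b, quad_sim.genotypes.allele_b)
        assert not out.missing.any()

    def test_dropout_fraction_matches_binomial_expectation(self, founder_panel, base_config):
        sim = si.simulate_quads(founder_panel, 250, seed=9)  # 1000 samples
        cfg = base_config.replace(stutter_up=0.0, stutter_down=0.0, dropout_rate=0.25)
        out = si.inject_genotyping_errors(sim.genotypes, cfg, seed=10)
        frac = out.missing[out.str_index].mean()
        # 3 SE binomial band around 0.25 at n=1000
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 1000)

    def test_certain_up_stutter_shifts_every_allele_one_unit(self, quad_sim, base_config):
        cfg = base_config.replace(stutter_up=1.0, stutter_down=0.0, dropout_rate=0.0)
        out = si.inject_genotyping_errors(quad_sim.genotypes, cfg)
        i = out.str_index
        period = out.str_locus.period
        assert np.array_equal(out.allele_a[i], quad_sim.genotypes.allele_a[i] + period)
        assert np.array_equal(out.allele_b[i], quad_sim.genotypes.allele_b[i] + period)

    def test_homozygous_concordance_matches_closed_form(self, rng):
        """P(called genotype concordant) = (1 - e_up - e_down)^2 for homozygous truth."""
        e_up, e_down = 0.08, 0.12
        cfg = si.SimulationConfig(seed=0, stutter_up=e_up, stutter_down=e_down, dropout_rate=0.0)
        n = 4000
        positions = np.array([1, 100])
        is_str = np.array([False, True])
        locus = si.StrLocus("chr1", 100, 103, "AC", 4)
        zeros = np.zeros((2, n), dtype=np.int32)
        table = si.GenotypeTable(
            "chr1", positions, is_str, zeros.copy(), zeros.copy(), np.zeros((2, n), bool),
            locus, [f"s{i}" for i in range(n)],
        )
        out = si.inject_genotyping_errors(table, cfg, seed=99)
        scores = [
            si.genotype_concordance(t, o)
            for t, o in zip(table.str_genotypes(), out.str_genotypes())
        ]
        p_exact = sum(s == 1.0 for s in scores) / n
        expected = (1 - e_up - e_down) ** 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(p_exact - expected) < 3 * se


class TestExpression:
    def test_zero_noise_is_collinear_with_dosage(self, rng):
        d = rng.integers(0, 8, 100).astype(float)
        y = si.simulate_expression(d, beta=1.0, noise_sd=0.0, seed=1)
        assert si.length_r2(d, y) == pytest.approx(1.0)

    def test_covariate_dimension_mismatch_rejected(self, rng):
        d = rng.integers(0, 8, 50).astype(float)
        with pytest.raises(ValueError, match="covariate"):
            si.simulate_expression(d, beta=0.5, covariates=np.ones((49, 2)), seed=1)

    def test_slope_recovery_coverage(self, rng):
        """OLS CI for beta covers the generating value at ~95% of replicates."""
        d = rng.integers(0, 10, 336).astype(float) * 2
        hits = 0
        for rep in range(40):
            y = si.simulate_expression(d, beta=0.5, noise_sd=np.sqrt(0.75), seed=rep)
            res = si.association_test(si.scale_genotype(d), y, kind="linear")
            hits += abs(res.beta_hat - 0.5) < 1.96 * res.se
        assert hits >= 0.9 * 40
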