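"""Transmission phasing, panel building, window-matching imputation, LOO."""

import numpy as np
import pytest

import strimpute as si
from strimpute.containers import MISSING
from tests.conftest import parents_panel


def _phase_accuracy(sim: si.SimulatedQuads) -> float:
    """Fraction of transmission-resolved het sites phased to the truth."""
    phased = si.phase_quads_by_transmission(sim.genotypes, sim.families)
    panel, resolved = phased.panel, phased.transmission_resolved
    truth = sim.truth
    correct = total = 0
    for pi, parent in enumerate(panel.samples):
        c0, c1 = panel.haplotype_columns(parent)
        t0, t1 = truth.haplotype_columns(parent)
        het = (
            resolved[:, pi]
            & (panel.alleles[:, c0] != panel.alleles[:, c1])
            & (panel.alleles[:, c0] != MISSING)
        )
        # the reconstructed pair matches the truth pair up to column order;
        # count per-site agreement under the better of the two orderings
        straight = (panel.alleles[het, c0] == truth.alleles[het, t0]).sum()
        crossed = (panel.alleles[het, c0] == truth.alleles[het, t1]).sum()
        correct += max(straight, crossed)
        total += int(het.sum())
    return correct / total if total else 1.0


class TestTransmissionPhasing:
    def test_all_homozygous_sites_phase_trivially(self):
        cfg = si.SimulationConfig(seed=20, n_snps=5)
        panel = si.simulate_founder_haplotypes(cfg)
        sim = si.simulate_quads(panel, 3, seed=21, recomb_switch_rate=0.0)
        gt = sim.genotypes
        hom = gt.allele_a == gt.allele_b
        phased = si.phase_quads_by_transmission(gt, sim.families)
        for pi, parent in enumerate(phased.panel.samples):
            j = gt.sample_index(parent)
            c0, c1 = phased.panel.haplotype_columns(parent)
            rows = np.flatnonzero(hom[:, j])
            assert np.array_equal(phased.panel.alleles[rows, c0], gt.allele_a[rows, j])
            assert np.array_equal(phased.panel.alleles[rows, c0], phased.panel.alleles[rows, c1])
            assert phased.transmission_resolved[rows, pi].all()

    def test_error_free_quads_phase_to_truth(self, founder_panel):
        sim = si.simulate_quads(founder_panel, 30, seed=22, recomb_switch_rate=0.0)
        assert _phase_accuracy(sim) >= 0.99

    def test_mendelian_inconsistency_sets_site_missing(self, founder_panel):
        sim = si.simulate_quads(founder_panel, 3, seed=23, recomb_switch_rate=0.0)
        gt = sim.genotypes.copy()
        # corrupt child1 of family 0 at the STR with an impossible allele
        i = gt.str_index
        j = gt.sample_index(sim.families[0].child1)
        gt.allele_a[i, j] = 9999
        gt.allele_b[i, j] = 9999
        phased = si.phase_quads_by_transmission(gt, sim.families)
        assert phased.n_inconsistent_sites > 0


class TestBuildReferencePanel:
    def test_no_missing_data_panel_equals_phased_input(self, quad_sim):
        phased = si.phase_quads_by_transmission(quad_sim.genotypes, quad_sim.families)
        if (phased.panel.alleles == MISSING).any():
            pytest.skip("phasing left missing sites on this fixture")
        ref = si.build_reference_panel(phased)
        assert np.array_equal(ref.alleles, phased.panel.alleles)

    def test_parent_count_follows_quad_arithmetic(self, quad_sim):
        phased = si.phase_quads_by_transmission(quad_sim.genotypes, quad_sim.families)
        ref = si.build_reference_panel(phased)
        assert len(ref.samples) == 2 * len(quad_sim.families)
        assert ref.n_haplotypes == 4 * len(quad_sim.families)

    def test_missing_str_allele_filled_from_best_snp_match(self, reference_panel):
        panel = reference_panel.copy()
        hole = 5
        true_allele = int(panel.alleles[panel.str_index, hole])
        panel.alleles[panel.str_index, hole] = MISSING
        filled = si.build_reference_panel(panel)
        assert (filled.alleles != MISSING).all()
        # an identical-SNP haplotype exists in this pool, so the fill is exact
        snp = panel.snp_alleles
        twins = [
            h
            for h in range(panel.n_haplotypes)
            if h != hole and np.array_equal(snp[:, h], snp[:, hole])
        ]
        if twins and len({int(panel.alleles[panel.str_index, h]) for h in twins}) == 1:
            assert int(filled.alleles[filled.str_index, hole]) == int(
                panel.alleles[panel.str_index, twins[0]]
            )

    def test_panel_vcf_roundtrip_is_bit_identical(self, reference_panel, tmp_path):
        from strimpute import io

        path = tmp_path / "panel.vcf"
        io.write_panel_vcf(reference_panel, path)
        back = io.read_panel_vcf(path)
        assert np.array_equal(back.alleles, reference_panel.alleles)
        assert back.samples == reference_panel.samples
        assert back.str_locus == reference_panel.str_locus


class TestImputeStr:
    def test_identical_target_copies_str_allele_with_zero_mismatch(self, reference_panel):
        snp_mask = ~reference_panel.is_str
        target = reference_panel.alleles[snp_mask, 0]
        result = si.impute_str(target, reference_panel)
        assert result.mismatches == 0
        # every zero-mismatch haplotype shares SNPs with column 0; the copied
        # allele must be carried by at least one of them
        assert result.allele in set(reference_panel.str_alleles.tolist())

    def test_perfectly_partitioning_snp_recovers_truth(self):
        # panel: one SNP splits haplotypes into STR allele 0 vs 4
        positions = np.array([49_000, 50_000])
        is_str = np.array([False, True])
        locus = si.StrLocus("chr1", 50_000, 50_039, "AC", 40)
        H = np.array([[0, 0, 1, 1], [0, 0, 4, 4]], dtype=np.int32)
        panel = si.HaplotypePanel("chr1", positions, is_str, H, locus, ["s1", "s2"])
        assert si.impute_str(np.array([0]), panel).allele == 0
        assert si.impute_str(np.array([1]), panel).allele == 4

    def test_tie_prefers_most_frequent_then_smallest_allele(self):
        positions = np.array([49_000, 50_000])
        is_str = np.array([False, True])
        locus = si.StrLocus("chr1", 50_000, 50_039, "AC", 40)
        H = np.array([[0, 0, 0, 0], [4, 2, 4, 8]], dtype=np.int32)
        panel = si.HaplotypePanel("chr1", positions, is_str, H, locus, ["s1", "s2"])
        assert si.impute_str(np.array([0]), panel).allele == 4  # most frequent
        H2 = np.array([[0, 0, 0, 0], [8, 2, 8, 2]], dtype=np.int32)
        panel2 = si.HaplotypePanel("chr1", positions, is_str, H2, locus, ["s1", "s2"])
        assert si.impute_str(np.array([0]), panel2).allele == 2  # tie -> smaller

    def test_no_overlapping_snps_flags_missing(self, reference_panel):
        target = np.full(reference_panel.snp_positions.shape[0], MISSING, dtype=np.int32)
        result = si.impute_str(target, reference_panel)
        assert result.missing

    def test_deterministic_given_panel_and_target(self, reference_panel):
        snp_mask = ~reference_panel.is_str
        target = reference_panel.alleles[snp_mask, 3]
        a = si.impute_str(target, reference_panel)
        b = si.impute_str(target, reference_panel)
        assert a == b


class TestLeaveOneOut:
    def test_requires_at_least_three_samples(self, reference_panel):
        small = reference_panel.subset_samples(reference_panel.samples[:2])
        with pytest.raises(ValueError, match="at least 3"):
            si.leave_one_out(small)

    def test_perfect_ld_gives_unit_concordance(self):
        # two founder haplotypes with distinct SNPs and STR alleles
        cfg = si.SimulationConfig(
            seed=3, snp_mutation_rate=0.0, recomb_switch_rate=0.0, str_mutation_rate=0.0
        )
        panel = si.simulate_founder_haplotypes(cfg)
        sim = si.simulate_quads(panel, 20, seed=24, recomb_switch_rate=0.0)
        ref = parents_panel(sim)
        pairs = si.leave_one_out(ref)
        assert all(p.observed == p.imputed for p in pairs)

    def test_panel_order_independence(self, reference_panel):
        pairs = si.leave_one_out(reference_panel)
        # remove a sample, re-add it at the end, re-run
        target = reference_panel.samples[4]
        others = [s for s in reference_panel.samples if s != target]
        reordered = reference_panel.subset_samples(others + [target])
        pairs2 = si.leave_one_out(reordered)
        by_sample = {p.sample: p for p in pairs}
        for p in pairs2:
            assert by_sample[p.sample].imputed == p.imputed

    def test_concordance_improves_with_ld_strength(self, founder_panel):
        """LOO concordance rises as SNP-STR LD strengthens (decoupling grid)."""
        means = []
        for keep in (0.0, 0.5, 1.0):
            cs = []
            for r in range(10):
                cfg = si.SimulationConfig(seed=800 + r)
                pool = si.simulate_founder_haplotypes(cfg)
                pool = si.decouple_str(pool, 900 + r, fraction=1.0 - keep)
                sim = si.simulate_quads(pool, 25, seed=1000 + r)
                ref = parents_panel(sim)
                rep = si.evaluate_locus(
                    [(p.observed, p.imputed) for p in si.leave_one_out(ref)], seed=r
                )
                cs.append(rep.concordance)
            means.append(np.mean(cs))
        assert means[0] < means[1] < means[2]
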