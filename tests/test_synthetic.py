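"""Generator ground truth: the simulators must plant exactly what they claim."""

import numpy as np
import pytest

import juglandiv as jd
from juglandiv.synthetic import encode, jc_evolve, revcomp


class TestDiploidGenome:
    def test_zero_het_gives_identical_haplotypes(self):
        g = jd.simulate_diploid_genome(100_000, 0.0, seed=3)
        assert g.haplotype_a == g.haplotype_b
        assert g.het_sites == []

    def test_het_site_count_within_binomial_bounds(self):
        g = jd.simulate_diploid_genome(1_000_000, 0.01, seed=1)
        # 10000 +/- 3 * sqrt(1e6 * 0.01 * 0.99)
        assert 9700 <= len(g.het_sites) <= 10300

    def test_het_sites_strictly_increasing_and_consistent(self):
        g = jd.simulate_diploid_genome(50_000, 0.005, seed=9)
        pos = [p for p, _, _ in g.het_sites]
        assert pos == sorted(set(pos))
        for p, a, b in g.het_sites:
            assert g.haplotype_a[p] == a != b == g.haplotype_b[p]
        mism = sum(x != y for x, y in zip(g.haplotype_a, g.haplotype_b))
        assert mism == len(g.het_sites)

    def test_seed_determinism(self):
        a = jd.simulate_diploid_genome(100_000, 0.002, seed=7)
        b = jd.simulate_diploid_genome(100_000, 0.002, seed=7)
        assert a.haplotype_a == b.haplotype_a and a.haplotype_b == b.haplotype_b

    @pytest.mark.parametrize("length,het", [(500, 0.01), (10_000, 0.2), (10_000, -0.1)])
    def test_invalid_arguments_raise(self, length, het):
        with pytest.raises(ValueError):
            jd.simulate_diploid_genome(length, het)


class TestReads:
    def test_read_count_matches_depth(self):
        g = jd.simulate_diploid_genome(100_000, 0.0, seed=1)
        reads = jd.simulate_reads(g, depth=100, read_len=150, seed=2)
        expected = 100 * 100_000 / 150
        assert abs(len(reads) - expected) / expected < 0.05
        # conservation: total bases within 1% of depth * length
        assert abs(reads.total_bases - 100 * 100_000) / (100 * 100_000) < 0.01

    def test_error_free_reads_are_substrings(self):
        g = jd.simulate_diploid_genome(5_000, 0.0, seed=4)
        reads = jd.simulate_reads(g, depth=5, read_len=80, err=0.0, seed=5)
        ref = g.haplotype_a
        for seq in reads.sequences():
            assert seq in ref or revcomp(seq) in ref

    def test_fastq_is_byte_identical_across_runs(self):
        g = jd.simulate_diploid_genome(2_000, 0.01, seed=6)
        r1 = jd.simulate_reads(g, 10, 100, 0.01, seed=8)
        r2 = jd.simulate_reads(g, 10, 100, 0.01, seed=8)
        assert r1.to_fastq_string() == r2.to_fastq_string()

    def test_read_longer_than_genome_rejected(self):
        g = jd.simulate_diploid_genome(1_000, 0.0, seed=1)
        with pytest.raises(ValueError):
            jd.simulate_reads(g, 10, read_len=2_000)


class TestSpeciesSet:
    def test_zero_branch_lengths_give_identical_sequences(self):
        ss = jd.simulate_species_set("(A:0.0,B:0.0);", 5_000, seed=1)
        assert ss.sequences["A"] == ss.sequences["B"]

    def test_mismatch_matches_jukes_cantor_expectation(self):
        # path distance 0.1 -> p = (3/4)(1 - exp(-0.4/3)) ~ 0.0921
        ss = jd.simulate_species_set("(A:0.05,B:0.05);", 1_000_000, seed=2)
        a = encode(ss.sequences["A"])
        b = encode(ss.sequences["B"])
        p_obs = np.mean(a != b)
        p_exp = 0.75 * (1 - np.exp(-0.4 / 3))
        sd = np.sqrt(p_exp * (1 - p_exp) / 1_000_000)
        assert abs(p_obs - p_exp) < 3 * sd

    def test_star_tree_symmetry(self):
        ss = jd.simulate_species_set("(A:0.05,B:0.05,C:0.05);", 200_000, seed=3)
        seqs = {k: encode(v) for k, v in ss.sequences.items()}
        ps = [
            np.mean(seqs[x] != seqs[y])
            for x, y in [("A", "B"), ("A", "C"), ("B", "C")]
        ]
        p_exp = 0.75 * (1 - np.exp(-0.4 / 3))
        sd = np.sqrt(p_exp * (1 - p_exp) / 200_000)
        assert max(ps) - min(ps) < 6 * sd

    def test_true_distances_are_additive_and_symmetric(self, quartet_tree_newick):
        ss = jd.simulate_species_set(quartet_tree_newick, 2_000, seed=4)
        D = ss.true_pairwise_d
        assert D["A", "B"] == pytest.approx(0.05)
        assert D["A", "C"] == pytest.approx(0.08)
        assert np.allclose(D.data, D.data.T)
        assert np.all(np.diag(D.data) == 0)

    def test_oversized_branch_rejected(self):
        with pytest.raises(ValueError):
            jd.simulate_species_set("(A:0.8,B:0.1);", 2_000)


class TestCodonSet:
    TREE = "((A:0.05,B:0.05)n1:0.05,C:0.1)root;"

    def test_zero_omega_branch_has_no_nonsynonymous_changes(self):
        om = {"A": 0.0, "B": 1.0, "n1": 0.5, "C": 0.5}
        cs = jd.simulate_codon_set(self.TREE, om, 500, seed=1)
        assert cs.true_branch_changes["A"][0] == 0
        assert cs.true_branch_changes["B"][0] > 0

    def test_no_stop_codons_anywhere(self):
        om = {k: 1.0 for k in ("A", "B", "n1", "C")}
        cs = jd.simulate_codon_set(self.TREE, om, 300, seed=2)
        for seq in {**cs.alignment, **cs.internal}.values():
            assert len(seq) % 3 == 0
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert codons.isdisjoint({"TAA", "TAG", "TGA"})

    def test_recorded_counts_equal_applied_mutations(self):
        om = {k: 0.5 for k in ("A", "B", "n1", "C")}
        cs = jd.simulate_codon_set(self.TREE, om, 400, seed=3)
        # each branch's parent/child mismatch count is bounded by applied
        # mutations (equality unless a site mutated twice)
        parent = {"A": "n1", "B": "n1", "n1": "root", "C": "root"}
        seqs = {**cs.alignment, **cs.internal}
        for child, par in parent.items():
            diffs = sum(x != y for x, y in zip(seqs[child], seqs[par]))
            applied = sum(cs.true_branch_changes[child])
            assert diffs <= applied
            assert applied <= diffs * 2 + 10  # few multi-hits at this divergence

    def test_seed_determinism(self):
        om = {k: 0.3 for k in ("A", "B", "n1", "C")}
        a = jd.simulate_codon_set(self.TREE, om, 200, seed=4)
        b = jd.simulate_codon_set(self.TREE, om, 200, seed=4)
        assert a.alignment == b.alignment

    def test_missing_branch_omega_rejected(self):
        with pytest.raises(ValueError):
            jd.simulate_codon_set(self.TREE, {"A": 1.0}, 200)


class TestPolymorphism:
    def test_zero_theta_gives_zero_segregating_sites(self):
        ps = jd.simulate_polymorphism(10, 50_000, 0.0, seed=1)
        assert ps.S == 0 and ps.pairwise_pi() == 0.0

    def test_allele_counts_polymorphic(self):
        ps = jd.simulate_polymorphism(8, 100_000, 0.01, seed=2)
        counts = ps.genotypes.sum(axis=1)
        assert np.all((counts >= 1) & (counts <= 7))
        assert np.all(ps.depths >= 0)

    def test_seed_determinism(self):
        a = jd.simulate_polymorphism(6, 30_000, 0.005, seed=5)
        b = jd.simulate_polymorphism(6, 30_000, 0.005, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_sample_size_validated(self):
        with pytest.raises(ValueError):
            jd.simulate_polymorphism(1, 10_000, 0.01)


@pytest.fixture(scope="module")
def base():
    genome = jd.simulate_diploid_genome(10_000, 0.005, seed=20)
    gene = jd.simulate_diploid_genome(1_000, 0.0, seed=21).haplotype_a[:800]
    return genome, gene


class TestPlantGeneCopy:

    def test_allelic_copy_kmers_on_one_haplotype(self, base):
        genome, gene = base
        g2, truth = jd.plant_gene_copy(genome, gene, "allelic", 0.02, seed=22)
        specific_b = jd.copy_kmer_sets(truth.copy_a, truth.copy_b, 21)[1]
        from juglandiv.kmer import kmer_set

        assert specific_b
        assert specific_b <= kmer_set(g2.haplotype_b, 21)
        assert not (specific_b & kmer_set(g2.haplotype_a, 21))

    def test_tandem_copy_kmers_on_both_haplotypes(self, base):
        genome, gene = base
        g2, truth = jd.plant_gene_copy(genome, gene, "tandem_duplicate", 0.02, seed=23)
        from juglandiv.kmer import kmer_set

        specific_b = jd.copy_kmer_sets(truth.copy_a, truth.copy_b, 21)[1]
        assert specific_b <= kmer_set(g2.haplotype_a, 21)
        assert specific_b <= kmer_set(g2.haplotype_b, 21)

    def test_zero_divergence_gives_no_specific_kmers(self, base):
        genome, gene = base
        _, truth = jd.plant_gene_copy(genome, gene, "allelic", 0.0, seed=24)
        only_a, only_b, shared = jd.copy_kmer_sets(truth.copy_a, truth.copy_b, 21)
        assert not only_a and not only_b and shared

    def test_gene_longer_than_genome_rejected(self, base):
        genome, _ = base
        with pytest.raises(ValueError):
            jd.plant_gene_copy(genome, "A" * 20_000, "allelic")


def test_jc_evolve_composition_matches_single_step():
    """Two successive JC steps have the same marginal as one step of summed length."""
    rng1 = np.random.default_rng(1)
    base = rng1.integers(0, 4, size=500_000).astype(np.uint8)
    two = jc_evolve(jc_evolve(base, 0.05, np.random.default_rng(2)), 0.05, np.random.default_rng(3))
    p_two = np.mean(base != two)
    p_exp = 0.75 * (1 - np.exp(-0.4 / 3))
    sd = np.sqrt(p_exp * (1 - p_exp) / 500_000)
    assert abs(p_two - p_exp) < 4 * sd
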