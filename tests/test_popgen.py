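"""Diversity, relative-rate and HKA tests, Nei-Gojobori Ka/Ks, parsimony."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import juglandiv as jd
from juglandiv.phylo import read_newick
from juglandiv.popgen import ng86_pathway_counts, ng86_site_counts
from juglandiv.synthetic import _AA, _STOP_CODONS, PolymorphismSample


def _sample(genotypes, length=1000, depths=None):
    gt = np.array(genotypes, dtype=np.uint8)
    n = gt.shape[1]
    pos = np.arange(gt.shape[0], dtype=np.int64)
    d = np.full(gt.shape[0], 30, dtype=np.int64) if depths is None else np.asarray(depths)
    return PolymorphismSample(n, length, 0.0, pos, gt, d)


class TestDepthCutoffs:
    def test_uniform_depth_bracketed(self):
        cc = jd.depth_cutoffs({30: 10_000})
        assert 30 in cc

    def test_repeat_shoulder_excluded(self):
        hist = {30: 97_500, 31: 2_000, 200: 500}
        cc = jd.depth_cutoffs(hist, upper_q=0.99)
        assert 200 not in cc and 30 in cc

    def test_full_quantiles_keep_everything(self):
        hist = {5: 10, 30: 100, 90: 10}
        cc = jd.depth_cutoffs(hist, lower_q=0.0, upper_q=1.0)
        assert 5 in cc and 90 in cc

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            jd.depth_cutoffs({})


class TestNucleotideDiversity:
    def test_hand_computed_single_site(self):
        # one segregating site, p=1/2, n=4, 1000 callable sites
        summ = jd.nucleotide_diversity(_sample([[1, 1, 0, 0]]), {"all": 1000})
        assert summ.pi == pytest.approx(2 * 0.25 * (4 / 3) / 1000)
        assert summ.S == 1 and summ.allele_counts == [2]

    def test_no_segregating_sites_gives_zero(self):
        summ = jd.nucleotide_diversity(_sample(np.empty((0, 4))), {"all": 1000})
        assert summ.pi == 0.0 and summ.S == 0

    def test_matches_direct_pairwise_computation(self):
        ps = jd.simulate_polymorphism(10, 50_000, 0.01, seed=3)
        summ = jd.nucleotide_diversity(ps, {"all": ps.length})
        assert summ.pi == pytest.approx(ps.pairwise_pi(), rel=1e-9)

    def test_class_weighting_normalizes(self):
        # identical per-class pi -> overall equals the common value for any weights
        gt = [[1, 0, 1, 0]] * 4
        depths = [10, 10, 50, 50]
        classes = {
            "lo": jd.DepthCutoffs(0, 30),
            "hi": jd.DepthCutoffs(30.5, 100),
        }
        summ = jd.nucleotide_diversity(
            _sample(gt, depths=depths), {"lo": 200, "hi": 800}, classes
        )
        per_site = 2 * 0.25 * (4 / 3)
        assert summ.pi_by_class["lo"] == pytest.approx(2 * per_site / 200)
        expect = (2 * per_site / 200) * 0.2 + (2 * per_site / 800) * 0.8
        assert summ.pi == pytest.approx(expect)

    def test_site_without_class_rejected(self):
        classes = {"lo": jd.DepthCutoffs(0, 20)}
        with pytest.raises(ValueError):
            jd.nucleotide_diversity(
                _sample([[1, 0, 1, 0]], depths=[50]), {"lo": 100}, classes
            )

    def test_vcf_round_trip(self, tmp_path):
        ps = jd.simulate_polymorphism(12, 30_000, 0.008, seed=4)
        path = tmp_path / "sample.vcf"
        ps.to_vcf(path)
        summ = jd.nucleotide_diversity(str(path), {"all": ps.length})
        assert summ.S == ps.S
        assert summ.pi == pytest.approx(ps.pairwise_pi(), rel=1e-9)


class TestRelativeRate:
    def test_lineage_change_counting(self):
        assert jd.count_lineage_changes("AAAA", "AAAA", "AAAA") == (0, 0)
        assert jd.count_lineage_changes("AAAA", "AAAT", "AAAA") == (0, 1)
        # three distinct states at a site are ignored
        assert jd.count_lineage_changes("AAAC", "AAAT", "AAAG") == (0, 0)

    def test_equal_rates_give_p_one(self):
        res = jd.tajima_relative_rate(7, 7)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_ppo_worked_example(self):
        res = jd.tajima_relative_rate(46, 5)
        assert res.chi2 == pytest.approx(41**2 / 51)
        assert res.p < 1e-6

    def test_symmetry(self):
        assert jd.tajima_relative_rate(46, 5).chi2 == jd.tajima_relative_rate(5, 46).chi2

    def test_rate_asymmetry_recovered_from_simulation(self):
        rng = np.random.default_rng(5)
        from juglandiv.synthetic import decode, jc_evolve

        anc = rng.integers(0, 4, size=200_000).astype(np.uint8)
        a = jc_evolve(anc, 0.09, np.random.default_rng(6))
        b = jc_evolve(anc, 0.03, np.random.default_rng(7))
        m1, m2 = jd.count_lineage_changes(decode(a), decode(b), decode(anc))
        assert 2.4 < m1 / m2 < 3.6

    def test_undefined_without_changes(self):
        with pytest.raises(ValueError):
            jd.tajima_relative_rate(0, 0)


class TestHKA:
    def test_ppo_worked_example(self):
        res = jd.hka_test(8, 20, 53, 13)
        assert res.p < 3e-6
        # hand-computed expecteds from the margins
        assert res.expected == pytest.approx(
            np.array([[18.17, 9.83], [42.83, 23.17]]), abs=0.01
        )

    def test_proportional_table_is_null(self):
        res = jd.hka_test(10, 20, 30, 60)
        assert res.chi2 == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_small_expected_cells_warn(self):
        with pytest.warns(UserWarning):
            jd.hka_test(1, 9, 15, 40)

    def test_matches_contingency_oracle(self):
        res = jd.hka_test(8, 20, 53, 13)
        oracle = sps.chi2_contingency(np.array([[8, 20], [53, 13]]), correction=False)
        assert res.chi2 == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)

    @settings(derandomize=True, max_examples=40)
    @given(st.tuples(*[st.integers(3, 200)] * 4))
    def test_fuzzed_tables_match_oracle(self, table):
        from hypothesis import assume

        s1, s2, d1, d2 = table
        obs = np.array([[s1, s2], [d1, d2]], dtype=float)
        exp = obs.sum(axis=1, keepdims=True) @ obs.sum(axis=0, keepdims=True) / obs.sum()
        assume(np.all(exp >= 1))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = jd.hka_test(s1, s2, d1, d2)
        oracle = sps.chi2_contingency(np.array([[s1, s2], [d1, d2]]), correction=False)
        assert res.chi2 == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            jd.hka_test(0, 0, 10, 20)


class TestNeiGojobori:
    def test_ttt_site_partition(self):
        # Phe TTT: only third-position TTT->TTC is synonymous
        n, s = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_site_counts_match_brute_force_for_all_sense_codons(self):
        for codon in _AA:
            if codon in _STOP_CODONS:
                continue
            syn = 0
            for pos, b in itertools.product(range(3), "ACGT"):
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                syn += _AA[alt] == _AA[codon]
            n, s = ng86_site_counts(codon)
            assert s == pytest.approx(syn / 3)
            assert n + s == pytest.approx(3.0)

    def test_single_difference_is_the_single_path(self):
        assert ng86_pathway_counts("TTT", "TTC") == (0.0, 1.0)  # Phe->Phe
        assert ng86_pathway_counts("TTT", "TTA") == (1.0, 0.0)  # Phe->Leu

    def test_two_difference_pathway_average(self):
        # TTT (Phe) -> GTA (Val): paths via GTT (Val) and TTA (Leu)
        # path1: TTT->GTT (N) ->GTA (S); path2: TTT->TTA (N) ->GTA (N)
        nd, sd = ng86_pathway_counts("TTT", "GTA")
        assert nd == pytest.approx(1.5)
        assert sd == pytest.approx(0.5)

    def test_stop_passing_paths_excluded(self):
        # TAT (Tyr) -> TGG (Trp): the path via TAG (stop) is excluded, so
        # only TAT->TGT (Cys) ->TGG counts: two nonsynonymous steps
        nd, sd = ng86_pathway_counts("TAT", "TGG")
        assert (nd, sd) == (2.0, 0.0)

    def test_identical_sequences_zero_rates(self):
        seq = "ATGGCTAAAGGT" * 10
        r = jd.branch_ka_ks(seq, seq)
        assert r.Ka == 0.0 and r.Ks == 0.0

    def test_single_synonymous_change(self):
        # filler codons (Gly GGT, fourfold) keep the synonymous site count
        # away from saturation
        parent = "TTT" + "GGT" * 99
        child = "TTC" + "GGT" * 99
        r = jd.branch_ka_ks(parent, child)
        assert r.Na == 0.0 and r.Ns == 1.0
        assert r.A + r.Sy == pytest.approx(300.0)
        assert r.Ka == 0.0 and r.Ks > 0

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            jd.branch_ka_ks("ATGTAAGGG", "ATGTAAGGG")


class TestAncestralParsimony:
    def test_identical_leaves_propagate(self):
        t = read_newick("((A:1,B:1)ab:1,C:1)root;")
        seq = "ACGTACGTT"
        rec = jd.ancestral_parsimony({n: seq for n in "ABC"}, t)
        assert set(rec.sequences.values()) == {seq}
        assert rec.score == 0

    def test_autapomorphy_on_terminal_branch(self):
        t = read_newick("((A:1,B:1)ab:1,C:1)root;")
        rec = jd.ancestral_parsimony({"A": "AAAT", "B": "AAAA", "C": "AAAA"}, t)
        assert rec.sequences["ab"] == "AAAA"
        assert rec.sequences["root"] == "AAAA"
        assert rec.score == 1

    def test_high_recovery_at_low_divergence(self):
        tree = "((A:0.04,B:0.04)n1:0.04,(C:0.04,D:0.04)n2:0.04)root;"
        om = {k: 0.5 for k in ("A", "B", "C", "D", "n1", "n2")}
        cs = jd.simulate_codon_set(tree, om, 2_000, seed=8)
        rec = jd.ancestral_parsimony(cs.alignment, cs.tree)
        for name, true_seq in cs.internal.items():
            est = rec.sequences[name]
            frac = np.mean([x == y for x, y in zip(est, true_seq)])
            assert frac >= 0.95

    def test_leaf_mismatch_rejected(self):
        t = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            jd.ancestral_parsimony({"A": "AAAA", "B": "AAAA"}, t)


class TestLineageKaKs:
    def test_branch_with_no_changes_is_zero(self):
        tree = "((A:0.0,B:0.01)n1:0.01,C:0.01)root;"
        om = {"A": 0.5, "B": 0.5, "n1": 0.5, "C": 0.5}
        cs = jd.simulate_codon_set(tree, om, 500, seed=9)
        rates = {r.branch: r for r in jd.lineage_ka_ks(cs.alignment, cs.tree)}
        assert cs.true_branch_changes["A"] == (0, 0)
        # parsimony can misplace a change only where two branches hit one site
        assert rates["A"].Na + rates["A"].Ns <= 1

    def test_total_changes_conserved(self):
        tree = "((A:0.03,B:0.03)n1:0.03,(C:0.03,D:0.03)n2:0.03)root;"
        om = {k: 0.5 for k in ("A", "B", "C", "D", "n1", "n2")}
        cs = jd.simulate_codon_set(tree, om, 1_000, seed=10)
        rec = jd.ancestral_parsimony(cs.alignment, cs.tree)
        rates = jd.lineage_ka_ks(cs.alignment, cs.tree)
        total = sum(r.Na + r.Ns for r in rates)
        # pathway-averaged difference counts add up to the parsimony score
        assert total == pytest.approx(rec.score, rel=0.02)

    def test_omega_one_branch_recovered_with_true_ancestor(self):
        tree = "((A:0.1,B:0.1)n1:0.05,C:0.1)root;"
        om = {"A": 1.0, "B": 1.0, "n1": 1.0, "C": 1.0}
        cs = jd.simulate_codon_set(tree, om, 8_000, kappa=1.0, seed=11)
        r = jd.branch_ka_ks(cs.internal["n1"], cs.alignment["A"], "A")
        assert 0.8 <= r.omega <= 1.2
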