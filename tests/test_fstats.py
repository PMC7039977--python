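import numpy as np
import pandas as pd
import pytest

from paleostruct.fstats import (GroupFrequencies, f3, f4_or_d, fixed_outgroup,
                                fst, group_frequencies, outgroup_f3_matrix)
from paleostruct.io import MISSING, make_blocks
from paleostruct.simulate import (AdmixtureGraph, AdmixtureNode, DriftEdge,
                                  sample_group_counts, simulate_frequencies)

from conftest import make_geno, random_group_counts, variant_frame
from oracles import naive_f3, naive_truth_fst_hudson


class TestGroupFrequencies:
    def test_diploid_het(self):
        geno = make_geno([[1]], ploidy=["diploid"], groups=["P"])
        gf = group_frequencies(geno)
        k, n = gf.row("P")
        assert k[0] == 1 and n[0] == 2

    def test_one_allele_rule_for_ph(self):
        geno = make_geno([[2], [MISSING]],
                         ploidy=["pseudo_haploid"] * 2, groups=["P", "P"])
        gf = group_frequencies(geno)
        k, n = gf.row("P")
        assert k[0] == 1 and n[0] == 1

    def test_mixed_cohort_hand_counts(self):
        # 3 diploid + 2 PH samples, 3 sites, hand-enumerated (k, n)
        calls = np.array([[0, 1, 2],
                          [1, 1, MISSING],
                          [2, MISSING, 0],
                          [2, 0, MISSING],
                          [0, 2, 2]], dtype=np.int8)
        ploidy = ["diploid"] * 3 + ["pseudo_haploid"] * 2
        geno = make_geno(calls, ploidy=ploidy, groups=["P"] * 5)
        gf = group_frequencies(geno)
        k, n = gf.row("P")
        assert k.tolist() == [3 + 1 + 0, 2 + 0 + 1, 2 + 0 + 1]
        assert n.tolist() == [6 + 2, 4 + 2, 4 + 1]

    def test_unknown_label_errors(self):
        geno = make_geno([[0]])
        with pytest.raises(KeyError):
            group_frequencies(geno, groups={"nope": "P"})

    def test_exclusion_of_relatives(self):
        geno = make_geno([[2], [2]], ploidy=["pseudo_haploid"] * 2,
                         groups=["P", "P"])
        gf = group_frequencies(geno, exclude={"s1"})
        _, n = gf.row("P")
        assert n[0] == 1


class TestFixedOutgroup:
    def test_counts_and_exclusion(self):
        variants = variant_frame(3)
        variants.loc[1, "allele_ancestral"] = "G"   # ancestral = alt
        variants.loc[2, "allele_ancestral"] = "N"   # unknown -> excluded
        label, k, n = fixed_outgroup(variants, n_fixed=10 ** 6)
        assert k.tolist() == [0.0, 10 ** 6, 0.0]
        assert n.tolist() == [10 ** 6, 10 ** 6, 0.0]

    def test_correction_vanishes(self):
        # h/n = p(1-p) n/(n-1)/n is exactly 0 at p in {0, 1}
        for p in (0.0, 1.0):
            n = 10 ** 6
            assert p * (1 - p) * n / (n - 1) / n == 0.0


def freqs_with_outgroup(rng, n_snps=10):
    gf = random_group_counts(rng, 3, n_snps)
    label, k, n = fixed_outgroup(variant_frame(n_snps))
    return gf.add_group(label, k, n)


class TestF3:
    def test_fixed_outgroup_reduces_to_mean_ab(self, rng, small_blocks):
        gf = freqs_with_outgroup(rng)
        res = f3(gf, "Ancestral", "G0", "G1", small_blocks)
        a = gf.freq("G0")
        b = gf.freq("G1")
        np.testing.assert_allclose(res.estimate, np.mean(a * b), rtol=1e-12)

    def test_three_snp_worked_fixture(self):
        # hand arithmetic: per-site (c-a)(c-b) - c(1-c)/(n_c - 1)
        gf = GroupFrequencies(
            ["A", "B", "C"],
            k=np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 2.0], [1.0, 0.0, 2.0]]),
            n=np.array([[2.0, 4.0, 2.0], [4.0, 2.0, 4.0], [4.0, 4.0, 4.0]]))
        variants = variant_frame(3)
        blocks = make_blocks(variants, blen=2)   # sizes (2, 1)
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.5, 0.5, 0.5])
        c = np.array([0.25, 0.0, 0.5])
        per_site = (c - a) * (c - b) - c * (1 - c) / 3.0
        res = f3(gf, "C", "A", "B", blocks)
        np.testing.assert_allclose(res.estimate, per_site.mean(), rtol=1e-12)

    def test_admixed_target_negative(self):
        """alpha=0.5 mixture with strong post-admixture drift gives the
        classic negative admixture-f3 with |Z| > 3."""
        g = AdmixtureGraph(
            root="R",
            edges={"A": DriftEdge("R", 0.15), "B": DriftEdge("R", 0.15)},
            admixtures={"T": AdmixtureNode("A", "B", 0.5, 0.05)})
        truth = simulate_frequencies(g, 50000, seed=21)
        rows = {}
        for i, node in enumerate(["A", "B", "T"]):
            rows[node] = sample_group_counts(truth, node, 50, seed=31 + i)
        gf = GroupFrequencies(list(rows), np.array([rows[x][0] for x in rows], float),
                              np.array([rows[x][1] for x in rows], float))
        blocks = make_blocks(variant_frame(50000), 1000)
        res = f3(gf, "T", "A", "B", blocks)
        assert res.estimate < 0
        assert res.z < -3

    def test_normalized_monomorphic_outgroup_errors(self, rng, small_blocks):
        gf = freqs_with_outgroup(rng)
        with pytest.raises(ValueError, match="unnormalized"):
            f3(gf, "Ancestral", "G0", "G1", small_blocks, normalize=True)

    def test_matches_naive_oracle(self, rng, small_blocks):
        gf = random_group_counts(rng, 3, 10)
        res = f3(gf, "G2", "G0", "G1", small_blocks)
        expect, n_used = naive_f3(*gf.row("G2"), *gf.row("G0"), *gf.row("G1"))
        np.testing.assert_allclose(res.estimate, expect, rtol=1e-12)
        assert res.n_snps == n_used


class TestF4D:
    def test_same_group_is_zero(self, rng, small_blocks):
        gf = random_group_counts(rng, 3, 10)
        res = f4_or_d(gf, "G0", "G0", "G1", "G2", small_blocks)
        assert res.estimate == 0.0

    def test_symmetries(self, rng, small_blocks):
        gf = random_group_counts(rng, 4, 10)
        base = f4_or_d(gf, "G0", "G1", "G2", "G3", small_blocks)
        swapped = f4_or_d(gf, "G1", "G0", "G2", "G3", small_blocks)
        pairs = f4_or_d(gf, "G2", "G3", "G0", "G1", small_blocks)
        np.testing.assert_allclose(swapped.estimate, -base.estimate, rtol=1e-12)
        np.testing.assert_allclose(pairs.estimate, base.estimate, rtol=1e-12)

    def test_additivity_identity(self, rng, small_blocks):
        """f4(A,B;C,D) = f4(A,B;C,E) + f4(A,B;E,D) on a shared site set."""
        gf = random_group_counts(rng, 5, 10)
        full = f4_or_d(gf, "G0", "G1", "G2", "G3", small_blocks)
        left = f4_or_d(gf, "G0", "G1", "G2", "G4", small_blocks)
        right = f4_or_d(gf, "G0", "G1", "G4", "G3", small_blocks)
        np.testing.assert_allclose(full.estimate,
                                   left.estimate + right.estimate, rtol=1e-10)

    def test_null_tree_z_controlled(self):
        """((A,B),(C,D)) without gene flow: |Z| < 3 in nearly all runs."""
        ok = 0
        for rep in range(20):
            g = AdmixtureGraph(
                root="R",
                edges={"AB": DriftEdge("R", 0.03), "CD": DriftEdge("R", 0.03),
                       "A": DriftEdge("AB", 0.02), "B": DriftEdge("AB", 0.02),
                       "C": DriftEdge("CD", 0.02), "D": DriftEdge("CD", 0.02)})
            truth = simulate_frequencies(g, 50000, seed=800 + rep)
            names = ["A", "B", "C", "D"]
            counts = [sample_group_counts(truth, x, 15, seed=900 + 10 * rep + i)
                      for i, x in enumerate(names)]
            gf = GroupFrequencies(names, np.array([c[0] for c in counts], float),
                                  np.array([c[1] for c in counts], float))
            blocks = make_blocks(variant_frame(50000), 1000)
            res = f4_or_d(gf, "A", "B", "C", "D", blocks)
            ok += abs(res.z) < 3
        assert ok >= 18

    def test_d_zero_denominator_errors(self, small_blocks):
        gf = GroupFrequencies(["A", "B", "C", "D"],
                              k=np.zeros((4, 10)), n=np.full((4, 10), 4.0))
        with pytest.raises(ValueError, match="denominator"):
            f4_or_d(gf, "A", "B", "C", "D", small_blocks, mode="D")


class TestFst:
    def test_fixed_difference_is_one(self, small_blocks):
        n = np.full(10, 200.0)
        gf = GroupFrequencies(["P", "Q"],
                              k=np.vstack([n, np.zeros(10)]), n=np.vstack([n, n]))
        res = fst(gf, "P", "Q", small_blocks, estimator="hudson")
        np.testing.assert_allclose(res.estimate, 1.0, rtol=1e-9)

    def test_same_population_near_zero(self):
        g = AdmixtureGraph(root="R", edges={"P": DriftEdge("R", 0.05)})
        truth = simulate_frequencies(g, 20000, seed=51)
        k1, n1 = sample_group_counts(truth, "P", 15, seed=52, mode="diploid")
        k2, n2 = sample_group_counts(truth, "P", 15, seed=53, mode="diploid")
        gf = GroupFrequencies(["P1", "P2"], np.array([k1, k2], float),
                              np.array([n1, n2], float))
        blocks = make_blocks(variant_frame(20000), 1000)
        res = fst(gf, "P1", "P2", blocks)
        assert abs(res.estimate) < 3 * res.se

    @pytest.mark.parametrize("estimator", ["hudson", "patterson"])
    def test_drifted_pair_matches_truth_oracle(self, estimator):
        g = AdmixtureGraph(root="R", edges={"P": DriftEdge("R", 0.1),
                                            "Q": DriftEdge("R", 0.1)})
        truth = simulate_frequencies(g, 50000, seed=61)
        k1, n1 = sample_group_counts(truth, "P", 40, seed=62, mode="diploid")
        k2, n2 = sample_group_counts(truth, "Q", 40, seed=63, mode="diploid")
        gf = GroupFrequencies(["P", "Q"], np.array([k1, k2], float),
                              np.array([n1, n2], float))
        blocks = make_blocks(variant_frame(50000), 1000)
        res = fst(gf, "P", "Q", blocks, estimator=estimator)
        oracle = naive_truth_fst_hudson(truth["P"], truth["Q"])
        assert abs(res.estimate - oracle) < 4 * res.se

    def test_zero_denominator_errors(self, small_blocks):
        gf = GroupFrequencies(["P", "Q"], k=np.zeros((2, 10)),
                              n=np.full((2, 10), 6.0))
        with pytest.raises(ValueError, match="denominator"):
            fst(gf, "P", "Q", small_blocks)


class TestOutgroupF3Matrix:
    def make_panel(self, n_snps=50000, seed=71):
        # (P, Q) sisters, R outer, distant outgroup via fixed ancestral
        g = AdmixtureGraph(
            root="Root",
            edges={"PQ": DriftEdge("Root", 0.05),
                   "P": DriftEdge("PQ", 0.02), "Q": DriftEdge("PQ", 0.02),
                   "R": DriftEdge("Root", 0.02)})
        truth = simulate_frequencies(g, n_snps, seed=seed)
        names = ["P", "Q", "R"]
        counts = [sample_group_counts(truth, x, 20, seed=seed + i + 1)
                  for i, x in enumerate(names)]
        gf = GroupFrequencies(names, np.array([c[0] for c in counts], float),
                              np.array([c[1] for c in counts], float))
        label, k, n = fixed_outgroup(variant_frame(n_snps))
        return gf.add_group(label, k, n), make_blocks(variant_frame(n_snps), 1000)

    def test_symmetry_and_shared_drift_ordering(self):
        gf, blocks = self.make_panel()
        mat = outgroup_f3_matrix(gf, ["P", "Q", "R"], "Ancestral", blocks)
        pd.testing.assert_frame_equal(mat, mat.T)
        # sisters share the PQ drift; difference of f3 values is large
        res = mat.attrs["results"]
        by = {tuple(sorted(r.labels[1:])): r for r in res}
        sisters = by[("P", "Q")]
        outer = by[("P", "R")]
        z_diff = (sisters.estimate - outer.estimate) / np.hypot(sisters.se, outer.se)
        assert z_diff > 3

    def test_se_scaling_with_snp_count(self):
        gf1, blocks1 = self.make_panel(n_snps=20000, seed=81)
        gf2, blocks2 = self.make_panel(n_snps=40000, seed=82)
        r1 = f3(gf1, "Ancestral", "P", "Q", blocks1)
        r2 = f3(gf2, "Ancestral", "P", "Q", blocks2)
        # doubling SNPs roughly halves SE^2 (loose: within a factor of 2)
        ratio = r1.se ** 2 / r2.se ** 2
        assert 1.0 < ratio < 4.0
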