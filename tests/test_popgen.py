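import itertools

import numpy as np
import pandas as pd
import pytest

from snparray import (MISSING, SNPArrayError, SimConfig, allele_freqs,
                      hclust_order, ibs_distance, make_genotype_set,
                      mendel_check, pca_genotypes, simulate_genotypes, subset)

from conftest import toy_gset, toy_markers


class TestAlleleFreqs:
    @pytest.mark.parametrize("calls,freq", [
        ([0, 1, 2], 0.5),
        ([0, 0, 0], 0.0),
        ([2, 2], 1.0),
        ([1, MISSING], 0.5),
    ])
    def test_freq_examples(self, calls, freq):
        g = toy_gset(np.array([calls]))
        assert allele_freqs(g)["freq_B"].iloc[0] == pytest.approx(freq)

    def test_all_missing_marker_is_nan(self):
        g = toy_gset(np.array([[MISSING, MISSING]]))
        assert np.isnan(allele_freqs(g)["freq_B"].iloc[0])


def ibs_oracle(u, v):
    """Brute-force allele-sharing: count matched alleles out of the four
    pairwise comparisons via per-allele min-counts."""
    num = den = 0
    for a, b in zip(u, v):
        if a == MISSING or b == MISSING:
            continue
        shared = min(2 - a, 2 - b) + min(a, b)  # A-allele + B-allele matches
        num += shared / 2.0
        den += 1
    return 1.0 - num / den if den else np.nan


class TestIBSDistance:
    def test_identical_samples_distance_zero(self):
        g = toy_gset(np.tile([[0], [1], [2]], (1, 2)))
        assert ibs_distance(g).values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        g = toy_gset(np.array([[0, 2], [0, 2], [2, 0]]))
        assert ibs_distance(g).values[0, 1] == 1.0

    def test_worked_example(self):
        g = toy_gset(np.array([[0, 1], [1, 1]]))
        assert ibs_distance(g).values[0, 1] == pytest.approx(0.25)

    def test_matches_bruteforce_on_all_small_instances(self):
        """Every pair of length-3 dosage vectors over {missing,0,1,2} agrees
        with the per-locus allele-counting oracle."""
        vecs = list(itertools.product((MISSING, 0, 1, 2), repeat=3))
        for u, v in itertools.combinations_with_replacement(vecs, 2):
            g = toy_gset(np.array([u, v]).T)
            got = ibs_distance(g).values[0, 1]
            want = ibs_oracle(u, v)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_min_overlap_masks_sparse_pairs(self):
        g = toy_gset(np.array([[0, MISSING], [MISSING, 0], [1, 1]]))
        d = ibs_distance(g, min_overlap=2)
        assert np.isnan(d.values[0, 1])
        assert d.values[0, 0] == 0.0

    def test_divergence_continuity(self):
        """As the divergence parameter goes to 0 the between-population mean
        IBS distance approaches the within-population mean."""
        gaps = []
        for div in (0.8, 0.0):
            cfg = SimConfig(seed=31, divergence=div, n_pops=2, n_per_pop=8,
                            n_markers=1500)
            g, labels = simulate_genotypes(cfg)
            d = ibs_distance(g).values
            same = labels[:, None] == labels[None, :]
            off = ~np.eye(len(labels), dtype=bool)
            gaps.append(d[~same].mean() - d[same & off].mean())
        assert gaps[0] > 0.05          # diverged pops clearly separated
        assert abs(gaps[1]) < 0.01     # exchangeable at divergence 0


class TestHclustOrder:
    def test_two_tight_clusters_merge_within_first(self):
        calls = np.array([[0, 0, 2, 2]] * 6)
        g = toy_gset(calls)
        order, Z = hclust_order(ibs_distance(g))
        # first merges join the two zero-distance within-cluster pairs
        assert Z[0, 2] == 0.0 and Z[1, 2] == 0.0

    def test_three_population_leaf_contiguity(self):
        cfg = SimConfig(seed=33, n_per_pop=(10, 9, 9))
        g, labels = simulate_genotypes(cfg)
        order, _ = hclust_order(ibs_distance(g))
        ordered = pd.Series(labels, index=g.sample_ids).loc[order].to_numpy()
        runs = 1 + int((ordered[1:] != ordered[:-1]).sum())
        assert runs == 3

    def test_missing_entries_rejected(self):
        g = toy_gset(np.array([[0, MISSING, 1], [MISSING, 0, 1]]))
        with pytest.raises(SNPArrayError, match="min_overlap"):
            hclust_order(ibs_distance(g, min_overlap=2))

    def test_two_samples_single_merge(self):
        g = toy_gset(np.array([[0, 2], [1, 1]]))
        order, Z = hclust_order(ibs_distance(g))
        assert Z.shape == (1, 4) and len(order) == 2


class TestPCA:
    def test_duplicated_samples_identical_projections(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(40, 4))
        calls[:, 3] = calls[:, 0]
        g = toy_gset(calls)
        proj, _ = pca_genotypes(g, k=2)
        np.testing.assert_allclose(proj.iloc[0], proj.iloc[3], atol=1e-9)

    def test_variance_fractions_bounded_and_sorted(self):
        cfg = SimConfig(seed=35, n_per_pop=5, n_markers=300)
        g, _ = simulate_genotypes(cfg)
        _, ve = pca_genotypes(g, k=5)
        assert ve.sum() <= 1 + 1e-9
        assert (np.diff(ve) <= 1e-12).all()

    def test_marker_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(60, 6))
        markers = toy_markers(60)
        g1 = make_genotype_set(calls, markers, [f"s{j}" for j in range(6)])
        perm = rng.permutation(60)
        g2 = make_genotype_set(calls[perm], markers.iloc[perm],
                               [f"s{j}" for j in range(6)])
        p1, _ = pca_genotypes(g1, k=3)
        p2, _ = pca_genotypes(g2, k=3)
        np.testing.assert_allclose(np.abs(p1), np.abs(p2), atol=1e-8)

    def test_k_too_large_rejected(self, small_gset):
        with pytest.raises(SNPArrayError, match="out of range"):
            pca_genotypes(small_gset, k=10)

    def test_zero_variance_rejected(self):
        g = toy_gset(np.ones((5, 3), dtype=int))
        with pytest.raises(SNPArrayError, match="zero variance"):
            pca_genotypes(g, k=1)


def mendel_oracle(kid, dad, mom):
    """Gamete enumeration: which offspring dosages are reachable."""
    gametes = {0: [0], 1: [0, 1], 2: [1], MISSING: [0, 1]}
    return any(a + b == kid for a in gametes[dad] for b in gametes[mom])


def trio_gset(kid, dad, mom, chrom="1", kid_sex="female"):
    markers = toy_markers(1, chrom=chrom)
    samples = pd.DataFrame({
        "id": ["dad", "mom", "kid"],
        "sex": ["male", "female", kid_sex],
        "father": ["0", "0", "dad"],
        "mother": ["0", "0", "mom"],
    })
    return make_genotype_set(np.array([[dad, mom, kid]]), markers, samples)


class TestMendelCheck:
    def test_consistency_table_matches_gamete_enumeration(self):
        """All 4^3 (kid, dad, mom) dosage combinations, including missing
        parents, agree with brute-force gamete enumeration; markers with a
        missing offspring or two missing parents are untested."""
        for kid, dad, mom in itertools.product((MISSING, 0, 1, 2), repeat=3):
            rep = mendel_check(trio_gset(kid, dad, mom))
            assert len(rep) == 1
            row = rep.iloc[0]
            testable = kid != MISSING and (dad != MISSING or mom != MISSING)
            assert row["n_tested"] == int(testable)
            if testable:
                want_bad = not mendel_oracle(kid, dad, mom)
                assert row["n_inconsistent"] == int(want_bad)

    def test_single_parent_duo_rule(self):
        # parent 0, offspring 2: no shared allele -> inconsistent
        rep = mendel_check(trio_gset(2, 0, MISSING))
        assert rep.iloc[0]["n_inconsistent"] == 1

    def test_male_x_hemizygous_rule(self):
        # son's X comes from mom: call must be 0/2 and match a maternal allele
        for kid, mom, bad in [(0, 2, True), (2, 2, False), (1, 1, True),
                              (0, 1, False), (2, 0, True)]:
            rep = mendel_check(trio_gset(kid, 2, mom, chrom="X",
                                         kid_sex="male"))
            assert rep.iloc[0]["n_inconsistent"] == int(bad), (kid, mom)

    def test_female_x_uses_paternal_allele(self):
        # dad X is hemizygous 2 -> daughter must carry one B allele from him
        rep = mendel_check(trio_gset(0, 2, 0, chrom="X", kid_sex="female"))
        assert rep.iloc[0]["n_inconsistent"] == 1

    def test_absent_trio_member_skipped(self, small_gset):
        g = small_gset
        g.samples.loc["s0", "father"] = "ghost"
        rep = mendel_check(g)
        assert rep.empty
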