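import itertools

import numpy as np
import pandas as pd
import pytest

from pwmbench import (ClusteringParams, PFM, all_word_scores, distance_matrix,
                      jaccard_distance, random_pfm, regularize, representative,
                      score_distribution, threshold_for_pvalue, upgma_cluster,
                      word_set)
from pwmbench.cluster import SCORE_TOL, _alignment_similarity

BASES = "ACGT"


def word_to_index(word):
    v = 0
    for c in word:
        v = v * 4 + BASES.index(c)
    return v


def index_to_word(idx, L):
    out = []
    for _ in range(L):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def brute_jaccard(pfm_a, pfm_b, pvalue):
    """Oracle: enumerate every word of the aligned span at every offset and
    orientation, testing sub-word membership directly."""
    t_a, _ = threshold_for_pvalue(pfm_a, pvalue)
    t_b, _ = threshold_for_pvalue(pfm_b, pvalue)
    wa = {word_to_index(w) for w in word_set(pfm_a, t_a)}
    wb_words = word_set(pfm_b, t_b)
    la, lb = pfm_a.length, pfm_b.length
    comp = str.maketrans("ACGT", "TGCA")
    best = 0.0
    for orient in range(2):
        if orient:
            wb = {word_to_index(w.translate(comp)[::-1]) for w in wb_words}
        else:
            wb = {word_to_index(w) for w in wb_words}
        for k in range(-(lb - 1), la):
            span = max(la, k + lb) - min(0, k)
            words = np.arange(4 ** span, dtype=np.int64)
            # A occupies span columns [-min(0,k), -min(0,k)+la)
            a_off = -min(0, k)
            sub_a = (words // 4 ** (span - a_off - la)) % 4 ** la
            b_off = a_off + k
            sub_b = (words // 4 ** (span - b_off - lb)) % 4 ** lb
            in_a = np.isin(sub_a, np.fromiter(wa, dtype=np.int64))
            in_b = np.isin(sub_b, np.fromiter(wb, dtype=np.int64))
            union = (in_a | in_b).sum()
            if union:
                best = max(best, (in_a & in_b).sum() / union)
    return 1.0 - best


class TestScoreDistribution:
    def test_single_skewed_column_has_two_atoms(self):
        pfm = PFM("s", np.array([[0.97, 0.01, 0.01, 0.01]]))
        scores, masses = score_distribution(pfm)
        assert scores.size == 2
        np.testing.assert_allclose(sorted(masses), [0.25, 0.75])

    def test_uniform_pfm_is_a_point_mass(self, uniform_pfm):
        scores, masses = score_distribution(uniform_pfm(4))
        assert scores.size == 1 and masses[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_within_binning(self, seed,
                                                regular_random_pfm):
        pfm = regular_random_pfm(5, seed=seed)
        delta = 0.01
        scores, masses = score_distribution(pfm, delta)
        assert masses.sum() == pytest.approx(1.0)
        exact = np.sort(all_word_scores(pfm))
        # reconstruct the sample from the binned distribution and compare
        approx = np.sort(np.repeat(scores, np.round(masses * 4 ** 5).astype(int)))
        assert approx.size == exact.size
        assert np.max(np.abs(approx - exact)) <= 5 * delta / 2 + 1e-9


class TestThreshold:
    def test_pvalue_one_admits_every_word(self, regular_random_pfm):
        pfm = regular_random_pfm(3, seed=1)
        t, tail = threshold_for_pvalue(pfm, 1.0)
        assert len(word_set(pfm, t)) == 64
        assert tail == pytest.approx(1.0)

    def test_concentrated_motif_yields_consensus_only(self):
        pfm = regularize(PFM("aa", np.array([[1.0, 0, 0, 0]] * 2)))
        t, tail = threshold_for_pvalue(pfm, 1 / 16)
        assert word_set(pfm, t) == {"AA"}
        assert tail == pytest.approx(1 / 16)

    def test_threshold_monotone_in_pvalue(self, regular_random_pfm):
        pfm = regular_random_pfm(6, seed=2)
        ts = [threshold_for_pvalue(pfm, p)[0]
              for p in (0.001, 0.01, 0.1, 0.5, 1 - 1e-9)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_unattainable_pvalue_returns_best_word_score(self,
                                                         regular_random_pfm):
        pfm = regular_random_pfm(2, seed=3)
        t, tail = threshold_for_pvalue(pfm, 1e-9)
        assert t == pytest.approx(all_word_scores(pfm).max())
        assert tail >= 1 / 16


class TestWordSet:
    def test_uniform_pfm_at_minimum_gets_all_words(self, uniform_pfm):
        pfm = uniform_pfm(3)
        assert len(word_set(pfm, 3 * np.log(0.25))) == 64

    @pytest.mark.parametrize("seed", range(20))
    def test_branch_and_bound_equals_enumeration(self, seed,
                                                 regular_random_pfm):
        L = 4 + seed % 5
        pfm = regular_random_pfm(L, seed=seed)
        scores = all_word_scores(pfm)
        t = float(np.quantile(scores, 0.98))
        expected = {index_to_word(i, L) for i in np.where(
            scores >= t - SCORE_TOL)[0]}
        assert word_set(pfm, t) == expected

    def test_raising_threshold_never_adds_words(self, regular_random_pfm):
        pfm = regular_random_pfm(5, seed=7)
        scores = np.sort(all_word_scores(pfm))
        low, high = float(scores[100]), float(scores[900])
        assert word_set(pfm, high) <= word_set(pfm, low)

    def test_cap_exceeded_is_an_error(self, regular_random_pfm):
        pfm = regular_random_pfm(6, seed=8)
        with pytest.raises(ValueError, match="cap"):
            word_set(pfm, -1e9, cap=10)


class TestJaccard:
    def test_identical_motifs_at_distance_zero(self, regular_random_pfm):
        pfm = regular_random_pfm(5, seed=1)
        assert jaccard_distance(pfm, pfm,
                                ClusteringParams(pvalue=0.01)) == 0.0

    def test_provably_disjoint_word_sets(self):
        poly_a = regularize(PFM("pa", np.array([[1.0, 0, 0, 0]] * 4)))
        poly_c = regularize(PFM("pc", np.array([[0, 1.0, 0, 0]] * 4)))
        d = jaccard_distance(poly_a, poly_c, ClusteringParams(
            pvalue=1 / 256, both_orientations=False))
        assert d == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_alignment_enumeration(self, seed,
                                                      regular_random_pfm):
        rng = np.random.default_rng(seed)
        pa = regular_random_pfm(int(rng.integers(3, 6)), seed=2 * seed)
        pb = regular_random_pfm(int(rng.integers(3, 6)), seed=2 * seed + 1)
        pvalue = 0.02
        got = jaccard_distance(pa, pb, ClusteringParams(pvalue=pvalue))
        assert got == pytest.approx(brute_jaccard(pa, pb, pvalue), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetry_identity_and_range(self, seed, regular_random_pfm):
        pa = regular_random_pfm(4, seed=3 * seed)
        pb = regular_random_pfm(5, seed=3 * seed + 1)
        params = ClusteringParams(pvalue=0.02)
        d_ab = jaccard_distance(pa, pb, params)
        d_ba = jaccard_distance(pb, pa, params)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
        assert 0.0 <= d_ab <= 1.0
        assert jaccard_distance(pa, pa, params) == 0.0


class TestUpgma:
    def test_halt_rule_keeps_singletons(self):
        ids = ["a", "b", "c"]
        d = pd.DataFrame(0.96 * (1 - np.eye(3)), index=ids, columns=ids)
        clusters, merges = upgma_cluster(d, cutoff=0.95)
        assert clusters == [["a"], ["b"], ["c"]] and merges == []

    def test_hand_computed_three_leaf_tree(self):
        ids = ["A", "B", "C"]
        d = pd.DataFrame([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
                         index=ids, columns=ids)
        clusters, merges = upgma_cluster(d, cutoff=0.95)
        assert clusters == [["A", "B", "C"]]
        assert merges[0].distance == pytest.approx(0.2)
        assert merges[1].distance == pytest.approx(0.6)

    def test_partition_invariant_under_relabeling_permutation(self):
        rng = np.random.default_rng(5)
        n = 8
        raw = rng.uniform(0.1, 1.0, size=(n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0.0)
        ids = [f"m{i}" for i in range(n)]
        d = pd.DataFrame(sym, index=ids, columns=ids)
        base, _ = upgma_cluster(d, cutoff=0.7)
        perm = rng.permutation(n)
        d2 = d.iloc[perm, perm]
        shuffled, _ = upgma_cluster(d2, cutoff=0.7)
        assert sorted(map(tuple, base)) == sorted(map(tuple, shuffled))

    def test_cluster_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(6)
        n = 10
        raw = rng.uniform(0.05, 1.0, size=(n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0.0)
        ids = [f"m{i}" for i in range(n)]
        d = pd.DataFrame(sym, index=ids, columns=ids)
        counts = [len(upgma_cluster(d, cutoff=c)[0])
                  for c in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_merge_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(7)
        n = 7
        raw = rng.uniform(0.1, 1.0, size=(n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0.0)
        ids = [f"m{i}" for i in range(n)]
        d = pd.DataFrame(sym, index=ids, columns=ids)
        _, merges = upgma_cluster(d, cutoff=1.1)  # no halt: full tree
        ours = sorted(m.distance for m in merges)
        theirs = sorted(linkage(squareform(sym), method="average")[:, 2])
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)


class TestRepresentative:
    def make_dist(self, ids, mat):
        return pd.DataFrame(np.array(mat, dtype=float), index=ids, columns=ids)

    def test_singleton_represents_itself(self):
        d = self.make_dist(["x"], [[0.0]])
        assert representative(["x"], d) == "x"

    def test_medoid_selected(self):
        ids = ["a", "b", "c"]
        d = self.make_dist(ids, [[0, 0.1, 0.1], [0.1, 0, 0.5], [0.1, 0.5, 0]])
        assert representative(ids, d) == "a"

    def test_twin_beats_distant_members(self):
        ids = ["a", "a_twin", "far"]
        d = self.make_dist(ids, [[0, 0.0, 0.8], [0.0, 0, 0.8], [0.8, 0.8, 0]])
        assert representative(ids, d) == "a"  # tie with twin -> lexicographic
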