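"""Signed overlaps, profile clustering and preranked GSEA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txsig import (
    SignedGeneSets,
    cluster_profiles,
    gsea_batch,
    hypergeom_overlap_p,
    preranked_gsea,
    reversal_screen,
    signed_overlap_enrichment,
)


def hypergeom_p_bruteforce(universe, n_a, n_b, observed):
    """Two-tailed overlap p by explicit summation over the support."""

    def pmf(k):
        if k > n_a or k > n_b or n_b - k > universe - n_a:
            return 0.0
        return (
            math.comb(n_a, k) * math.comb(universe - n_a, n_b - k) / math.comb(universe, n_b)
        )
    support = range(0, min(n_a, n_b) + 1)
    upper = sum(pmf(k) for k in support if k >= observed)
    lower = sum(pmf(k) for k in support if k <= observed)
    return min(1.0, 2.0 * min(upper, lower))


def es_bruteforce(ranked: pd.Series, gene_set, weight=1.0):
    """Full running-sum enumeration of the weighted-KS enrichment score."""
    df = pd.DataFrame({"stat": ranked})
    df["gene"] = df.index.astype(str)
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
    hits = df["gene"].isin({str(g) for g in gene_set}).to_numpy()
    w = np.abs(df["stat"].to_numpy()) ** weight
    n, k = len(df), hits.sum()
    inc = np.where(hits, w / w[hits].sum(), -1.0 / (n - k))
    running = np.cumsum(inc)
    i_max, i_min = np.argmax(running), np.argmin(running)
    return running[i_max] if running[i_max] >= -running[i_min] else running[i_min]


def _sets(up, down, universe, label="x"):
    return SignedGeneSets(frozenset(up), frozenset(down), frozenset(universe), label)


class TestSignedOverlap:
    def test_hand_example_fold_two(self):
        universe = [f"g{i}" for i in range(100)]
        a = _sets(universe[:20], [], universe)
        b = _sets(universe[8:38], [], universe)  # overlap with a.up = 12
        rec = signed_overlap_enrichment(a, b)["concordant-up"]
        assert rec.observed == 12
        assert rec.expected == pytest.approx(6.0)
        assert rec.fold == pytest.approx(2.0)
        assert rec.p_value == pytest.approx(
            hypergeom_p_bruteforce(100, 20, 30, 12), abs=1e-12
        )

    def test_identity_gives_maximal_overlap(self):
        universe = [f"g{i}" for i in range(50)]
        a = _sets(universe[:10], universe[10:18], universe)
        rec = signed_overlap_enrichment(a, a)
        assert rec["concordant-up"].observed == 10
        assert rec["concordant-up"].fold == pytest.approx(10 / (10 * 10 / 50))
        assert rec["discordant"].observed == 0

    def test_empty_side_flagged(self):
        universe = [f"g{i}" for i in range(30)]
        a = _sets(universe[:5], [], universe)
        b = _sets([], universe[:5], universe)
        rec = signed_overlap_enrichment(a, b)["concordant-up"]
        assert rec.degenerate and rec.p_value == 1.0 and rec.fold == 0.0

    def test_restricts_to_shared_universe(self):
        a = _sets(["g1", "g2"], [], [f"g{i}" for i in range(10)])
        b = _sets(["g1"], [], [f"g{i}" for i in range(5)])
        rec = signed_overlap_enrichment(a, b)["concordant-up"]
        assert rec.observed == 1
        assert rec.expected == pytest.approx(2 * 1 / 5)

    def test_random_independent_sets_mean_fold_near_one(self):
        rng = np.random.default_rng(11)
        universe = np.array([f"g{i}" for i in range(200)])
        folds = []
        for _ in range(1000):
            a_up = rng.choice(universe, 40, replace=False)
            b_up = rng.choice(universe, 40, replace=False)
            a = _sets(a_up, [], universe)
            b = _sets(b_up, [], universe)
            folds.append(signed_overlap_enrichment(a, b)["concordant-up"].fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)

    @given(st.integers(10, 60), st.data())
    @settings(max_examples=40, derandomize=True)
    def test_p_matches_bruteforce_summation(self, universe, data):
        n_a = data.draw(st.integers(1, universe))
        n_b = data.draw(st.integers(1, universe))
        obs = data.draw(st.integers(0, min(n_a, n_b)))
        assert hypergeom_overlap_p(universe, n_a, n_b, obs) == pytest.approx(
            hypergeom_p_bruteforce(universe, n_a, n_b, obs), abs=1e-12
        )


class TestClusterProfiles:
    def test_two_identical_groups_split_perfectly(self):
        profiles = pd.DataFrame(
            [[0.0, 0.0]] * 5 + [[5.0, 5.0]] * 3,
            index=[f"g{i}" for i in range(8)],
        )
        labels = cluster_profiles(profiles, k=2)
        assert labels.nunique() == 2
        assert labels.iloc[:5].nunique() == 1 and labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] == 1  # largest cluster labeled 1

    def test_planted_three_clusters_recovered(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 10]], dtype=float)
        rows, truth = [], []
        for c, center in enumerate(centers):
            for _ in range(20):
                rows.append(center + rng.normal(0, 1.0, 3))
                truth.append(c)
        profiles = pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(60)])
        labels = cluster_profiles(profiles, k=3)
        # adjusted agreement with truth should be perfect (centers >= 5 sd apart)
        from scipy.stats import mode

        mapping = {}
        for c in range(3):
            mapping[c] = mode(labels.to_numpy()[np.array(truth) == c]).mode
        assert len(set(mapping.values())) == 3
        pred = np.array([mapping[t] for t in truth])
        assert (pred == labels.to_numpy()).all()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(rng.normal(size=(20, 4)), index=[f"g{i:02d}" for i in range(20)])
        l1 = cluster_profiles(profiles, k=4)
        l2 = cluster_profiles(profiles.iloc[rng.permutation(20)], k=4)
        pd.testing.assert_series_equal(l1.sort_index(), l2.sort_index())

    def test_duplicate_ids_error(self):
        profiles = pd.DataFrame([[0.0, 1.0]] * 3, index=["g1", "g1", "g2"])
        with pytest.raises(ValueError, match="duplicate"):
            cluster_profiles(profiles, k=2)

    def test_k_validation(self):
        profiles = pd.DataFrame([[0.0], [1.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            cluster_profiles(profiles, k=1)
        with pytest.raises(ValueError):
            cluster_profiles(profiles, k=3)


class TestPrerankedGsea:
    def test_worked_four_gene_example(self):
        ranked = pd.Series([3.0, 2.0, 1.0, 0.5], index=["g1", "g2", "g3", "g4"])
        res = preranked_gsea(ranked, {"g1", "g3"}, n_permutations=100, seed=0)
        assert res.es == pytest.approx(0.75, abs=1e-12)
        assert res.leading_edge_count == 1

    def test_single_top_gene_hits_es_one(self):
        ranked = pd.Series([5.0, 1.0, 0.9, 0.8, 0.7], index=list("abcde"))
        res = preranked_gsea(ranked, {"a"}, n_permutations=100, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge_count == 1

    def test_bottom_heavy_set_negative_es(self):
        ranked = pd.Series(np.linspace(3, -3, 50), index=[f"g{i:02d}" for i in range(50)])
        res = preranked_gsea(ranked, {f"g{i:02d}" for i in range(45, 50)},
                             n_permutations=200, seed=1)
        assert res.es < 0
        assert res.leading_edge_count <= 5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_es_matches_bruteforce_running_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        ranked = pd.Series(rng.normal(size=n), index=[f"g{i:02d}" for i in range(n)])
        k = int(rng.integers(2, n - 1))
        gene_set = set(rng.choice(ranked.index, size=k, replace=False))
        res = preranked_gsea(ranked, gene_set, n_permutations=100, seed=0)
        assert res.es == pytest.approx(es_bruteforce(ranked, gene_set), abs=1e-12)

    def test_weight_zero_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        ranked = pd.Series(rng.uniform(1, 10, 40), index=[f"g{i:02d}" for i in range(40)])
        gene_set = set(rng.choice(ranked.index, 8, replace=False))
        a = preranked_gsea(ranked, gene_set, weight_exponent=0.0, n_permutations=100, seed=5)
        b = preranked_gsea(ranked**3, gene_set, weight_exponent=0.0, n_permutations=100, seed=5)
        assert a.es == pytest.approx(b.es, abs=1e-12)
        assert a.nes == pytest.approx(b.nes, abs=1e-12)

    def test_requires_seed_and_permutations(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="seed"):
            preranked_gsea(ranked, {"a"}, n_permutations=100)
        with pytest.raises(ValueError, match="100 permutations"):
            preranked_gsea(ranked, {"a"}, n_permutations=10, seed=0)

    def test_all_zero_statistics_error(self):
        ranked = pd.Series([0.0, 0.0, 0.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="zero"):
            preranked_gsea(ranked, {"a"}, n_permutations=100, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        ranked = pd.Series(rng.normal(size=100), index=[f"g{i:03d}" for i in range(100)])
        gene_set = set(rng.choice(ranked.index, 15, replace=False))
        r1 = preranked_gsea(ranked, gene_set, n_permutations=200, seed=42)
        r2 = preranked_gsea(ranked, gene_set, n_permutations=200, seed=42)
        assert (r1.es, r1.nes, r1.fdr) == (r2.es, r2.nes, r2.fdr)


class TestReversalScreen:
    def test_constructed_reversal_is_negatively_enriched(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i:03d}" for i in range(300)]
        stats = pd.Series(rng.normal(size=300), index=genes)
        cluster = genes[:30]
        stats[cluster] = rng.normal(-4, 0.3, size=30)  # pushed to the bottom
        res = reversal_screen({"c1": set(cluster)}, stats, n_permutations=500, seed=6)["c1"]
        assert res.es < 0
        assert res.fdr < 0.01

    def test_uniformly_placed_cluster_not_significant(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:03d}" for i in range(400)]
        stats = pd.Series(rng.normal(size=400), index=genes)
        cluster = set(rng.choice(genes, 40, replace=False))
        res = reversal_screen({"c1": cluster}, stats, n_permutations=500, seed=8)["c1"]
        assert abs(res.nes) < 2.0
        assert res.fdr > 0.01

    def test_batch_reports_every_cluster(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i:03d}" for i in range(200)]
        stats = pd.Series(rng.normal(size=200), index=genes)
        sets = {f"c{j}": set(rng.choice(genes, 20, replace=False)) for j in range(3)}
        out = gsea_batch(stats, sets, n_permutations=200, seed=3)
        assert set(out) == {"c0", "c1", "c2"}
        for res in out.values():
            assert -1 <= res.es <= 1 and 0 <= res.fdr <= 1
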