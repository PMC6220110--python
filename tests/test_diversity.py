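"""UniFrac correctness (vs an independent implementation), group comparisons."""

import numpy as np
import pytest
from skbio import TreeNode

from mbherit import simdata
from mbherit.diversity import (DistanceMatrix, compare_groups, pairwise_distances,
                               relatedness_pairs, unweighted_unifrac,
                               weighted_unifrac)
from mbherit.taxa import OTUTable


def _tree(newick):
    return TreeNode.read([newick])


class TestUnweightedUnifrac:
    def test_identical_sets_zero(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert unweighted_unifrac(t, {"A", "C"}, {"A", "C"}) == 0.0

    def test_disjoint_clades_one(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert unweighted_unifrac(t, {"A", "B"}, {"C", "D"}) == 1.0

    def test_partial_overlap_hand_value(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert unweighted_unifrac(t, {"A", "C"}, {"A", "D"}) == pytest.approx(2 / 5)

    def test_depends_only_on_presence(self):
        t = _tree("((A:1,B:2):0.5,(C:1,D:3):1);")
        a = np.array([0.9, 0.0, 0.1, 0.0])
        b = np.array([0.2, 0.0, 0.8, 0.0])
        scaled = unweighted_unifrac(t, a * 5, b * 0.1)
        assert unweighted_unifrac(t, a, b) == pytest.approx(scaled)

    def test_both_empty_rejected(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            unweighted_unifrac(t, set(), set())


class TestWeightedUnifrac:
    def test_identical_abundances_zero(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        v = {"A": 0.25, "B": 0.25, "C": 0.3, "D": 0.2}
        assert weighted_unifrac(t, v, dict(v)) == 0.0

    def test_star_tree_raw_two(self):
        t = _tree("(A:1,B:1);")
        assert weighted_unifrac(t, {"A": 1.0}, {"B": 1.0}) == pytest.approx(2.0)

    def test_leaf_label_order_invariant(self):
        t = _tree("((A:1,B:2):0.5,(C:1,D:3):1);")
        a = {"A": 0.1, "B": 0.4, "C": 0.2, "D": 0.3}
        b = {"A": 0.3, "B": 0.1, "C": 0.4, "D": 0.2}
        assert weighted_unifrac(t, a, b) == pytest.approx(weighted_unifrac(t, b, a))

    def test_negative_abundance_rejected(self):
        t = _tree("(A:1,B:1);")
        with pytest.raises(ValueError):
            weighted_unifrac(t, {"A": -0.1, "B": 1.1}, {"A": 1.0})


class TestAgainstIndependentImplementation:
    """Random 8-leaf trees; scikit-bio's UniFrac is the independent oracle."""

    @pytest.mark.parametrize("metric", ["unweighted_unifrac", "weighted_unifrac"])
    def test_random_trees_match_skbio(self, metric):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(7)
        for rep in range(50):
            tree = simdata._random_bifurcating_tree(
                [f"L{k}" for k in range(8)], rng)
            counts = rng.integers(0, 20, size=(2, 8))
            counts[0, counts[0].argmax()] += 1  # ensure non-empty
            ids = ["x", "y"]
            taxa_ids = [f"L{k}" for k in range(8)]
            sk = beta_diversity(metric, counts, ids, tree=tree, taxa=taxa_ids,
                                validate=True)
            d_sk = sk[0, 1]
            rel = counts / counts.sum(axis=1, keepdims=True)
            table = OTUTable(ids, taxa_ids, rel, "relabund")
            ours = pairwise_distances(tree, table, metric).values[0, 1]
            if metric == "weighted_unifrac":
                # skbio raw weighted unifrac operates on proportions too
                assert ours == pytest.approx(d_sk, abs=1e-10)
            else:
                assert ours == pytest.approx(d_sk, abs=1e-10)

    def test_pairwise_matches_per_pair_calls(self):
        rng = np.random.default_rng(8)
        tree = simdata._random_bifurcating_tree([f"L{k}" for k in range(6)], rng)
        rel = rng.dirichlet(np.ones(6), size=5)
        table = OTUTable([f"s{i}" for i in range(5)], [f"L{k}" for k in range(6)],
                         rel, "relabund")
        D = pairwise_distances(tree, table, "weighted_unifrac")
        for i in range(5):
            for j in range(i + 1, 5):
                d = weighted_unifrac(tree,
                                     dict(zip(table.features, rel[i])),
                                     dict(zip(table.features, rel[j])))
                assert D.values[i, j] == pytest.approx(d, abs=1e-12)

    def test_missing_otu_named(self):
        tree = _tree("(A:1,B:1);")
        table = OTUTable(["s0"], ["A", "Z"], np.array([[0.5, 0.5]]), "relabund")
        with pytest.raises(KeyError, match="Z"):
            pairwise_distances(tree, table)


class TestRelatednessPairs:
    def test_constructed_pedigree_enumeration(self):
        import pandas as pd
        rows = [("s1", None, None, "castrated_M", 0, 0, 0),
                ("s2", None, None, "castrated_M", 0, 0, 0),
                ("d1", None, None, "F", 0, 0, 0),
                ("d2", None, None, "F", 0, 0, 0),
                ("k1", "s1", "d1", "F", 1, 0, 1),
                ("k2", "s1", "d1", "F", 2, 0, 1),
                ("k3", "s1", "d2", "F", 3, 0, 1),
                ("k4", "s2", "d2", "F", 1, 0, 1)]
        ped = simdata.Pedigree(pd.DataFrame(
            rows, columns=["animal_id", "sire_id", "dam_id", "sex", "pen",
                           "batch", "generation"]))
        pairs = relatedness_pairs(ped, cross_pen_only=False)
        assert set(map(frozenset, pairs["fullsib"])) == {frozenset({"k1", "k2"})}
        assert set(map(frozenset, pairs["halfsib"])) == {
            frozenset({"k1", "k3"}), frozenset({"k2", "k3"}),
            frozenset({"k3", "k4"})}
        assert len(pairs["unrelated"]) == 2  # (k1,k4), (k2,k4)

        # same-pen exclusion removes (k1,k4)
        pairs_x = relatedness_pairs(ped, cross_pen_only=True)
        assert frozenset({"k1", "k4"}) not in set(map(frozenset, pairs_x["unrelated"]))


class TestCompareGroups:
    def _dm(self, values, ids):
        return DistanceMatrix(ids, values, "weighted_unifrac")

    def test_complete_separation_minimum_p(self):
        # 8 vs 8 fully separated pair distances: the chance that a random
        # repartition reproduces the split (tying |t*| with |t|) is ~2/12870
        # per draw, so a seeded 200-draw run attains the minimum p.
        ids = [f"s{i}" for i in range(32)]
        fullsib = [(ids[2 * k], ids[2 * k + 1]) for k in range(8)]
        unrelated = [(ids[16 + 2 * k], ids[17 + 2 * k]) for k in range(8)]
        V = np.zeros((32, 32))
        for a, b in fullsib:
            V[ids.index(a), ids.index(b)] = V[ids.index(b), ids.index(a)] = 0.1
        for a, b in unrelated:
            V[ids.index(a), ids.index(b)] = V[ids.index(b), ids.index(a)] = 0.9
        res = compare_groups(self._dm(V, ids),
                             {"fullsib": fullsib, "unrelated": unrelated},
                             n_mc=200, seed=1)
        comp = [c for c in res if c.group_pair == "fullsib_vs_unrelated"][0]
        assert comp.p_mc == pytest.approx(1 / 201)

    def test_tiny_case_matches_exhaustive_repartition(self):
        from itertools import combinations
        vals = np.array([0.1, 0.5, 0.4, 0.9])
        ids = [f"s{i}" for i in range(8)]
        V = np.zeros((8, 8))
        pairs = {"fullsib": [(ids[0], ids[1]), (ids[2], ids[3])],
                 "unrelated": [(ids[4], ids[5]), (ids[6], ids[7])]}
        flat = pairs["fullsib"] + pairs["unrelated"]
        for (a, b), v in zip(flat, vals):
            V[ids.index(a), ids.index(b)] = V[ids.index(b), ids.index(a)] = v

        from mbherit.diversity import _two_sample_t
        t_obs = _two_sample_t(vals[:2], vals[2:])
        exceed = 0
        combos = list(combinations(range(4), 2))
        for pick in combos:
            rest = [i for i in range(4) if i not in pick]
            t_star = _two_sample_t(vals[list(pick)], vals[rest])
            if abs(t_star) >= abs(t_obs) - 1e-15:
                exceed += 1
        p_exact = exceed / len(combos)

        res = compare_groups(self._dm(V, ids), pairs, n_mc=4000, seed=2)
        comp = [c for c in res if c.group_pair == "fullsib_vs_unrelated"][0]
        assert abs(comp.p_mc - p_exact) < 0.05

    def test_empty_group_rejected(self):
        ids = ["a", "b", "c", "d"]
        V = np.zeros((4, 4))
        with pytest.raises(ValueError):
            compare_groups(self._dm(V, ids),
                           {"fullsib": [("a", "b")], "unrelated": [("c", "d")]},
                           n_mc=10, seed=0)
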