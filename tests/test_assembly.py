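import networkx as nx
import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from protcomm import (
    CommunityAssembly,
    beta_mntd,
    beta_nti,
    partition_processes,
    patristic_distances,
    raup_crick,
    within_group_pairs,
)
from protcomm.simulate import simulate_tree

TREE = "((A:1,B:1):1,C:2);"


def brute_force_beta_mntd(counts: pd.DataFrame, pdm: pd.DataFrame, weighted=True):
    """Literal double-loop betaMNTD, the independent oracle."""
    ids = list(counts.index)
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in ids:
        for b in ids:
            if a == b:
                continue
            ta = [t for t in counts.columns if counts.loc[a, t] > 0]
            tb = [t for t in counts.columns if counts.loc[b, t] > 0]
            if weighted:
                fa = counts.loc[a, ta] / counts.loc[a, ta].sum()
                fb = counts.loc[b, tb] / counts.loc[b, tb].sum()
            else:
                fa = pd.Series(1 / len(ta), index=ta)
                fb = pd.Series(1 / len(tb), index=tb)
            s1 = sum(fa[i] * min(pdm.loc[i, j] for j in tb) for i in ta)
            s2 = sum(fb[j] * min(pdm.loc[j, i] for i in ta) for j in tb)
            out.loc[a, b] = 0.5 * (s1 + s2)
    return out


class TestPatristic:
    def test_hand_worked_example(self):
        pdm = patristic_distances(TreeNode.read([TREE]))
        assert pdm.loc["A", "B"] == pytest.approx(2.0)
        assert pdm.loc["A", "C"] == pytest.approx(4.0)
        assert pdm.loc["B", "C"] == pytest.approx(4.0)
        assert np.allclose(np.diag(pdm.to_numpy()), 0)

    def test_matches_graph_shortest_path_oracle(self):
        tree = simulate_tree(20, seed=9)
        pdm = patristic_distances(tree)
        g = nx.Graph()
        for node in tree.traverse(include_self=False):
            g.add_edge(id(node.parent), id(node), weight=node.length)
        tips = {t.name: id(t) for t in tree.tips()}
        for a in pdm.index:
            lengths = nx.single_source_dijkstra_path_length(g, tips[a])
            for b in pdm.columns:
                assert pdm.loc[a, b] == pytest.approx(lengths[tips[b]], abs=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            patristic_distances(TreeNode.read(["((A:1,A:1):1,C:2);"]))


class TestBetaMNTD:
    def test_hand_worked_examples(self):
        pdm = patristic_distances(TreeNode.read([TREE]))
        counts = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [1, 0, 1]],
            index=["onlyA", "onlyB", "AC"],
            columns=list("ABC"),
        )
        bm = beta_mntd(counts, pdm)
        # {A} vs {B}: 1/2 (2 + 2) = 2
        assert bm["onlyA", "onlyB"] == pytest.approx(2.0)
        # {A:0.5, C:0.5} vs {B:1}: 1/2 (0.5*2 + 0.5*4 + 1*2) = 2.5
        assert bm["AC", "onlyB"] == pytest.approx(2.5)

    def test_identical_communities_have_zero_distance(self):
        pdm = patristic_distances(TreeNode.read([TREE]))
        counts = pd.DataFrame([[2, 3, 1], [2, 3, 1]], index=["x", "y"], columns=list("ABC"))
        assert beta_mntd(counts, pdm)["x", "y"] == pytest.approx(0.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(4)
        tree = simulate_tree(12, seed=2)
        pdm = patristic_distances(tree)
        counts = pd.DataFrame(
            rng.integers(0, 9, size=(6, 12)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"ASV_{i+1}" for i in range(12)],
        )
        counts.iloc[:, 0] += 1  # no empty samples
        ours = beta_mntd(counts, pdm, weighted=weighted)
        oracle = brute_force_beta_mntd(counts, pdm, weighted=weighted)
        assert np.allclose(ours.data, oracle.to_numpy(), atol=1e-12)

    def test_unweighted_zero_iff_identical_taxon_sets(self):
        pdm = patristic_distances(TreeNode.read([TREE]))
        counts = pd.DataFrame(
            [[5, 1, 0], [1, 9, 0], [1, 0, 1]], index=["x", "y", "z"], columns=list("ABC")
        )
        bm = beta_mntd(counts, pdm, weighted=False)
        assert bm["x", "y"] == pytest.approx(0.0)  # same taxon set {A,B}
        assert bm["x", "z"] > 0

    def test_empty_sample_rejected(self):
        pdm = patristic_distances(TreeNode.read([TREE]))
        counts = pd.DataFrame([[1, 0, 0], [0, 0, 0]], index=["x", "empty"], columns=list("ABC"))
        with pytest.raises(ValueError, match="empty"):
            beta_mntd(counts, pdm)


class TestBetaNTI:
    def test_star_tree_is_undefined(self):
        # all tips equidistant: shuffling changes nothing, null sd = 0
        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        pdm = patristic_distances(star)
        counts = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["x", "y"], columns=list("ABCD")
        )
        res = beta_nti(counts, pdm, n_null=49, seed=0)
        assert np.isnan(res.beta_nti.loc["x", "y"])
        assert res.null_sd.loc["x", "y"] == pytest.approx(0.0)

    def test_invariant_under_tip_relabeling(self):
        rng = np.random.default_rng(0)
        tree = simulate_tree(10, seed=3)
        pdm = patristic_distances(tree)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(5, 10)),
            index=[f"s{i}" for i in range(5)],
            columns=[f"ASV_{i+1}" for i in range(10)],
        )
        counts.iloc[:, 0] += 1
        res1 = beta_nti(counts, pdm, n_null=99, seed=7)
        relabel = {f"ASV_{i+1}": f"X{i}" for i in range(10)}
        pdm2 = pdm.rename(index=relabel, columns=relabel)
        counts2 = counts.rename(columns=relabel)
        res2 = beta_nti(counts2, pdm2, n_null=99, seed=7)
        assert np.allclose(
            res1.beta_nti.to_numpy(), res2.beta_nti.to_numpy(), equal_nan=True
        )

    def test_seed_reproducibility_and_nnull_validation(self):
        tree = simulate_tree(8, seed=1)
        pdm = patristic_distances(tree)
        counts = pd.DataFrame(
            np.random.default_rng(2).integers(1, 9, size=(4, 8)),
            index=list("wxyz"),
            columns=[f"ASV_{i+1}" for i in range(8)],
        )
        a = beta_nti(counts, pdm, n_null=49, seed=3)
        b = beta_nti(counts, pdm, n_null=49, seed=3)
        assert np.allclose(a.beta_nti.to_numpy(), b.beta_nti.to_numpy(), equal_nan=True)
        with pytest.raises(ValueError):
            beta_nti(counts, pdm, n_null=0)


class TestRaupCrick:
    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.multinomial(500, rng.dirichlet(np.ones(15)), size=5),
            index=[f"s{i}" for i in range(5)],
            columns=[f"t{i}" for i in range(15)],
        )
        a = raup_crick(counts, n_null=99, seed=4)
        b = raup_crick(counts, n_null=99, seed=4)
        vals = a.to_numpy()[np.triu_indices(5, 1)]
        assert ((vals >= -1) & (vals <= 1)).all()
        assert np.allclose(a.to_numpy(), b.to_numpy(), equal_nan=True)

    def test_identical_samples_approach_minus_one(self):
        rng = np.random.default_rng(1)
        base = rng.multinomial(1000, rng.dirichlet(np.ones(20)), size=4)
        counts = pd.DataFrame(
            np.vstack([base, base[0]]),
            index=[f"s{i}" for i in range(5)],
            columns=[f"t{i}" for i in range(20)],
        )
        rc = raup_crick(counts, n_null=199, seed=2)
        assert rc.loc["s0", "s4"] <= -0.95

    def test_maximally_dissimilar_pair_reaches_plus_one(self):
        # disjoint 6+6 taxa: observed BC is exactly 1, while a null draw
        # is disjoint only if it reproduces the complementary split
        # (probability 1/C(12,6) per draw), which this seeded run never does
        counts = pd.DataFrame(
            [[10] * 6 + [0] * 6, [0] * 6 + [10] * 6],
            index=["a", "b"],
            columns=[f"t{i}" for i in range(12)],
        )
        rc = raup_crick(counts, n_null=99, seed=0)
        assert rc.loc["a", "b"] == pytest.approx(1.0)

    def test_neutral_stochastic_pairs_classified_as_drift(self, neutral_dataset):
        """Under neutral assembly, most phylogenetically stochastic pairs
        show Bray-Curtis turnover inside the null envelope (drift)."""
        sub = neutral_dataset.subset_samples(
            [s for s in neutral_dataset.sample_ids if s.endswith(("_1", "_2"))]
        )
        nti = beta_nti(
            sub.counts, patristic_distances(sub.tree), n_null=199, seed=0
        )
        rc = raup_crick(sub.counts, n_null=199, seed=1)
        b = nti.beta_nti.to_numpy()[np.triu_indices(len(sub.sample_ids), 1)]
        r = rc.to_numpy()[np.triu_indices(len(sub.sample_ids), 1)]
        stoch = (~np.isnan(b)) & (np.abs(b) <= 2)
        assert np.mean(np.abs(r[stoch]) <= 0.95) >= 0.6

    def test_single_sample_rejected(self):
        counts = pd.DataFrame([[1, 2]], index=["only"], columns=["t0", "t1"])
        with pytest.raises(ValueError):
            raup_crick(counts, n_null=9)


class TestPartition:
    def test_threshold_forced_classification(self):
        ids = ["s1", "s2", "s3"]
        bnti = pd.DataFrame(np.nan, index=ids, columns=ids)
        rc = pd.DataFrame(np.nan, index=ids, columns=ids)
        bnti.loc["s1", "s2"] = bnti.loc["s2", "s1"] = 2.5
        bnti.loc["s1", "s3"] = bnti.loc["s3", "s1"] = -3.0
        bnti.loc["s2", "s3"] = bnti.loc["s3", "s2"] = 1.0
        rc.loc["s2", "s3"] = rc.loc["s3", "s2"] = 0.99
        rc.loc["s1", "s2"] = rc.loc["s2", "s1"] = 0.0
        rc.loc["s1", "s3"] = rc.loc["s3", "s1"] = 0.0
        out = partition_processes(
            bnti, rc, {"all": [("s1", "s2"), ("s1", "s3"), ("s2", "s3")]}
        )
        row = out.loc["all"]
        assert row["heterogeneous_selection"] == pytest.approx(1 / 3)
        assert row["homogeneous_selection"] == pytest.approx(1 / 3)
        assert row["dispersal_limitation"] == pytest.approx(1 / 3)

    def test_all_drift(self):
        ids = ["a", "b"]
        zero = pd.DataFrame([[np.nan, 0.0], [0.0, np.nan]], index=ids, columns=ids)
        out = partition_processes(zero, zero, {"g": [("a", "b")]})
        assert out.loc["g", "drift"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_and_undefined_counted(self):
        ids = ["a", "b", "c"]
        bnti = pd.DataFrame(0.0, index=ids, columns=ids)
        bnti.loc["a", "b"] = bnti.loc["b", "a"] = np.nan  # undefined pair
        rc = pd.DataFrame(0.0, index=ids, columns=ids)
        out = partition_processes(
            bnti, rc, {"g": [("a", "b"), ("a", "c"), ("b", "c")]}
        )
        procs = [
            "heterogeneous_selection",
            "homogeneous_selection",
            "dispersal_limitation",
            "homogenizing_dispersal",
            "drift",
        ]
        assert out.loc["g", procs].sum() == pytest.approx(1.0, abs=1e-9)
        assert out.loc["g", "n_undefined"] == 1

    def test_empty_pair_set_named(self):
        zero = pd.DataFrame([[np.nan]], index=["a"], columns=["a"])
        with pytest.raises(ValueError, match="lonely"):
            partition_processes(zero, zero, {"lonely": []})


class TestAssemblyModel:
    def test_fit_on_synthetic_selection_data(self, selection_dataset):
        sub = selection_dataset.subset_samples(
            [s for s in selection_dataset.sample_ids if "flowering" in s][:12]
        )
        res = CommunityAssembly(sub).fit(n_null=99, seed=0, groupby="cell")
        procs = [
            "heterogeneous_selection",
            "homogeneous_selection",
            "dispersal_limitation",
            "homogenizing_dispersal",
            "drift",
        ]
        assert np.allclose(res.fractions[procs].sum(axis=1), 1.0, atol=1e-9)
        assert set(res.classification["process"]) <= set(procs) | {"undefined"}
        assert len(res.classification) == 12 * 11 // 2
        assert "selection fraction" in res.summary()

    def test_within_group_pairs_combinatorics(self):
        labels = pd.Series(["a", "a", "a", "b", "b"], index=list("vwxyz"))
        pairs = within_group_pairs(labels)
        assert len(pairs["a"]) == 3 and len(pairs["b"]) == 1
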