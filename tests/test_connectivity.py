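from itertools import product

import numpy as np
import pandas as pd
import pytest

from neckcompare import (
    build_adjacency,
    cluster_by_rank,
    effective_connectivity,
    extract_circuit,
    information_flow_rank,
    input_fraction,
    rank_by_type,
    type_average,
)


def syn_table(edges):
    """Synapse table with one row per synapse from (pre, post, count) triples."""
    rows = []
    for pre, post, n in edges:
        rows += [(pre, post, 0.0, 0.0, 0.0)] * n
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "x", "y", "z"])


class TestAdjacency:
    def test_counts_rows_per_pair(self):
        adj = build_adjacency(syn_table([("A", "B", 3), ("A", "C", 1)]))
        assert adj.loc["A", "B"] == 3
        assert adj.loc["A", "C"] == 1
        assert adj.to_numpy().sum() == 4

    def test_empty_table(self):
        adj = build_adjacency(syn_table([]))
        assert adj.size == 0

    def test_restriction_drops_outside_edges(self):
        adj = build_adjacency(syn_table([("A", "B", 3), ("A", "C", 1)]), {"A", "B"})
        assert adj.to_numpy().sum() == 3

    def test_weight_conserved_under_type_regrouping(self):
        rng = np.random.default_rng(0)
        ids = [f"n{i}" for i in range(12)]
        edges = [(ids[i], ids[j], int(rng.integers(0, 5)))
                 for i, j in product(range(12), repeat=2) if i != j]
        adj = build_adjacency(syn_table(edges))
        tmap = {n: f"t{i % 4}" for i, n in enumerate(adj.index)}
        pre_types = pd.Series([tmap[n] for n in adj.index], index=adj.index)
        post_types = pd.Series([tmap[n] for n in adj.columns], index=adj.columns)
        regrouped = adj.groupby(pre_types).sum().T.groupby(post_types).sum().T
        assert regrouped.to_numpy().sum() == adj.to_numpy().sum()


class TestInputFraction:
    def test_percent_shares(self):
        adj = build_adjacency(syn_table([("A", "C", 3), ("B", "C", 1)]))
        pct = input_fraction(adj, percent=True)
        assert pct.loc["A", "C"] == pytest.approx(75.0)
        assert pct.loc["B", "C"] == pytest.approx(25.0)

    def test_columns_sum_to_one_or_zero(self):
        rng = np.random.default_rng(1)
        edges = [(f"n{i}", f"n{j}", int(rng.integers(0, 4)))
                 for i, j in product(range(8), repeat=2)]
        frac = input_fraction(build_adjacency(syn_table(edges)))
        sums = frac.to_numpy().sum(axis=0)
        for s in sums:
            assert s == pytest.approx(1.0, abs=1e-12) or s == 0.0

    def test_autapses_excluded_from_denominator(self):
        adj = build_adjacency(syn_table([("A", "A", 10), ("B", "A", 10)]))
        frac = input_fraction(adj)
        assert frac.loc["B", "A"] == pytest.approx(1.0)
        assert frac.loc["A", "A"] == 0.0


class TestTypeAverage:
    def test_hand_example(self):
        """a1,a2 -> b1 at 10% each and -> b2 at 0/20%: type entry is 20%."""
        m = pd.DataFrame(
            [[10.0, 0.0], [10.0, 20.0]], index=["a1", "a2"], columns=["b1", "b2"]
        )
        out = type_average(m, {"a1": "S", "a2": "S", "b1": "T", "b2": "T"})
        assert out.loc["S", "T"] == pytest.approx(20.0)

    def test_singleton_types_identity(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=["a", "b"])
        out = type_average(m, {"a": "a", "b": "b"})
        pd.testing.assert_frame_equal(out, m, check_names=False)

    def test_unmapped_neuron_rejected(self):
        m = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            type_average(m, {})


def hand_circuit():
    """12-node adjacency exercising every extraction rule.

    Seed S outputs: A 40, B 8, C 11, F 10, X 752 (total 821).
      A: weight > 10 and 4.87% output      -> stage 1
      B: 8 <= 10 fails weight              -> out
      C: weight 11 > 10, 1.34% > 0.5%      -> stage 1
      F: weight 10 is not > 10             -> out (strict boundary)
      X: 752, 91.6%                        -> stage 1
    Upstream: P -> S 12 (P's sole output, 100%)        -> stage 1
              Q -> S 11 but 0.27% of Q's output        -> out
    Augmentation (> 5 onto/from stage 1): M1 (MN) from A at 6 -> added;
      M2 (MN) touches only B -> not added; S1 (SN) from A at 5 -> not added.
    X -> M1 600 makes A -> M1 a 0.99% input edge (pruned at 1% display).
    """
    edges = [
        ("S", "A", 40), ("S", "B", 8), ("S", "C", 11), ("S", "F", 10), ("S", "X", 752),
        ("P", "S", 12),
        ("Q", "S", 11), ("Q", "QS", 4000),
        ("A", "M1", 6), ("X", "M1", 600),
        ("B", "M2", 7),
        ("A", "S1", 5),
    ]
    classes = {"M1": "MN", "M2": "MN", "S1": "SN"}
    return build_adjacency(syn_table(edges)), classes


class TestExtractCircuit:
    def test_hand_derived_node_and_edge_sets(self):
        adj, classes = hand_circuit()
        g = extract_circuit(adj, {"S"}, classes=classes)
        assert set(g.nodes) == {"S", "A", "C", "X", "P", "M1"}
        assert set(g.edges) == {
            ("S", "A"), ("S", "C"), ("S", "X"), ("P", "S"), ("A", "M1"), ("X", "M1")
        }
        assert g.edges["A", "M1"]["input_percent"] == pytest.approx(100 * 6 / 606)

    def test_display_pruning_at_one_percent(self):
        adj, classes = hand_circuit()
        g = extract_circuit(adj, {"S"}, classes=classes, display_input_min=1.0)
        assert ("A", "M1") not in g.edges  # 0.99% pruned
        assert ("X", "M1") in g.edges  # 99.01% kept

    def test_example_thresholds_both_required(self):
        """Targets (12, 3%), (8, 5%), (11, 0.3%): only the first retained."""
        edges = [("S", "A", 12), ("S", "B", 8), ("S", "C", 11),
                 ("S", "X", 369), ("C2", "C", 1)]
        # S total out = 400: A 3%, B 2%, C 2.75% -- make C fail on share
        edges = [("S", "A", 12), ("S", "B", 8), ("S", "C", 11), ("S", "X", 3669)]
        adj = build_adjacency(syn_table(edges))
        g = extract_circuit(adj, {"S"}, out_frac_min=0.31)
        # total 3700: A 0.32% > 0.31 and 12 > 10 kept; B weight fails; C 0.297% fails
        assert set(g.nodes) == {"S", "A", "X"}

    def test_empty_seed_rejected(self):
        adj, _ = hand_circuit()
        with pytest.raises(ValueError):
            extract_circuit(adj, set())

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_under_threshold_increase(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"n{i}" for i in range(10)]
        edges = [(a, b, int(rng.integers(0, 30)))
                 for a in ids for b in ids if a != b and rng.random() < 0.4]
        if not edges:
            pytest.skip("empty graph")
        adj = build_adjacency(syn_table(edges))
        classes = {n: ("MN" if int(n[1:]) % 3 == 0 else "IN") for n in adj.index}
        seeds = {str(adj.index[0])}
        base = extract_circuit(adj, seeds, classes=classes,
                               weight_min=5, out_frac_min=0.5, augment_weight_min=2)
        for kw in (
            {"weight_min": 8}, {"out_frac_min": 2.0}, {"augment_weight_min": 4},
            {"display_input_min": 2.0},
        ):
            args = dict(weight_min=5, out_frac_min=0.5, augment_weight_min=2)
            args.update(kw)
            tighter = extract_circuit(adj, seeds, classes=classes, **args)
            assert set(tighter.nodes) <= set(base.nodes)
            assert set(tighter.edges) <= set(base.edges)


def brute_force_influence(frac, src, dst, hops):
    """Oracle: enumerate all directed paths of exactly `hops` edges."""
    nodes = list(frac.index)
    total = 0.0
    def walk(node, depth, prod):
        nonlocal total
        if depth == hops:
            if node == dst:
                total += prod
            return
        for nxt in nodes:
            f = frac.loc[node, nxt]
            if f > 0:
                walk(nxt, depth + 1, prod * f)
    walk(src, 0, 1.0)
    return total


class TestEffectiveConnectivity:
    def test_two_hop_chain_product(self):
        frac = pd.DataFrame(
            [[0, 0.5, 0], [0, 0, 0.4], [0, 0, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        out = effective_connectivity(frac, ["A"], ["C"], max_hops=2)
        hop2 = out[(out.hop == 2)].iloc[0]
        assert hop2["influence"] == pytest.approx(0.2)

    def test_hop_one_equals_fraction_entry(self):
        rng = np.random.default_rng(2)
        ids = list("ABCDE")
        frac = pd.DataFrame(rng.uniform(0, 0.3, (5, 5)), index=ids, columns=ids)
        out = effective_connectivity(frac, ids, ids, max_hops=1)
        for _, r in out[out.hop == 1].iterrows():
            assert r["influence"] == pytest.approx(frac.loc[r["source"], r["target"]])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ids = [f"n{i}" for i in range(n)]
        frac = pd.DataFrame(
            np.where(rng.random((n, n)) < 0.4, rng.uniform(0, 0.5, (n, n)), 0.0),
            index=ids, columns=ids,
        )
        out = effective_connectivity(frac, ids[:2], ids[-2:], max_hops=4)
        for _, r in out[out.hop != "cumulative"].iterrows():
            expect = brute_force_influence(frac, r["source"], r["target"], int(r["hop"]))
            assert r["influence"] == pytest.approx(expect, abs=1e-12)


class TestInformationFlow:
    def test_feedforward_chain_ranks(self):
        adj = build_adjacency(syn_table([("seed", "X1", 10), ("X1", "X2", 10)]))
        ranks = information_flow_rank(adj, {"m": {"seed"}})
        assert ranks.loc["X1", "m"] == 1
        assert ranks.loc["X2", "m"] == 2

    def test_deterministic_equals_bfs_on_single_input_graphs(self):
        """Every non-seed neuron draws all input from one predecessor."""
        rng = np.random.default_rng(3)
        edges = []
        parents = {0: None}
        for i in range(1, 15):
            p = int(rng.integers(0, i))
            parents[i] = p
            edges.append((f"n{p}", f"n{i}", int(rng.integers(5, 20))))
        adj = build_adjacency(syn_table(edges))
        ranks = information_flow_rank(adj, {"m": {"n0"}})
        depth = {0: 0}
        for i in range(1, 15):
            depth[i] = depth[parents[i]] + 1
        for i in range(1, 15):
            assert ranks.loc[f"n{i}", "m"] == depth[i]

    def test_stochastic_probability_one_at_theta_fraction(self):
        """30% input from seeds at theta 0.3: visit probability min(1, f/theta)=1,
        so the rank is 1 in every run."""
        adj = build_adjacency(
            syn_table([("seed", "T", 30), ("other", "T", 70), ("x", "other", 1)])
        )
        ranks = information_flow_rank(
            adj, {"m": {"seed"}}, mode="stochastic", n_runs=50, rng_seed=0
        )
        assert ranks.loc["T", "m"] == pytest.approx(1.0, abs=0)

    def test_disconnected_component_unreached(self):
        adj = build_adjacency(syn_table([("seed", "A", 5), ("B", "C", 5)]))
        ranks = information_flow_rank(adj, {"m": {"seed"}})
        assert np.isnan(ranks.loc["C", "m"])

    def test_stochastic_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        edges = [(f"n{i}", f"n{j}", int(rng.integers(1, 10)))
                 for i in range(8) for j in range(8) if i != j and rng.random() < 0.3]
        adj = build_adjacency(syn_table(edges))
        seeds = {"m": {str(adj.index[0])}}
        a = information_flow_rank(adj, seeds, mode="stochastic", n_runs=20, rng_seed=9)
        b = information_flow_rank(adj, seeds, mode="stochastic", n_runs=20, rng_seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_theta_out_of_range_rejected(self):
        adj = build_adjacency(syn_table([("a", "b", 1)]))
        with pytest.raises(ValueError):
            information_flow_rank(adj, {"m": {"a"}}, theta=0.0)

    def test_excluded_rows_dropped(self):
        adj = build_adjacency(syn_table([("seed", "A", 5), ("A", "B", 5)]))
        ranks = information_flow_rank(adj, {"m": {"seed"}}, exclude={"B"})
        assert "B" not in ranks.index
        assert "seed" not in ranks.index


class TestRankByType:
    def test_mean_and_unreached_exclusion(self):
        ranks = pd.DataFrame({"m": [2.0, 4.0, np.nan, 5.0]},
                             index=["a1", "a2", "b1", "b2"])
        out = rank_by_type(ranks, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert out.loc["A", "m"] == pytest.approx(3.0)
        assert out.loc["B", "m"] == pytest.approx(5.0)

    def test_all_unreached_type_stays_unreached(self):
        ranks = pd.DataFrame({"m": [np.nan]}, index=["a"])
        out = rank_by_type(ranks, {"a": "A"})
        assert np.isnan(out.loc["A", "m"])


class TestClusterByRank:
    def planted_blocks(self, rng, n_per=6, sep=10.0, noise=1.0):
        centers = np.array([[1.0, 1, 1, 1], [1 + sep, 1, 1, 1], [1, 1 + sep, 1 + sep, 1]])
        rows, labels = [], []
        for b, c in enumerate(centers):
            for i in range(n_per):
                rows.append(c + rng.normal(0, noise / 10, 4))
                labels.append(b)
        idx = [f"t{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx), np.array(labels)

    def test_identical_vectors_share_cluster(self):
        ranks = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                             index=["a", "b", "c"])
        labels, _ = cluster_by_rank(ranks, cut_height=0.5)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_planted_blocks_recovered_exactly(self):
        """Separation 10x noise: flat clusters equal the planted partition."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        ranks, truth = self.planted_blocks(rng)
        labels, _ = cluster_by_rank(ranks, cut_height=5.0)
        assert labels.nunique() == 3
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_cut_above_root_single_cluster(self):
        rng = np.random.default_rng(6)
        ranks, _ = self.planted_blocks(rng)
        _, Z = cluster_by_rank(ranks, cut_height=1.0)
        above_root = float(Z[-1, 2]) + 1.0
        labels, _ = cluster_by_rank(ranks, cut_height=above_root)
        assert labels.nunique() == 1

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_by_rank(pd.DataFrame([[1.0]], index=["a"]))
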