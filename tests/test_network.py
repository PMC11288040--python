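"""Similarity-network topology and robustness: oracles and invariants."""

import networkx as nx
import numpy as np
import pytest

import rosmine as rm
from rosmine.network import NetworkConfig, attack_auc
from rosmine.screen import ScreenHit


def make_hit(q, s, evalue=1e-10, bitscore=100.0):
    return ScreenHit(q, s, 50.0, 100, 0, 0, 1, 100, 1, 100, evalue, bitscore)


def kshell_bruteforce(g: nx.Graph) -> dict:
    """Independent peeling oracle: for each k, repeatedly delete nodes of
    degree < k; nodes surviving in the k-core get shell >= k."""
    shell = {v: 0 for v in g.nodes()}
    k = 0
    work = g.copy()
    while work.number_of_nodes():
        k += 1
        while True:
            low = [v for v, d in work.degree() if d < k]
            if not low:
                break
            work.remove_nodes_from(low)
        for v in work.nodes():
            shell[v] = k
    return shell


def pagerank_dense_oracle(g: nx.Graph, damping=0.85, iters=10_000):
    """Dense power iteration on the Google matrix (dangling mass uniform)."""
    nodes = list(g.nodes())
    n = len(nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    out = A.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        P[i] = A[i] / out[i] if out[i] > 0 else 1.0 / n
    v = np.full(n, 1.0 / n)
    for _ in range(iters):
        nv = damping * v @ P + (1 - damping) / n
        if np.abs(nv - v).sum() < 1e-15:
            v = nv
            break
        v = nv
    return dict(zip(nodes, v))


class TestBuildNetwork:
    def test_identical_sequences_triangle(self, small_reference):
        seqs = [("g1", small_reference.records[0][1])] * 1
        seq = small_reference.records[0][1]
        records = [("g1", seq), ("g2", seq), ("g3", seq)]
        hits = rm.screen.all_pairs_hits(records)
        net = rm.build_network(hits)
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 3

    def test_strict_threshold_edgeless_keeps_nodes(self):
        hits = [make_hit("a", "b", evalue=1e-3), make_hit("b", "c", evalue=1e-4)]
        net = rm.build_network(hits, config=NetworkConfig(max_evalue=1e-20))
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 0

    def test_better_direction_wins(self):
        hits = [make_hit("a", "b", evalue=1.0, bitscore=10.0),
                make_hit("b", "a", evalue=1e-8, bitscore=80.0)]
        net = rm.build_network(hits)
        assert net.has_edge("a", "b")
        assert net["a"]["b"]["weight"] == 80.0

    def test_input_order_symmetric(self):
        hits = [make_hit("a", "b"), make_hit("b", "c"), make_hit("a", "c")]
        n1 = rm.build_network(hits)
        n2 = rm.build_network(list(reversed(hits)))
        assert sorted(n1.edges()) == sorted(n2.edges())

    def test_missing_metadata_warns_keeps_node(self):
        import pandas as pd

        meta = pd.DataFrame({"id": ["a"], "category": ["catalase"],
                             "phylum": ["Firmicutes"]})
        with pytest.warns(UserWarning, match="absent from metadata"):
            net = rm.build_network([make_hit("a", "b")], meta)
        assert "b" in net.nodes

    def test_family_partition_beats_random_modularity(self, small_reference):
        """Family clustering dominates: modularity of the true family
        partition exceeds that of a random partition of the same sizes."""
        hits = rm.screen.all_pairs_hits(small_reference.records)
        net = rm.build_network(hits, config=NetworkConfig(max_evalue=1e-5))
        labels = small_reference.labels
        fams = {}
        for node in net.nodes():
            fams.setdefault(labels[node], set()).add(node)
        true_part = list(fams.values())
        mod_true = nx.algorithms.community.modularity(net, true_part)
        rng = np.random.default_rng(0)
        nodes = list(net.nodes())
        rand_mods = []
        for _ in range(10):
            perm = rng.permutation(nodes)
            out, i = [], 0
            for block in true_part:
                out.append(set(perm[i:i + len(block)]))
                i += len(block)
            rand_mods.append(nx.algorithms.community.modularity(net, out))
        assert mod_true > float(np.mean(rand_mods))


class TestDegreeDistribution:
    def test_complete_and_star(self):
        assert rm.degree_distribution(nx.complete_graph(4)) == {3: 4}
        assert rm.degree_distribution(nx.star_graph(5)) == {5: 1, 1: 5}

    def test_counts_sum_to_node_count(self):
        g = rm.gen_test_graph("scale_free", 200, seed=1)
        hist = rm.degree_distribution(g)
        assert sum(hist.values()) == 200


class TestKShell:
    def test_complete_graph(self):
        ks = rm.kshell(nx.complete_graph(4))
        assert all(v == 3 for v in ks.shell.values())
        assert ks.max_shell == 3

    def test_star_all_shell_one(self):
        ks = rm.kshell(nx.star_graph(5))
        assert all(v == 1 for v in ks.shell.values())

    def test_oracle_equivalence_random_graphs(self):
        for seed in range(30):
            g = nx.gnp_random_graph(30, 0.2, seed=seed)
            assert rm.kshell(g).shell == kshell_bruteforce(g)

    def test_shell_bounded_by_degree(self):
        g = rm.gen_test_graph("scale_free", 100, seed=2)
        ks = rm.kshell(g)
        deg = dict(g.degree())
        assert all(ks.shell[v] <= deg[v] for v in g.nodes())


class TestCoreFraction:
    def test_complete_graph_all_core(self):
        assert rm.core_fraction(rm.kshell(nx.complete_graph(5))) == 1.0

    def test_star_all_core(self):
        assert rm.core_fraction(rm.kshell(nx.star_graph(9))) == 1.0

    def test_clique_with_pendant_chain(self):
        g = nx.complete_graph(5)
        chain = [(4, 5), (5, 6), (6, 7), (7, 8), (8, 9)]
        g.add_edges_from(chain)
        assert rm.core_fraction(rm.kshell(g)) == 0.5


class TestPageRank:
    def test_cycle_uniform(self):
        pr = rm.pagerank(nx.cycle_graph(6))
        assert all(abs(v - 1 / 6) < 1e-9 for v in pr.values())

    def test_star_center_dominates(self):
        pr = rm.pagerank(nx.star_graph(4))
        assert pr[0] > max(pr[i] for i in range(1, 5))

    def test_normalization_and_dense_oracle(self):
        for seed in range(5):
            g = nx.gnp_random_graph(40, 0.1, seed=seed)
            pr = rm.pagerank(g)
            assert abs(sum(pr.values()) - 1.0) < 1e-9
            oracle = pagerank_dense_oracle(g)
            for v in g.nodes():
                assert pr[v] == pytest.approx(oracle[v], abs=1e-8)

    def test_isolated_nodes_allowed(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        g.add_edge(1, 2)
        pr = rm.pagerank(g)
        assert abs(sum(pr.values()) - 1.0) < 1e-9


class TestAttack:
    def test_endpoints(self):
        g = rm.gen_test_graph("scale_free", 60, seed=4)
        curve = rm.attack(g, "max_degree", step=0.25)
        assert curve.fractions[0] == 0.0
        assert curve.rs[0] == 1.0
        assert curve.re[0] == 1.0
        assert curve.rs[-1] == 0.0

    @pytest.mark.parametrize("strategy", ["random", "max_degree", "max_pagerank"])
    def test_rs_non_increasing(self, strategy):
        g = rm.gen_test_graph("scale_free", 80, seed=5)
        curve = rm.attack(g, strategy, step=0.1, seed=1, compute_re=False)
        assert np.all(np.diff(curve.rs) <= 1e-12)
        assert np.all((curve.rs >= 0) & (curve.rs <= 1))

    def test_targeted_beats_random(self):
        """Fewer removals fragment the network under targeted attack."""
        g = rm.gen_test_graph("scale_free", 100, seed=6)
        random_aucs = [attack_auc(rm.attack(g, "random", 0.1, seed=s,
                                            compute_re=False))
                       for s in range(5)]
        deg = attack_auc(rm.attack(g, "max_degree", 0.1, compute_re=False))
        assert deg < float(np.mean(random_aucs))

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            rm.attack(nx.path_graph(5), "betweenness", 0.5)

    def test_random_seed_reproducible(self):
        g = rm.gen_test_graph("erdos_renyi", 50, seed=7, p=0.15)
        c1 = rm.attack(g, "random", 0.2, seed=3, compute_re=False)
        c2 = rm.attack(g, "random", 0.2, seed=3, compute_re=False)
        assert np.array_equal(c1.rs, c2.rs)


class TestExport:
    def test_graphml_roundtrip(self, tmp_path):
        g = rm.gen_test_graph("erdos_renyi", 20, seed=8, p=0.2)
        path = tmp_path / "net.graphml"
        rm.network.export_graphml(g, path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 20
        assert all("shell" in d and "pagerank" in d for _, d in back.nodes(data=True))
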