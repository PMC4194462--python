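import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gcnforge.graph_metrics import (AnnotationTable, VARIABLE_NAMES,
                                    assortativity_label, attack_tolerance,
                                    centralization, characterize,
                                    degree_domain_correlation, density,
                                    heterogeneity, read_annotations_tsv)


class TestDensity:
    def test_complete_graph(self):
        assert density(nx.complete_graph(4)) == pytest.approx(1.0)

    def test_path_of_three(self):
        assert density(nx.path_graph(3)) == pytest.approx(2 / 3)

    def test_five_nodes_four_edges(self):
        G = nx.path_graph(5)
        assert density(G) == pytest.approx(0.4)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            density(nx.empty_graph(1))


class TestHeterogeneity:
    def test_regular_graph_is_zero(self):
        assert heterogeneity(nx.cycle_graph(7)) == pytest.approx(0.0)

    def test_star(self):
        # degrees (3,1,1,1): population sd 0.866, mean 1.5
        assert heterogeneity(nx.star_graph(3)) == pytest.approx(np.sqrt(0.75) / 1.5)

    def test_path_of_four(self):
        assert heterogeneity(nx.path_graph(4)) == pytest.approx(1 / 3)


class TestCentralization:
    def test_star_is_maximal(self):
        assert centralization(nx.star_graph(6)) == pytest.approx(1.0)

    def test_cycle_is_zero(self):
        assert centralization(nx.cycle_graph(8)) == pytest.approx(0.0)

    def test_path_of_four(self):
        assert centralization(nx.path_graph(4)) == pytest.approx(4 / 9)

    def test_disconnected_uses_largest_component(self):
        G = nx.union(nx.star_graph(4), nx.path_graph(2), rename=("a", "b"))
        with pytest.warns(UserWarning, match="largest component"):
            assert centralization(G) == pytest.approx(1.0)


class TestAssortativity:
    def test_two_cliques_perfectly_assortative(self):
        G = nx.union(nx.complete_graph(3), nx.complete_graph(3), rename=("a", "b"))
        labels = {v: v[0] for v in G.nodes()}
        assert assortativity_label(G, labels) == pytest.approx(1.0)

    def test_complete_bipartite_disassortative(self):
        G = nx.complete_bipartite_graph(2, 2)
        labels = {0: "A", 1: "A", 2: "B", 3: "B"}
        assert assortativity_label(G, labels) == pytest.approx(-1.0)

    def test_four_cycle_mixed(self):
        G = nx.cycle_graph(4)
        labels = {0: "A", 1: "A", 2: "B", 3: "B"}
        assert assortativity_label(G, labels) == pytest.approx(0.0)

    def test_single_label_warns_zero(self):
        G = nx.complete_graph(3)
        with pytest.warns(UserWarning, match="single label|undefined"):
            assert assortativity_label(G, {v: "X" for v in G}) == 0.0

    def test_unlabelled_node_errors(self):
        with pytest.raises(ValueError, match="unlabelled"):
            assortativity_label(nx.path_graph(3), {0: "A", 1: "B"})


class TestAttackTolerance:
    def test_complete_graph_unaffected(self):
        assert attack_tolerance(nx.complete_graph(5)) == pytest.approx(1.0)

    def test_star_collapses_to_zero(self):
        assert attack_tolerance(nx.star_graph(5)) == pytest.approx(0.0)

    def test_path_hand_value(self):
        # remove node 'b' (degree tie broken lexicographically):
        # L = 10/6 before, 1 after on the {c,d} component
        G = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        assert attack_tolerance(G) == pytest.approx(5 / 3)


class TestDegreeDomainCorrelation:
    def test_perfect_separation(self):
        G = nx.Graph([("a", "b"), ("a", "c"), ("a", "d"), ("b", "e"), ("b", "f")])
        flags = {"a": 1, "b": 1, "c": 0, "d": 0, "e": 0, "f": 0}
        assert degree_domain_correlation(G, flags) == pytest.approx(1.0)

    def test_hand_point_biserial(self):
        G = nx.Graph([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        flags = {"a": 1, "b": 0, "c": 1, "d": 0}
        assert degree_domain_correlation(G, flags) == pytest.approx(np.sqrt(0.5))

    def test_regular_graph_warns_zero(self):
        G = nx.cycle_graph(6)
        flags = {v: v % 2 for v in G}
        with pytest.warns(UserWarning, match="undefined"):
            assert degree_domain_correlation(G, flags) == 0.0


class TestCharacterize:
    def test_triangle_composition(self):
        G = nx.complete_graph(3)
        ann = AnnotationTable({v: frozenset({"GO:1"}) for v in G},
                              {v: frozenset({"PF:1"}) for v in G},
                              {v: False for v in G})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row = characterize(G, ann, metadata={"network_id": "tri"})
        assert row["CC"] == 1.0 and row["Den"] == 1.0
        assert row["Het"] == 0.0 and row["Cen"] == 0.0
        assert row["AsG"] == 0.0 and row["Tol"] == 1.0 and row["KI"] == 0.0
        assert row["network_id"] == "tri"

    def test_deterministic_and_in_range(self, sim_network_500):
        from gcnforge.synthetic import simulate_annotations

        net = sim_network_500.network
        net = net.subgraph(net.degrees() > 0)
        degrees = dict(zip(net.gene_ids, net.degrees()))
        ann = simulate_annotations(net.gene_ids, module_assignments={},
                                   immunity_fraction=0.2, seed=5,
                                   degrees=degrees, degree_bias=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = characterize(net, ann)
            r2 = characterize(net, ann)
        pd.testing.assert_series_equal(r1, r2)
        assert 0 <= r1["CC"] <= 1 and 0 <= r1["Den"] <= 1
        assert 0 <= r1["Cen"] <= 1 and r1["Het"] >= 0 and r1["Tol"] >= 0
        assert -1 <= r1["AsG"] <= 1 and -1 <= r1["AsP"] <= 1
        assert -1 <= r1["KI"] <= 1

    def test_relabeling_invariance(self, rng):
        """All eight variables are invariant under node relabeling."""
        from gcnforge.thresholding import Network

        n = 30
        M = rng.random((n, n)) > 0.8
        A = np.triu(M, 1)
        A = A | A.T
        ids = np.array([f"g{i:02d}" for i in range(n)])
        net = Network(ids, A)
        perm = rng.permutation(n)
        net_p = Network(ids[perm], A[np.ix_(perm, perm)])
        terms = {g: frozenset({f"T{int(i) % 3}"})
                 for i, g in enumerate(ids)}
        ann = AnnotationTable(terms, terms, {g: (int(i) % 4 == 0)
                                             for i, g in enumerate(ids)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = characterize(net, ann)[VARIABLE_NAMES]
            r2 = characterize(net_p, ann)[VARIABLE_NAMES]
        pd.testing.assert_series_equal(r1, r2, atol=1e-9)


def test_size_independence_guard(rng):
    """Regression guard: the intensively-defined variables (clustering,
    heterogeneity, degree-immunity correlation) must not drift with network
    size when the generative parameters are fixed.  Extensive variables
    such as density are mechanically size-coupled at a fixed degree
    distribution (Den ~ mean degree / n) and are excluded from the guard."""
    from gcnforge.comparison import variable_size_correlation
    from gcnforge.synthetic import (NetworkSimSpec, simulate_annotations,
                                    simulate_network)

    rows, sizes = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        i = 0
        for n in [50, 100, 200, 350, 500]:
            for _ in range(3):
                sim = simulate_network(NetworkSimSpec(n, 2.0, 1.5, 0.1,
                                                      seed=100 + i))
                i += 1
                net = sim.network
                net = net.subgraph(net.degrees() > 0)
                degrees = dict(zip(net.gene_ids, net.degrees()))
                ann = simulate_annotations(net.gene_ids, immunity_fraction=0.2,
                                           seed=i, degrees=degrees,
                                           degree_bias=1.0)
                rows.append(characterize(net, ann))
                sizes.append(net.n_nodes)
        T = pd.DataFrame(rows)[VARIABLE_NAMES]
        corr = variable_size_correlation(T, sizes)
    assert (corr[["CC", "Het", "KI"]].abs() <= 0.5).all()


def test_annotation_tsv_round_trip(tmp_path):
    ann = AnnotationTable(
        {"g1": frozenset({"GO:1", "GO:2"}), "g2": frozenset()},
        {"g1": frozenset({"PF:9"}), "g2": frozenset({"PF:1"})},
        {"g1": True, "g2": False},
    )
    path = tmp_path / "ann.tsv"
    ann.to_frame().to_csv(path, sep="\t", index=False)
    back = read_annotations_tsv(path)
    assert back.go_for("g1") == ann.go_for("g1")
    assert back.pfam_for("g2") == ann.pfam_for("g2")
    assert back.immunity_for("g1") and not back.immunity_for("g2")
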