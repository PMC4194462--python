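import warnings

import numpy as np
import pandas as pd
import pytest

from gcnforge.similarity import apcc, ncmi, similarity_matrix
from gcnforge.synthetic import (NetworkSimSpec, embed_similarity,
                                recovery_experiment, simulate_annotations,
                                simulate_expression, simulate_network)
from gcnforge.thresholding import adjacency, select_threshold, threshold_curve


class TestSimulateNetwork:
    def test_realized_cv_near_target(self, sim_network_500):
        # group-1 parameters at n=500: realized CV within 15% of 2.86
        assert 2.43 <= sim_network_500.realized_cv <= 3.29

    def test_realized_clustering_near_target(self, sim_network_500):
        assert abs(sim_network_500.realized_cc - 0.02) <= 0.05

    def test_seeded_determinism(self):
        spec = NetworkSimSpec(120, 2.0, 1.5, 0.05, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = simulate_network(spec).network.adjacency
            b = simulate_network(spec).network.adjacency
        np.testing.assert_array_equal(a, b)

    def test_simple_graph(self, sim_network_500):
        A = sim_network_500.network.adjacency
        assert not A.diagonal().any()
        np.testing.assert_array_equal(A, A.T)

    def test_degree_tail_slope_near_minus_two(self, sim_network_500):
        """Log-log least-squares fit of the degree histogram tail."""
        k = sim_network_500.degree_sequence
        ks, counts = np.unique(k, return_counts=True)
        keep = counts >= 2  # drop one-off tail fluctuations
        slope = np.polyfit(np.log(ks[keep]), np.log(counts[keep]), 1)[0]
        assert abs(slope - (-2.0)) <= 0.5

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NetworkSimSpec(5, 2.0, 1.0, 0.02)
        with pytest.raises(ValueError):
            NetworkSimSpec(100, 0.9, 1.0, 0.02)
        with pytest.raises(ValueError):
            NetworkSimSpec(100, 2.0, 1.0, 1.5)


class TestEmbedSimilarity:
    def test_thresholding_recovers_planted_graph_exactly(self, sim_network_500):
        net = sim_network_500.network
        S = embed_similarity(net, 0.5, seed=2)
        back = adjacency(S, 0.5)
        np.testing.assert_array_equal(back.adjacency, net.adjacency)

    def test_band_separation(self, sim_network_500):
        net = sim_network_500.network
        tau, delta = 0.6, 0.05
        S = embed_similarity(net, tau, delta=delta, seed=2)
        off = ~np.eye(net.n_nodes, dtype=bool)
        edge_vals = S.values[net.adjacency]
        non_edge_vals = S.values[off & ~net.adjacency]
        assert edge_vals.min() >= tau
        assert non_edge_vals.max() <= tau - delta

    def test_symmetric_unit_diagonal(self, sim_network_500):
        S = embed_similarity(sim_network_500.network, 0.4, seed=9)
        np.testing.assert_allclose(S.values, S.values.T)
        np.testing.assert_allclose(np.diag(S.values), 1.0)

    def test_invalid_parameters(self, sim_network_500):
        with pytest.raises(ValueError):
            embed_similarity(sim_network_500.network, 1.2)
        with pytest.raises(ValueError):
            embed_similarity(sim_network_500.network, 0.3, delta=0.5)


class TestSimulateExpression:
    def test_noiseless_linear_module_perfectly_correlated(self):
        E = simulate_expression(5, 40, [(5, "linear")], noise_sd=0.0, seed=1)
        for i in range(1, 5):
            assert apcc(E.iloc[0], E.iloc[i]) == pytest.approx(1.0)

    def test_linear_module_high_apcc(self, module_expression):
        E = module_expression
        vals = [apcc(E.iloc[0], E.iloc[i]) for i in range(1, 10)]
        assert min(vals) >= 0.9

    def test_quadratic_module_ncmi_vs_apcc(self, module_expression):
        E = module_expression
        # quadratic module occupies rows 20..29; even rows carry the latent
        # linearly, odd rows quadratically
        lin, quad = E.iloc[20], E.iloc[21]
        assert apcc(lin, quad) < 0.3
        assert ncmi(lin, quad) >= 0.5

    def test_inverted_module_anticorrelated(self, module_expression):
        # inverted module occupies rows 10..19; adjacent genes carry
        # opposite signs of the same latent profile
        E = module_expression
        r = np.corrcoef(E.iloc[10], E.iloc[11])[0, 1]
        assert r < -0.9 and apcc(E.iloc[10], E.iloc[11]) >= 0.9

    def test_background_uncorrelated(self, module_expression):
        E = module_expression
        assert apcc(E.iloc[40], E.iloc[50]) < 0.4

    def test_module_budget_checked(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_expression(5, 10, [(10, "linear")])

    def test_seeded_determinism(self):
        a = simulate_expression(10, 20, [(4, "shifted")], seed=5)
        b = simulate_expression(10, 20, [(4, "shifted")], seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateAnnotations:
    def test_full_enrichment_two_module_cliques_assortative(self):
        import networkx as nx

        from gcnforge.graph_metrics import assortativity_label
        from gcnforge.graph_metrics import AnnotationTable  # noqa: F401

        G = nx.union(nx.complete_graph(4), nx.complete_graph(4), rename=("a", "b"))
        modules = {v: (0 if v.startswith("a") else 1) for v in G.nodes()}
        ann = simulate_annotations(list(G.nodes()), module_assignments=modules,
                                   enrichment=1.0, immunity_fraction=0.0, seed=0)
        from gcnforge.graph_metrics import _majority_label

        labels = _majority_label(G, {v: ann.go_for(v) for v in G.nodes()})
        assert assortativity_label(G, labels) == pytest.approx(1.0)

    def test_no_immunity_flags_gives_zero_ki(self):
        import networkx as nx

        from gcnforge.graph_metrics import degree_domain_correlation

        G = nx.star_graph(5)
        ann = simulate_annotations([str(v) for v in G.nodes()],
                                   immunity_fraction=0.0, seed=0)
        flags = {v: ann.immunity_for(str(v)) for v in G.nodes()}
        with pytest.warns(UserWarning, match="undefined"):
            assert degree_domain_correlation(G, flags) == 0.0

    def test_degree_bias_flags_hubs(self, sim_network_500):
        net = sim_network_500.network
        degrees = dict(zip(net.gene_ids, net.degrees()))
        ann = simulate_annotations(net.gene_ids, immunity_fraction=0.1, seed=1,
                                   degrees=degrees, degree_bias=3.0)
        flagged = [g for g in net.gene_ids if ann.immunity_for(g)]
        unflagged = [g for g in net.gene_ids if not ann.immunity_for(g)]
        assert np.mean([degrees[g] for g in flagged]) > \
            np.mean([degrees[g] for g in unflagged])


class TestRecoveryExperiment:
    def test_seeded_determinism(self):
        spec = NetworkSimSpec(200, 2.0, 1.5, 0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = recovery_experiment(spec, 0.5, 2, seed=4)
            r2 = recovery_experiment(spec, 0.5, 2, seed=4)
        pd.testing.assert_frame_equal(r1.replicates, r2.replicates)
        assert r1.eta == r2.eta

    def test_eta_exact_mean_absolute_error(self):
        from gcnforge.synthetic import RecoveryResult

        res = RecoveryResult(pd.DataFrame({"tau_true": [0.5, 0.5],
                                           "tau_hat": [0.52, 0.46]}))
        assert res.eta == pytest.approx(0.03)

    def test_eta_monotone_in_gap(self):
        """A wider edge/non-edge separation can only make recovery easier."""
        spec = NetworkSimSpec(300, 2.0, 2.86, 0.02)
        etas = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for delta in (0.01, 0.05, 0.1):
                etas.append(recovery_experiment(spec, 0.5, 5, seed=9,
                                                delta=delta).eta)
        assert etas[0] >= etas[1] - 1e-9 >= etas[2] - 2e-9

    def test_too_few_reps(self):
        with pytest.raises(ValueError):
            recovery_experiment(NetworkSimSpec(100), 0.5, 1, seed=0)
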