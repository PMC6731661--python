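import numpy as np
import networkx as nx
import pytest

from diauxlab.dbn import ExpressionDataset, fit_parameters, loo_prediction_error
from diauxlab.elsa import (NoArborescenceError, dependency_graph,
                           ensemble_rank, forward_select, max_arborescence)
from conftest import (brute_force_arborescence, make_chain_dbn,
                      sample_episodes)


def lagged_dataset(parent_series, child_series):
    genes = ["c", "p"]
    vals = np.vstack([child_series, parent_series])
    return ExpressionDataset(genes, np.arange(float(len(parent_series))),
                             vals)


class TestDependencyGraph:
    def test_exact_lagged_copy_scores_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        c = np.roll(p, 1)  # c[t+1] = p[t]
        g = dependency_graph(lagged_dataset(p, c), ["p"])
        assert g["p"]["c"]["weight"] == pytest.approx(1.0)

    def test_anticorrelation_scores_absolute_value(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        c = np.roll(-2.0 * p, 1)
        g = dependency_graph(lagged_dataset(p, c), ["p"])
        assert g["p"]["c"]["weight"] == pytest.approx(1.0)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=1000)
        c = rng.normal(size=1000)
        g = dependency_graph(lagged_dataset(p, c), ["p"])
        assert g["p"]["c"]["weight"] < 0.1

    def test_zero_variance_gene_scores_zero_with_warning(self):
        p = np.full(30, 0.5)
        c = np.arange(30.0)
        g = dependency_graph(lagged_dataset(p, c), ["p"])
        assert g["p"]["c"]["weight"] == 0.0

    def test_no_self_edges(self):
        rng = np.random.default_rng(3)
        data = ExpressionDataset(["a", "b"], np.arange(10.0),
                                 rng.uniform(size=(2, 10)))
        g = dependency_graph(data, ["a", "b"])
        assert not g.has_edge("a", "a") and not g.has_edge("b", "b")


class TestMaxArborescence:
    def test_single_node_empty_set(self):
        g = nx.DiGraph()
        g.add_node("r")
        assert max_arborescence(g, "r") == set()

    def test_three_node_example_by_hand(self):
        g = nx.DiGraph()
        g.add_weighted_edges_from([("r", "a", 2), ("r", "b", 1),
                                   ("a", "b", 3)])
        assert max_arborescence(g, "r") == {("r", "a"), ("a", "b")}

    def test_unreachable_node_reported(self):
        g = nx.DiGraph()
        g.add_weighted_edges_from([("r", "a", 1)])
        g.add_node("lonely")
        with pytest.raises(NoArborescenceError) as exc:
            max_arborescence(g, "r")
        assert "lonely" in exc.value.unreachable

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        nodes = [f"n{i}" for i in range(n)]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for u in nodes:
            for v in nodes:
                if u != v and rng.random() < 0.7:
                    g.add_edge(u, v, weight=float(rng.uniform(0, 5)))
        root = nodes[0]
        reachable = nx.descendants(g, root) | {root}
        if set(nodes) - reachable:
            with pytest.raises(NoArborescenceError):
                max_arborescence(g, root)
            return
        found = max_arborescence(g, root)
        best = brute_force_arborescence(g, root)
        w_found = sum(g[u][v]["weight"] for u, v in found)
        assert w_found == pytest.approx(best[0], abs=1e-9)


class TestEnsembleRank:
    def test_single_full_component_has_unit_frequencies(self):
        dbn = make_chain_dbn(5, weight=0.8, sigma=0.05)
        data = sample_episodes(dbn, 80, np.random.default_rng(0))
        ranking = ensemble_rank(data, dbn, K=1, row_frac=1.0, node_frac=1.0,
                                seed=0, prior_floor=0.0, w_min=0.0)
        freqs = {e.frequency for e in ranking}
        assert freqs == {1.0}

    def test_prior_edge_absent_from_data_survives_at_floor(self):
        dbn = make_chain_dbn(4, weight=0.8, sigma=0.05)
        prior = dbn.copy()
        prior.add_edge("r0", "r3", 0.5)  # not in the generating chain
        data = sample_episodes(dbn, 150, np.random.default_rng(1))
        ranking = ensemble_rank(data, prior, K=50, seed=1, prior_floor=0.5,
                                w_min=0.0)
        f = {(e.parent, e.child): e.frequency for e in ranking}
        assert f[("r0", "r3")] >= 0.5

    def test_empty_candidate_set_rejected(self):
        dbn = make_chain_dbn(3)
        data = sample_episodes(dbn, 30, np.random.default_rng(2))
        with pytest.raises(ValueError):
            ensemble_rank(data, None, candidates=[], K=5, seed=0)

    def test_frequencies_sorted_non_increasing(self):
        dbn = make_chain_dbn(6, weight=0.7, sigma=0.08)
        data = sample_episodes(dbn, 120, np.random.default_rng(3))
        ranking = ensemble_rank(data, dbn, K=30, seed=3, prior_floor=0.0)
        fs = [e.frequency for e in ranking]
        assert fs == sorted(fs, reverse=True)

    def test_invariant_to_gene_relabeling(self):
        dbn = make_chain_dbn(5, weight=0.7, sigma=0.08)
        data = sample_episodes(dbn, 100, np.random.default_rng(4))
        r1 = ensemble_rank(data, dbn, K=40, seed=7, prior_floor=0.0)
        ren = {g: g.replace("r", "q") for g in dbn.nodes}
        dbn2 = dbn.copy()
        dbn2.nodes = {ren[g]: n for g, n in dbn.nodes.items()}
        for e in dbn2.edges:
            e.parent, e.child = ren[e.parent], ren[e.child]
        data2 = ExpressionDataset([ren[g] for g in data.genes], data.times,
                                  data.values.copy())
        r2 = ensemble_rank(data2, dbn2, K=40, seed=7, prior_floor=0.0)
        assert {(ren[e.parent], ren[e.child], round(e.frequency, 9))
                for e in r1} == \
            {(e.parent, e.child, round(e.frequency, 9)) for e in r2}

    def test_planted_chain_ranks_true_edges_first(self):
        dbn = make_chain_dbn(8, weight=0.8, sigma=0.05)
        data = sample_episodes(dbn, 300, np.random.default_rng(5))
        ranking = ensemble_rank(data, dbn, K=100, seed=5, prior_floor=0.0)
        true_edges = {(e.parent, e.child) for e in dbn.edges}
        ranked = [(e.parent, e.child) for e in ranking]
        assert set(ranked[:7]) == true_edges


class TestForwardSelect:
    def test_empty_ranking_returns_refit_base(self):
        dbn = make_chain_dbn(3, weight=0.6, sigma=0.05)
        data = sample_episodes(dbn, 60, np.random.default_rng(0))
        from diauxlab.elsa import EdgeRanking
        out = forward_select(dbn, EdgeRanking([], 1), data, max_adds=5)
        assert {(e.parent, e.child) for e in out.edges} == \
            {(e.parent, e.child) for e in dbn.edges}

    def test_planted_extra_edge_is_accepted(self):
        rng = np.random.default_rng(6)
        accepted = 0
        for _ in range(10):
            truth = make_chain_dbn(4, weight=0.7, sigma=0.05)
            truth.add_edge("r0", "r2", 0.6)
            data = sample_episodes(truth, 200, rng)
            base = make_chain_dbn(4, weight=0.7, sigma=0.05)
            ranking = ensemble_rank(data, base, K=50,
                                    seed=int(rng.integers(2**31)),
                                    prior_floor=0.0)
            out = forward_select(base, ranking, data, max_adds=3)
            accepted += out.has_edge("r0", "r2")
        assert accepted >= 9

    def test_pure_noise_candidates_rarely_accepted(self):
        rng = np.random.default_rng(7)
        false_adds = 0
        for _ in range(10):
            truth = make_chain_dbn(5, weight=0.7, sigma=0.05)
            data = sample_episodes(truth, 200, rng)
            ranking = ensemble_rank(data, truth, K=50,
                                    seed=int(rng.integers(2**31)),
                                    prior_floor=0.0)
            out = forward_select(truth, ranking, data, max_adds=5)
            false_adds += len(out.edges) > len(truth.edges)
        assert false_adds <= 2

    def test_never_increases_loo_error(self):
        dbn = make_chain_dbn(5, weight=0.7, sigma=0.08)
        data = sample_episodes(dbn, 150, np.random.default_rng(8))
        base = make_chain_dbn(5, weight=0.7, sigma=0.08)
        base.remove_edge("r2", "r3")
        ranking = ensemble_rank(data, base, K=50, seed=8, prior_floor=0.0)
        before = loo_prediction_error(fit_parameters(base, data), data)
        out = forward_select(base, ranking, data, max_adds=4)
        after = loo_prediction_error(out, data)
        assert after <= before + 1e-12
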