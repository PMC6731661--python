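import numpy as np
import pytest

from diauxlab.models import ENZYME, REGULATOR, Node, RegulatoryDBN
from diauxlab.dbn import (ExpressionDataset, GeneStateSlice, backward_infer,
                          fit_parameters, forward_simulate, forward_step,
                          initial_slice, loo_prediction_error, node_loo_error,
                          SingularityError)
from conftest import make_chain_dbn, sample_episodes, joint_gaussian_posterior


def two_node_dbn(w=1.0, b=0.0, sigma=0.0):
    dbn = RegulatoryDBN(nodes={
        "p": Node(REGULATOR, bias=0.0, sigma=0.0, init_mean=0.5, init_sd=0.0),
        "c": Node(REGULATOR, bias=b, sigma=sigma)})
    dbn.add_edge("p", "c", w)
    return dbn


class TestForward:
    def test_parentless_node_goes_to_bias(self):
        dbn = RegulatoryDBN(nodes={"g": Node(REGULATOR, bias=0.2, sigma=0.1,
                                             init_mean=0.9, init_sd=0.4)})
        out = forward_step(dbn, initial_slice(dbn))
        assert out.mean["g"] == pytest.approx(0.2)
        assert out.sd["g"] == pytest.approx(0.1)

    def test_deterministic_copy_through_unit_edge(self):
        dbn = two_node_dbn(w=1.0)
        out = forward_step(dbn, initial_slice(dbn))
        assert out.mean["c"] == pytest.approx(0.5)
        assert out.sd["c"] == pytest.approx(0.0)

    def test_two_parent_propagation_matches_hand_calculation(self):
        dbn = RegulatoryDBN(nodes={
            "a": Node(REGULATOR, init_mean=0.4, init_sd=0.1),
            "b": Node(REGULATOR, init_mean=0.1, init_sd=0.2),
            "c": Node(REGULATOR, bias=0.05, sigma=0.05)})
        dbn.add_edge("a", "c", 2.0)
        dbn.add_edge("b", "c", -1.0)
        out = forward_step(dbn, initial_slice(dbn))
        assert out.mean["c"] == pytest.approx(0.05 + 2 * 0.4 - 0.1)
        assert out.sd["c"] == pytest.approx(
            np.sqrt(4 * 0.01 + 1 * 0.04 + 0.0025))

    def test_knocked_out_gene_clamped_to_zero(self):
        dbn = two_node_dbn(w=1.0, b=0.3)
        traj = forward_simulate(dbn, None, 5, knockouts={"c"})
        assert np.all(traj.means[:, traj.index("c")] == 0)
        assert np.all(traj.sds[:, traj.index("c")] == 0)

    def test_single_step_equals_forward_step(self):
        dbn = make_chain_dbn(4)
        traj = forward_simulate(dbn, None, 1)
        step = forward_step(dbn, initial_slice(dbn))
        for g in dbn.nodes:
            assert traj.state(g, 1)[0] == pytest.approx(step.mean[g])

    def test_stable_system_converges_to_linear_fixed_point(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(5)]
        dbn = RegulatoryDBN(nodes={g: Node(REGULATOR,
                                           bias=float(rng.uniform(0, .5)),
                                           sigma=0.0,
                                           init_mean=float(rng.uniform(0, 1)))
                                   for g in genes})
        for c in genes:  # total incoming |w| < 1 per node
            parents = [p for p in genes if p != c][:3]
            ws = rng.uniform(-0.3, 0.3, size=3)
            ws *= 0.9 / max(np.sum(np.abs(ws)), 1)
            for p, w in zip(parents, ws):
                dbn.add_edge(p, c, float(w))
        traj = forward_simulate(dbn, None, 200)
        order = sorted(genes)
        W = np.zeros((5, 5))
        for e in dbn.edges:
            W[order.index(e.child), order.index(e.parent)] = e.weight
        b = np.array([dbn.nodes[g].bias for g in order])
        fixed = np.linalg.solve(np.eye(5) - W, b)
        assert np.allclose(traj.means[-1], fixed, atol=1e-6)

    def test_forward_variance_monotone_in_sigma(self):
        for s1, s2 in [(0.01, 0.05), (0.05, 0.2)]:
            d1, d2 = two_node_dbn(sigma=s1), two_node_dbn(sigma=s2)
            t1 = forward_simulate(d1, None, 10)
            t2 = forward_simulate(d2, None, 10)
            assert np.all(t2.sds[:, t2.index("c")] >=
                          t1.sds[:, t1.index("c")] - 1e-12)


class TestBackward:
    def test_no_evidence_returns_forward_prior(self):
        dbn = make_chain_dbn(3, sigma=0.1)
        fwd = forward_simulate(dbn, None, 4)
        bwd = backward_infer(dbn, {}, 4)
        assert np.allclose(fwd.means, bwd.means)
        assert np.allclose(fwd.sds, bwd.sds)
        assert bwd.direction == "backward"

    def test_exact_consistent_evidence_pins_trajectory(self):
        dbn = make_chain_dbn(3, sigma=0.0)
        fwd = forward_simulate(dbn, None, 3)
        ev = {(g, t): (fwd.state(g, t)[0], 0.0)
              for g in dbn.nodes for t in range(4)}
        bwd = backward_infer(dbn, ev, 3)
        assert np.allclose(bwd.means, fwd.means, atol=1e-9)
        assert np.allclose(bwd.sds, 0.0, atol=1e-9)

    def test_chain_posterior_matches_hand_joint_conditioning(self):
        # r -> e; exact observation of e at t=1 informs r at t=0
        dbn = RegulatoryDBN(nodes={
            "r": Node(REGULATOR, bias=0.0, sigma=0.1, init_mean=0.5,
                      init_sd=0.2),
            "e": Node(ENZYME, bias=0.1, sigma=0.05)})
        dbn.add_edge("r", "e", 0.8)
        ev = {("e", 1): (0.9, 0.0)}
        bwd = backward_infer(dbn, ev, 1)
        genes, om, osd = joint_gaussian_posterior(dbn, ev, 1)
        assert np.allclose(bwd.means, om, atol=1e-9)
        assert np.allclose(bwd.sds, osd, atol=1e-9)

    def test_evidence_for_unknown_gene_or_time_raises(self):
        dbn = make_chain_dbn(2)
        with pytest.raises(KeyError):
            backward_infer(dbn, {("ghost", 0): (0.5, 0.1)}, 2)
        with pytest.raises(KeyError):
            backward_infer(dbn, {("r0", 7): (0.5, 0.1)}, 2)
        with pytest.raises(ValueError):
            backward_infer(dbn, {("r0", 0): (0.5, -0.1)}, 2)


class TestFit:
    def _data_from(self, dbn, n, rng, sigma_override=None, noise=0.0):
        return sample_episodes(dbn, n, rng, noise_sd=noise)

    def test_noise_free_recovery_is_exact(self):
        dbn = make_chain_dbn(4, weight=0.6, sigma=0.0)
        data = sample_episodes(dbn, 60, np.random.default_rng(0))
        fit = fit_parameters(dbn, data, ridge=0.0)
        for e in fit.edges:
            assert e.weight == pytest.approx(0.6, abs=1e-8)
        for g in fit.nodes:
            assert fit.nodes[g].sigma == pytest.approx(0.0, abs=1e-8)

    def test_infinite_ridge_shrinks_weights_to_zero(self):
        dbn = make_chain_dbn(3, weight=0.6, sigma=0.05)
        data = sample_episodes(dbn, 100, np.random.default_rng(1))
        fit = fit_parameters(dbn, data, ridge=1e12)
        for e in fit.edges:
            assert abs(e.weight) < 1e-6
        gi = data.genes.index("r1")
        dst = [j for _, j in data.transitions()]
        assert fit.nodes["r1"].bias == pytest.approx(
            float(np.mean(data.values[gi, dst])), abs=1e-6)

    def test_singularity_without_ridge(self):
        dbn = RegulatoryDBN(nodes={
            "a": Node(REGULATOR), "b": Node(REGULATOR),
            "c": Node(REGULATOR), "d": Node(REGULATOR)})
        for p in ("a", "b", "c"):
            dbn.add_edge(p, "d", 0.1)
        genes = sorted(dbn.nodes)
        vals = np.random.default_rng(2).uniform(0, 1, size=(4, 3))
        data = ExpressionDataset(genes, np.arange(3.0), vals)
        with pytest.raises(SingularityError):
            fit_parameters(dbn, data, ridge=0.0)

    def test_monte_carlo_weight_recovery(self):
        # planted weights recovered within 0.05 in the vast majority of cases
        rng = np.random.default_rng(42)
        ok = total = 0
        for _ in range(10):
            dbn = make_chain_dbn(5, weight=float(rng.uniform(0.3, 0.8)),
                                 sigma=0.1)
            data = sample_episodes(dbn, 500, rng)
            fit = fit_parameters(dbn, data, ridge=1e-2)
            truth = {(e.parent, e.child): e.weight for e in dbn.edges}
            for e in fit.edges:
                total += 1
                ok += abs(e.weight - truth[(e.parent, e.child)]) < 0.05
        assert ok / total >= 0.95

    def test_equivariant_to_gene_relabeling(self):
        dbn = make_chain_dbn(4, weight=0.5, sigma=0.08)
        data = sample_episodes(dbn, 80, np.random.default_rng(3))
        fit1 = fit_parameters(dbn, data, ridge=1e-2)
        # relabel r_i -> z_i everywhere
        ren = {g: g.replace("r", "z") for g in dbn.nodes}
        dbn2 = RegulatoryDBN(
            nodes={ren[g]: Node(n.kind, n.bias, n.sigma, n.init_mean,
                                n.init_sd) for g, n in dbn.nodes.items()})
        for e in dbn.edges:
            dbn2.add_edge(ren[e.parent], ren[e.child], e.weight)
        data2 = ExpressionDataset([ren[g] for g in data.genes], data.times,
                                  data.values.copy())
        fit2 = fit_parameters(dbn2, data2, ridge=1e-2)
        w1 = {(e.parent, e.child): e.weight for e in fit1.edges}
        w2 = {(e.parent, e.child): e.weight for e in fit2.edges}
        for (p, c), w in w1.items():
            assert w2[(ren[p], ren[c])] == pytest.approx(w)


class TestLOO:
    def test_zero_error_on_noise_free_data(self):
        dbn = make_chain_dbn(3, weight=0.7, sigma=0.0)
        data = sample_episodes(dbn, 50, np.random.default_rng(0))
        fit = fit_parameters(dbn, data, ridge=0.0)
        assert loo_prediction_error(fit, data, ridge=0.0) < 1e-12

    def test_predictive_parent_lowers_loo_error(self):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(10):
            dbn = two_node = make_chain_dbn(2, weight=0.8, sigma=0.05)
            data = sample_episodes(dbn, 100, rng)
            with_parent = node_loo_error(dbn, data, "r1", ridge=1e-2)
            no_parent = dbn.copy()
            no_parent.remove_edge("r0", "r1")
            without = node_loo_error(no_parent, data, "r1", ridge=1e-2)
            wins += with_parent < without
        assert wins >= 8

    def test_unstructured_data_stable_under_time_permutation(self):
        rng = np.random.default_rng(6)
        genes = ["a", "b"]
        vals = rng.normal(0, 1, size=(2, 60))
        data = ExpressionDataset(genes, np.arange(60.0), vals)
        dbn = RegulatoryDBN(nodes={g: Node(REGULATOR) for g in genes})
        dbn.add_edge("a", "b", 0.0)
        e1 = loo_prediction_error(dbn, data, ridge=1e-2)
        perm = rng.permutation(60)
        data2 = ExpressionDataset(genes, np.arange(60.0), vals[:, perm])
        e2 = loo_prediction_error(dbn, data2, ridge=1e-2)
        assert 0.5 < e1 / e2 < 2.0
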