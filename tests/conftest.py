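"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from diauxlab.models import (ENZYME, REGULATOR, HybridModel, MetabolicModel,
                             Metabolite, MetaboliteRule, Node, Reaction,
                             RegulatoryDBN)
from diauxlab.dbn import ExpressionDataset
from diauxlab.virtual_lab import LabConfig, generate_ground_truth

# Scaled-down study grid used throughout the suite (shorter batch, coarser
# sampling, less glucose) - same dynamics, ~3x fewer DFBA steps.
FAST = dict(horizon=24.0, dt=0.75, glucose_mM=8.0)


@pytest.fixture(scope="session")
def lab_config():
    return LabConfig(seed=1, **FAST)


@pytest.fixture(scope="session")
def toy_model(lab_config):
    return generate_ground_truth(lab_config)


@pytest.fixture
def tiny_metabolic():
    """Two-reaction chain: glc_e -(upt, ub 10)-> glc_c -(bio, 0.5/glc)-> X."""
    return MetabolicModel(
        metabolites={"glc_e": Metabolite("glc_e", external=True),
                     "glc_c": Metabolite("glc_c")},
        reactions={"upt": Reaction("upt", {"glc_e": -1, "glc_c": 1}, 0, 10),
                   "bio": Reaction("bio", {"glc_c": -1}, 0, 1000)},
        biomass_reaction="bio",
        gene_rules={"upt": "E1"},
        medium={"glc_e": 10.0},
        glucose_metabolite="glc_e")


def make_chain_dbn(n: int, weight: float = 0.8, sigma: float = 0.05,
                   bias: float = 0.1) -> RegulatoryDBN:
    """r0 -> r1 -> ... -> r_{n-1} chain, all nodes regulators."""
    nodes = {f"r{i}": Node(REGULATOR, bias=bias, sigma=sigma,
                           init_mean=0.5, init_sd=0.0) for i in range(n)}
    dbn = RegulatoryDBN(nodes=nodes)
    for i in range(n - 1):
        dbn.add_edge(f"r{i}", f"r{i+1}", weight)
    return dbn


def sample_episodes(dbn: RegulatoryDBN, n_transitions: int, rng,
                    episode_len: int = 10,
                    noise_sd: float = 0.0) -> ExpressionDataset:
    """Sample expression data from a DBN in restarted episodes.

    Independent of the package's virtual-lab generator: plain numpy
    ancestral sampling, used as the data source for recovery oracles."""
    genes = sorted(dbn.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    W = np.zeros((G, G))
    for e in dbn.edges:
        W[idx[e.child], idx[e.parent]] = e.weight
    b = np.array([dbn.nodes[g].bias for g in genes])
    sig = np.array([dbn.nodes[g].sigma for g in genes])
    cols, times = [], []
    while len(cols) - len(times) // episode_len < n_transitions + 1:
        x = rng.uniform(0, 1, size=G)
        for t in range(episode_len):
            if t > 0:
                x = b + W @ x + rng.normal(0, sig)
            cols.append(x.copy())
            times.append(float(t))
        if sum(1 for i in range(len(times) - 1)
               if times[i + 1] > times[i]) >= n_transitions:
            break
    values = np.array(cols).T + rng.normal(0, noise_sd,
                                           size=(G, len(cols))) \
        if noise_sd else np.array(cols).T
    return ExpressionDataset(genes, np.array(times), values)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_arborescence(graph, root):
    """Enumerate all spanning arborescences (each non-root node picks one
    in-neighbour; keep acyclic/connected assignments); return max weight."""
    nodes = [v for v in graph.nodes if v != root]
    choices = []
    for v in nodes:
        preds = [(u, graph[u][v]["weight"]) for u in graph.predecessors(v)]
        if not preds:
            return None
        choices.append(preds)
    best = None
    for combo in itertools.product(*choices):
        parent = {v: u for v, (u, _) in zip(nodes, combo)}
        # check no cycles (every node reaches root by parent pointers)
        ok = True
        for v in nodes:
            seen = set()
            cur = v
            while cur != root:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = parent.get(cur)
                if cur is None:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        w = sum(wt for _, wt in combo)
        edges = {(parent[v], v) for v in nodes}
        if best is None or w > best[0]:
            best = (w, edges)
    return best


def joint_gaussian_posterior(dbn: RegulatoryDBN, evidence, n: int):
    """Exact posterior via full joint covariance construction + conditioning.

    Brute-force oracle for Gaussian smoothing on small models."""
    genes = sorted(dbn.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    W = np.zeros((G, G))
    for e in dbn.edges:
        W[idx[e.child], idx[e.parent]] = e.weight
    b = np.array([dbn.nodes[g].bias for g in genes])
    sig = np.array([dbn.nodes[g].sigma for g in genes])
    m0 = np.array([dbn.nodes[g].init_mean for g in genes])
    s0 = np.array([dbn.nodes[g].init_sd for g in genes])
    D = G * (n + 1)
    mean = np.zeros(D)
    cov = np.zeros((D, D))
    mean[:G] = m0
    cov[:G, :G] = np.diag(s0 ** 2)
    for t in range(n):
        sl = slice(t * G, (t + 1) * G)
        nl = slice((t + 1) * G, (t + 2) * G)
        mean[nl] = b + W @ mean[sl]
        for s in range(t + 1):
            blk = cov[sl, s * G:(s + 1) * G]
            prop = W @ blk
            cov[nl, s * G:(s + 1) * G] = prop
            cov[s * G:(s + 1) * G, nl] = prop.T
        cov[nl, nl] = W @ cov[sl, sl] @ W.T + np.diag(sig ** 2)
    obs = [(idx[g] + t * G, m, s) for (g, t), (m, s) in evidence.items()]
    k = len(obs)
    H = np.zeros((k, D))
    y = np.zeros(k)
    R = np.zeros((k, k))
    for i, (j, m, s) in enumerate(obs):
        H[i, j] = 1.0
        y[i] = m
        R[i, i] = s ** 2
    S = H @ cov @ H.T + R
    K = cov @ H.T @ np.linalg.pinv(S)
    pm = mean + K @ (y - H @ mean)
    pc = cov - K @ H @ cov
    means = pm.reshape(n + 1, G)
    sds = np.sqrt(np.clip(np.diag(pc), 0, None)).reshape(n + 1, G)
    return genes, means, sds


def enumerate_lp_vertices(S, lo, hi):
    """All vertices of {S v = 0, lo <= v <= hi}: fix n-m variables at a
    bound, solve the square system for the rest, keep feasible points."""
    m, n = S.shape
    verts = []
    free_count = np.linalg.matrix_rank(S)
    for fixed_idx in itertools.combinations(range(n), n - free_count):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        if np.linalg.matrix_rank(A) < len(free_idx):
            continue
        for bounds_combo in itertools.product(*[(lo[j], hi[j])
                                                for j in fixed_idx]):
            v = np.zeros(n)
            for j, val in zip(fixed_idx, bounds_combo):
                v[j] = val
            rhs = -S[:, list(fixed_idx)] @ np.array(bounds_combo)
            sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free_idx] = sol
            if np.allclose(S @ v, 0, atol=1e-9) and \
               np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9):
                verts.append(v)
    return verts
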