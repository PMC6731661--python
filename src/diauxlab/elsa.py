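"""Ensemble Learning of Spanning Arborescences (ELSA).

Structure inference for the two-slice DBN: many simple components, each a
maximum-weight spanning arborescence (Edmonds/Chu-Liu) over a lagged
dependency graph built from a double sample (bootstrap over transitions x
random subspace over candidate parents), are aggregated by edge frequency
into a ranking. Edges present in a prior network are kept afloat with a
frequency floor; a postfilter drops edges whose fitted linear-Gaussian
coefficient on the full dataset is negligible. A forward-selection pass can
then add top-ranked edges to a base model when they improve leave-one-out
one-step prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import networkx as nx
import pandas as pd

from .models import RegulatoryDBN
from .dbn import ExpressionDataset, fit_parameters, node_loo_error

VIRTUAL_ROOT = "__root__"


class NoArborescenceError(ValueError):
    def __init__(self, unreachable: Sequence[str]):
        super().__init__(f"nodes unreachable from root: {sorted(unreachable)}")
        self.unreachable = sorted(unreachable)


@dataclass
class RankedEdge:
    parent: str
    child: str
    frequency: float
    weight: float


@dataclass
class EdgeRanking:
    edges: list[RankedEdge]
    ensemble_size: int
    prior_edges: set[tuple[str, str]] = field(default_factory=set)

    def __iter__(self):
        return iter(self.edges)

    def __len__(self):
        return len(self.edges)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([{"parent": e.parent, "child": e.child,
                       "frequency": e.frequency, "weight": e.weight}
                      for e in self.edges]).to_csv(path, sep="\t", index=False)


def dependency_graph(data: ExpressionDataset, candidates: Sequence[str],
                     transitions: Sequence[tuple[int, int]] | None = None,
                     children: Sequence[str] | None = None) -> nx.DiGraph:
    """Lagged dependency digraph: candidate parents -> all genes, edge weight
    |Pearson r| between parent at t and child at t+1. Zero-variance genes get
    zero-weight edges."""
    trans = list(transitions) if transitions is not None else data.transitions()
    if len(trans) < 2:
        raise ValueError("need at least 2 transitions")
    children = list(children) if children is not None else list(data.genes)
    gi = {g: i for i, g in enumerate(data.genes)}
    src = [i for i, _ in trans]
    dst = [j for _, j in trans]
    P = data.values[np.ix_([gi[p] for p in candidates], src)]
    C = data.values[np.ix_([gi[c] for c in children], dst)]
    Pc = P - P.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    sp = np.sqrt((Pc ** 2).sum(axis=1))
    sc = np.sqrt((Cc ** 2).sum(axis=1))
    denom = np.outer(sp, sc)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, (Pc @ Cc.T) / denom, 0.0)
    g = nx.DiGraph()
    g.add_nodes_from(children)
    g.add_nodes_from(candidates)
    for a, p in enumerate(candidates):
        for b, c in enumerate(children):
            if p == c:
                continue
            g.add_edge(p, c, weight=float(abs(corr[a, b])))
    return g


def max_arborescence(graph: nx.DiGraph, root: str) -> set[tuple[str, str]]:
    """Maximum-weight spanning arborescence rooted at ``root``.

    Ties are broken lexicographically on (parent, child) via an epsilon
    bonus far below any meaningful weight difference."""
    if root not in graph:
        raise KeyError(f"root {root} not in graph")
    reachable = nx.descendants(graph, root) | {root}
    missing = set(graph.nodes) - reachable
    if missing:
        raise NoArborescenceError(missing)
    if graph.number_of_nodes() == 1:
        return set()
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    edges = sorted(graph.edges(data="weight"),
                   key=lambda e: (e[0], e[1]))
    m = len(edges)
    for i, (u, v, w) in enumerate(edges):
        if v == root:
            continue  # root keeps no in-edges: arborescence is rooted there
        g.add_edge(u, v, weight=float(w) + (m - i) * 1e-12)
    arb = nx.maximum_spanning_arborescence(g, attr="weight",
                                           preserve_attrs=False)
    return set(arb.edges())


def ensemble_rank(data: ExpressionDataset, prior: RegulatoryDBN | None,
                  K: int = 200, row_frac: float = 0.8, node_frac: float = 0.7,
                  seed: int | None = None, prior_floor: float = 0.5,
                  w_min: float = 0.05, epsilon: float = 1e-6,
                  candidates: Sequence[str] | None = None) -> EdgeRanking:
    """Aggregate K double-sampled arborescence components by edge frequency.

    Each component bootstraps ``row_frac`` of the transitions and uniformly
    subsamples ``node_frac`` of the candidate parents, connects a virtual
    root to every node with weight ``epsilon`` to avoid designating a
    biological root, and keeps the component's non-root edges. Prior edges
    receive at least ``prior_floor`` frequency; the postfilter drops edges
    whose single-parent linear coefficient on the full data is below
    ``w_min`` in magnitude."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (0 < row_frac <= 1 and 0 < node_frac <= 1):
        raise ValueError("fractions must be in (0, 1]")
    if candidates is None:
        if prior is None:
            raise ValueError("need a prior or an explicit candidate set")
        candidates = sorted(g for g in prior.regulators() if g in data.genes)
    else:
        candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidate parent set is empty")
    children = [g for g in data.genes]
    trans = data.transitions()
    n_tr = len(trans)
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    for _ in range(K):
        rows = rng.integers(0, n_tr, size=max(2, round(row_frac * n_tr)))
        sub = sorted(rng.choice(candidates,
                                size=max(1, int(np.ceil(node_frac *
                                                        len(candidates)))),
                                replace=False).tolist())
        g = dependency_graph(data, sub, [trans[i] for i in rows], children)
        g.add_node(VIRTUAL_ROOT)
        for node in children:
            g.add_edge(VIRTUAL_ROOT, node, weight=epsilon)
        for e in max_arborescence(g, VIRTUAL_ROOT):
            if e[0] != VIRTUAL_ROOT:
                counts[e] = counts.get(e, 0) + 1

    freq = {e: c / K for e, c in counts.items()}
    prior_edges: set[tuple[str, str]] = set()
    if prior is not None:
        for e in prior.edges:
            if e.parent in data.genes and e.child in data.genes:
                key = (e.parent, e.child)
                prior_edges.add(key)
                freq[key] = max(freq.get(key, 0.0), prior_floor)

    # postfilter: single-parent lagged regression coefficient on full data
    gi = {g: i for i, g in enumerate(data.genes)}
    src = [i for i, _ in trans]
    dst = [j for _, j in trans]
    kept: list[RankedEdge] = []
    for (p, c), f in freq.items():
        x = data.values[gi[p], src]
        y = data.values[gi[c], dst]
        vx = x.var()
        w = float(np.cov(x, y, bias=True)[0, 1] / vx) if vx > 0 else 0.0
        if abs(w) >= w_min:
            kept.append(RankedEdge(p, c, f, w))
    kept.sort(key=lambda e: (-e.frequency, e.parent, e.child))
    return EdgeRanking(kept, K, prior_edges)


def forward_select(base: RegulatoryDBN, ranking: EdgeRanking,
                   data: ExpressionDataset, max_adds: int,
                   ridge: float = 1e-2,
                   rel_gain: float = 0.05) -> RegulatoryDBN:
    """Greedy forward selection: walk the ranking, keep an edge iff it
    lowers the (exact) leave-one-out one-step prediction error of its child
    node by at least the relative margin ``rel_gain`` (chance fluctuations
    of the LOO error stay well below it; genuinely predictive parents
    reduce it by far more); refit and return after ``max_adds``
    acceptances."""
    structure = base.copy()
    loo_cache: dict[str, float] = {}

    def node_err(node: str, extra: str | None = None) -> float:
        if extra is None and node in loo_cache:
            return loo_cache[node]
        err = node_loo_error(structure, data, node, ridge, extra_parent=extra)
        if extra is None:
            loo_cache[node] = err
        return err
    added = 0
    for e in ranking:
        if added >= max_adds:
            break
        if e.parent == e.child or structure.has_edge(e.parent, e.child):
            continue
        if e.parent not in structure.nodes or e.child not in structure.nodes:
            continue
        if structure.nodes[e.parent].kind != "regulator":
            continue
        if e.child not in data.genes or e.parent not in data.genes:
            continue
        before = node_err(e.child)
        after = node_err(e.child, extra=e.parent)
        if before > 0 and (before - after) / before >= rel_gain:
            structure.add_edge(e.parent, e.child, e.weight)
            loo_cache[e.child] = after
            added += 1
    return fit_parameters(structure, data, ridge)
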