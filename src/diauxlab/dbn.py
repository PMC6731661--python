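"""Inference and fitting for the two-slice linear-Gaussian DBN.

Forward simulation propagates per-gene Gaussian states with a diagonal
(independence) approximation between genes within a slice:

    mu[t+1]  = b + W mu[t]
    var[t+1] = W^2 var[t] + sigma^2   (elementwise)

Backward inference conditions the exact joint linear-Gaussian process on
partial (gene, time) evidence using Kalman filtering plus Rauch-Tung-Striebel
smoothing, so evidence on phenotype-constrained enzymes propagates both
upstream (to regulators) and across time. Degenerate (zero-variance)
directions are handled with pseudo-inverses.

Parameter fitting is per-node ridge regression over one-slice transitions;
leave-one-out prediction error uses the exact hat-matrix identity for linear
smoothers (equivalent to refitting on each leave-one-out fold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import RegulatoryDBN

Evidence = Mapping[tuple[str, int], tuple[float, float]]


class StateError(ValueError):
    pass


class SingularityError(ValueError):
    pass


@dataclass
class GeneStateSlice:
    """Per-gene Gaussian activity state at one time slice."""

    t: int
    mean: dict[str, float]
    sd: dict[str, float]

    def copy(self) -> "GeneStateSlice":
        return GeneStateSlice(self.t, dict(self.mean), dict(self.sd))


@dataclass
class GeneStateTrajectory:
    """Ordered per-gene Gaussian states over slices t = 0..n."""

    genes: list[str]
    means: np.ndarray  # (n+1, G)
    sds: np.ndarray    # (n+1, G)
    direction: str = "forward"

    @property
    def n_steps(self) -> int:
        return self.means.shape[0] - 1

    def index(self, gene: str) -> int:
        return self.genes.index(gene)

    def state(self, gene: str, t: int) -> tuple[float, float]:
        g = self.index(gene)
        return float(self.means[t, g]), float(self.sds[t, g])

    def slice(self, t: int) -> GeneStateSlice:
        return GeneStateSlice(
            t,
            {g: float(self.means[t, i]) for i, g in enumerate(self.genes)},
            {g: float(self.sds[t, i]) for i, g in enumerate(self.genes)})

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product([range(self.means.shape[0]),
                                          ["mean", "sd"]], names=["t", "stat"])
        data = np.empty((self.means.shape[0] * 2, len(self.genes)))
        data[0::2] = self.means
        data[1::2] = self.sds
        return pd.DataFrame(data, index=idx, columns=self.genes)


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with time stamps (hours).

    Samples from several culture episodes may be concatenated; a transition
    (t, t+1) is only used where the time stamps increase, so an episode
    restart (time resetting to 0) breaks the chain.
    """

    genes: list[str]
    times: np.ndarray          # (S,)
    values: np.ndarray         # (G, S)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def transitions(self) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(self.n_samples - 1)
                if self.times[i + 1] > self.times[i]]

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.genes,
                          columns=[f"{t:g}" for t in self.times])
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionDataset":
        # time stamps repeat across episodes, so the header is parsed by
        # hand (pandas would de-duplicate repeated column names)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        times = np.array([float(c) for c in header[1:]])
        df = pd.read_csv(path, sep="\t", header=None, skiprows=1,
                         index_col=0)
        return cls(list(df.index), times, df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Matrix compilation
# ---------------------------------------------------------------------------

class CompiledDBN:
    """Matrix form of a RegulatoryDBN for fast repeated propagation."""

    def __init__(self, dbn: RegulatoryDBN, knockouts: Iterable[str] = ()):
        self.genes = sorted(dbn.nodes)
        self.idx = {g: i for i, g in enumerate(self.genes)}
        G = len(self.genes)
        self.W = np.zeros((G, G))  # W[child, parent]
        for e in dbn.edges:
            self.W[self.idx[e.child], self.idx[e.parent]] = e.weight
        self.b = np.array([dbn.nodes[g].bias for g in self.genes])
        self.sigma = np.array([dbn.nodes[g].sigma for g in self.genes])
        self.init_mean = np.array([dbn.nodes[g].init_mean for g in self.genes])
        self.init_sd = np.array([dbn.nodes[g].init_sd for g in self.genes])
        self.ko_mask = np.zeros(G, dtype=bool)
        for g in knockouts:
            if g not in self.idx:
                raise KeyError(f"unknown knockout gene {g}")
            self.ko_mask[self.idx[g]] = True
        # Knocked-out genes are clamped to (0, 0): zero their dynamics.
        if self.ko_mask.any():
            self.W[self.ko_mask, :] = 0.0
            self.W[:, self.ko_mask] = 0.0
            self.b = np.where(self.ko_mask, 0.0, self.b)
            self.sigma = np.where(self.ko_mask, 0.0, self.sigma)
            self.init_mean = np.where(self.ko_mask, 0.0, self.init_mean)
            self.init_sd = np.where(self.ko_mask, 0.0, self.init_sd)

    def slice_to_arrays(self, s: GeneStateSlice) -> tuple[np.ndarray, np.ndarray]:
        try:
            mu = np.array([s.mean[g] for g in self.genes])
            sd = np.array([s.sd[g] for g in self.genes])
        except KeyError as exc:
            raise StateError(f"slice missing node {exc}") from exc
        return mu, sd

    def step_mean_var(self, mu: np.ndarray, var: np.ndarray):
        mu2 = self.b + self.W @ mu
        var2 = (self.W ** 2) @ var + self.sigma ** 2
        mu2 = np.where(self.ko_mask, 0.0, mu2)
        var2 = np.where(self.ko_mask, 0.0, var2)
        return mu2, var2


def forward_step(dbn: RegulatoryDBN, state: GeneStateSlice,
                 knockouts: Iterable[str] = ()) -> GeneStateSlice:
    """One regulatory step: diagonal Gaussian propagation through the DBN."""
    c = CompiledDBN(dbn, knockouts)
    mu, sd = c.slice_to_arrays(state)
    mu2, var2 = c.step_mean_var(mu, sd ** 2)
    sd2 = np.sqrt(var2)
    return GeneStateSlice(state.t + 1,
                          {g: float(mu2[i]) for g, i in c.idx.items()},
                          {g: float(sd2[i]) for g, i in c.idx.items()})


def initial_slice(dbn: RegulatoryDBN,
                  knockouts: Iterable[str] = ()) -> GeneStateSlice:
    ko = set(knockouts)
    return GeneStateSlice(
        0,
        {g: (0.0 if g in ko else n.init_mean) for g, n in dbn.nodes.items()},
        {g: (0.0 if g in ko else n.init_sd) for g, n in dbn.nodes.items()})


def forward_simulate(dbn: RegulatoryDBN, init: GeneStateSlice | None,
                     n: int, knockouts: Iterable[str] = ()) -> GeneStateTrajectory:
    """Pure regulatory chain of n forward steps (no metabolism, no rules)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    c = CompiledDBN(dbn, knockouts)
    if init is None:
        init = initial_slice(dbn, knockouts)
    mu, sd = c.slice_to_arrays(init)
    mu = np.where(c.ko_mask, 0.0, mu)
    var = np.where(c.ko_mask, 0.0, sd ** 2)
    means = np.empty((n + 1, len(c.genes)))
    vars_ = np.empty_like(means)
    means[0], vars_[0] = mu, var
    for t in range(n):
        mu, var = c.step_mean_var(mu, var)
        means[t + 1], vars_[t + 1] = mu, var
    return GeneStateTrajectory(c.genes, means, np.sqrt(vars_), "forward")


# ---------------------------------------------------------------------------
# Backward inference (Kalman + RTS smoothing, pinv for degenerate noise)
# ---------------------------------------------------------------------------

def backward_infer(dbn: RegulatoryDBN, evidence: Evidence, n_steps: int,
                   knockouts: Iterable[str] = (),
                   init: GeneStateSlice | None = None) -> GeneStateTrajectory:
    """Smoothed posterior over all genes and slices given partial evidence.

    ``evidence`` maps (gene, t) to a Gaussian observation (mean, sd); sd = 0
    means exact observation. With no evidence the forward prior is returned
    (diagonal propagation), as the posterior then equals the prior
    marginal-wise.
    """
    for (g, t), (m, s) in evidence.items():
        if g not in dbn.nodes:
            raise KeyError(f"evidence for unknown gene {g}")
        if not (0 <= t <= n_steps):
            raise KeyError(f"evidence at time {t} outside 0..{n_steps}")
        if s < 0:
            raise ValueError(f"negative evidence SD for ({g}, {t})")
    if not evidence:
        out = forward_simulate(dbn, init, n_steps, knockouts)
        out.direction = "backward"
        return out

    c = CompiledDBN(dbn, knockouts)
    G = len(c.genes)
    by_time: dict[int, list[tuple[int, float, float]]] = {}
    for (g, t), (m, s) in evidence.items():
        by_time.setdefault(t, []).append((c.idx[g], m, s))

    if init is not None:
        m0, sd0 = c.slice_to_arrays(init)
        m0 = np.where(c.ko_mask, 0.0, m0)
        sd0 = np.where(c.ko_mask, 0.0, sd0)
    else:
        m0, sd0 = c.init_mean, c.init_sd
    Q = np.diag(c.sigma ** 2)
    A = c.W

    def observe(m, P, obs):
        k = len(obs)
        H = np.zeros((k, G))
        y = np.zeros(k)
        R = np.zeros((k, k))
        for i, (j, om, os_) in enumerate(obs):
            H[i, j] = 1.0
            y[i] = om
            R[i, i] = os_ ** 2
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.pinv(S, hermitian=True)
        m = m + K @ (y - H @ m)
        P = P - K @ H @ P
        return m, 0.5 * (P + P.T)

    # forward filter
    ms_f = np.empty((n_steps + 1, G))
    Ps_f = np.empty((n_steps + 1, G, G))
    ms_p = np.empty_like(ms_f)   # one-step predictions
    Ps_p = np.empty_like(Ps_f)
    m, P = m0.copy(), np.diag(sd0 ** 2)
    ms_p[0], Ps_p[0] = m, P
    if 0 in by_time:
        m, P = observe(m, P, by_time[0])
    ms_f[0], Ps_f[0] = m, P
    for t in range(1, n_steps + 1):
        m = c.b + A @ m
        P = A @ P @ A.T + Q
        m = np.where(c.ko_mask, 0.0, m)
        ms_p[t], Ps_p[t] = m, P
        if t in by_time:
            m, P = observe(m, P, by_time[t])
        ms_f[t], Ps_f[t] = m, P

    # RTS smoother
    ms_s = ms_f.copy()
    Ps_s = Ps_f.copy()
    for t in range(n_steps - 1, -1, -1):
        Gk = Ps_f[t] @ A.T @ np.linalg.pinv(Ps_p[t + 1], hermitian=True)
        ms_s[t] = ms_f[t] + Gk @ (ms_s[t + 1] - ms_p[t + 1])
        Ps_s[t] = Ps_f[t] + Gk @ (Ps_s[t + 1] - Ps_p[t + 1]) @ Gk.T
    means = ms_s
    sds = np.sqrt(np.maximum(np.stack([np.diag(Ps_s[t])
                                       for t in range(n_steps + 1)]), 0.0))
    means[:, c.ko_mask] = 0.0
    sds[:, c.ko_mask] = 0.0
    return GeneStateTrajectory(c.genes, means, sds, "backward")


# ---------------------------------------------------------------------------
# Parameter fitting and leave-one-out error
# ---------------------------------------------------------------------------

def _design(dbn: RegulatoryDBN, data: ExpressionDataset, node: str,
            extra_parent: str | None = None):
    parents = [e.parent for e in dbn.parent_map()[node]]
    if extra_parent is not None and extra_parent not in parents:
        parents = parents + [extra_parent]
    trans = data.transitions()
    gi = {g: k for k, g in enumerate(data.genes)}
    src = [i for i, _ in trans]
    dst = [j for _, j in trans]
    if parents:
        X = data.values[np.ix_([gi[p] for p in parents], src)].T
    else:
        X = np.empty((len(src), 0))
    y = data.values[gi[node], dst]
    return parents, X, y


def _ridge_fit(X: np.ndarray, y: np.ndarray, ridge: float):
    """Ridge regression with unpenalized intercept. Returns (w, b, resid)."""
    n, p = X.shape
    A = np.hstack([X, np.ones((n, 1))])
    D = np.diag([ridge] * p + [0.0])
    M = A.T @ A + D
    if ridge == 0.0 and np.linalg.matrix_rank(M) < p + 1:
        raise SingularityError(
            "fewer independent transitions than parameters with ridge=0")
    theta = np.linalg.solve(M, A.T @ y)
    resid = y - A @ theta
    return theta[:p], float(theta[p]), resid


def fit_parameters(structure: RegulatoryDBN, data: ExpressionDataset,
                   ridge: float = 1e-2) -> RegulatoryDBN:
    """Fit (bias, weights, sigma) per node by ridge-penalized least squares
    over the dataset's one-slice transitions; the structure is fixed."""
    if len(data.transitions()) < 2:
        raise ValueError("need at least 2 transitions")
    out = structure.copy()
    weights: dict[tuple[str, str], float] = {}
    for node in sorted(out.nodes):
        if node not in data.genes:
            continue
        parents, X, y = _design(out, data, node)
        w, b, resid = _ridge_fit(X, y, ridge)
        out.nodes[node].bias = b
        out.nodes[node].sigma = float(np.sqrt(np.mean(resid ** 2)))
        for p, wi in zip(parents, w):
            weights[(p, node)] = float(wi)
    for e in out.edges:
        if (e.parent, e.child) in weights:
            e.weight = weights[(e.parent, e.child)]
    return out


def node_loo_error(dbn: RegulatoryDBN, data: ExpressionDataset, node: str,
                   ridge: float = 1e-2,
                   extra_parent: str | None = None) -> float:
    """Exact leave-one-transition-out squared prediction error for one node.

    Uses the hat-matrix identity e_loo = e / (1 - h_ii), which equals
    refitting the ridge model on each fold.
    """
    parents, X, y = _design(dbn, data, node, extra_parent)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 transitions for LOO")
    A = np.hstack([X, np.ones((n, 1))])
    D = np.diag([ridge] * p + [0.0])
    M = A.T @ A + D
    if ridge == 0.0 and np.linalg.matrix_rank(M) < p + 1:
        raise SingularityError("singular design with ridge=0")
    Minv = np.linalg.inv(M)
    H = A @ Minv @ A.T
    theta = Minv @ (A.T @ y)
    resid = y - A @ theta
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    loo = resid / (1.0 - h)
    return float(np.mean(loo ** 2))


def loo_prediction_error(dbn: RegulatoryDBN, data: ExpressionDataset,
                         ridge: float = 1e-2) -> float:
    """Mean squared one-step-ahead LOO prediction error over all nodes."""
    nodes = [g for g in sorted(dbn.nodes) if g in data.genes]
    return float(np.mean([node_loo_error(dbn, data, g, ridge) for g in nodes]))
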