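"""Experiment selection: active, coregulation-driven and discriminative.

Three designers propose knockout strains:

* ``adactive_rank`` (active learning): compares two phenotype-constrained
  posteriors over gene states - one conditioned on the growth parameters the
  model itself predicts, one conditioned on the observed growth parameters -
  and ranks genes by the summed per-slice Kullback-Leibler divergence
  between them. With self-generated evidence the two posteriors coincide and
  every divergence is exactly zero; a discrepancy between model and reality
  concentrates divergence on the genes that have to move to explain the
  observed growth. Evidence enters through the inverse DFBA mode
  (growth-rate-pinned flux variability -> enzyme activity Gaussians) and is
  propagated to regulators by exact Gaussian smoothing.

* ``coregmine_select``: builds regulator influence profiles from expression
  data and a coregulation graph from shared targets, finds dense same-class
  subgraphs, and returns the active->inactive regulators bordering an
  antagonistic (inactive->active) subgraph.

* ``adana_disagreement`` / ``adana_importance``: discriminative design
  between two rival models (largest predicted post-shift growth-rate
  disagreement per deletant) and gene importance in a single model
  (knockout effect on post-shift growth plus strong outgoing regulation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import networkx as nx

from .models import HybridModel
from .dbn import ExpressionDataset, backward_infer
from .dfba import bounds_from_growth
from .phenotype import GrowthParameters
from .simulate import simulate_strain, predicted_growth_params

SD_MIN = 1e-3


@dataclass
class DivergenceScore:
    """Per-gene total divergence with the per-(gene, time) matrix retained."""

    genes: list[str]
    per_time: np.ndarray  # (T+1, G)
    total: dict[str, float]


@dataclass
class InfluenceProfile:
    regulator: str
    influence: np.ndarray       # signed, per time point
    labels: np.ndarray          # active (True) / inactive (False)
    transition: str             # "active->inactive" | "inactive->active" | "stable"


def gaussian_kl(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """KL(N(mu1, sd1^2) || N(mu2, sd2^2))."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return (math.log(sd2 / sd1) +
            (sd1 ** 2 + (mu1 - mu2) ** 2) / (2 * sd2 ** 2) - 0.5)


def _growth_evidence(model: HybridModel, growth: GrowthParameters,
                     n_steps: int, dt: float,
                     sd_min: float = SD_MIN) -> dict[tuple[str, int], tuple[float, float]]:
    """Per-(enzyme gene, slice) activity evidence from a growth-curve fit.

    The observed pre-shift rate constrains slices before the observed shift
    time, the post-shift rate the slices after it; each distinct
    (rate, phase) pair is translated once through the fixed-growth inverse
    DFBA. Post-shift the glucose pool is exhausted, so reactions consuming
    the glucose metabolite are closed in the inverse problem - the observed
    respiratory rate must then be explained by the alternative carbon
    route."""
    from .dfba import default_bounds

    met = model.metabolic
    post_bounds = default_bounds(met)
    if met.glucose_metabolite is not None:
        for r, rx in met.reactions.items():
            if rx.stoichiometry.get(met.glucose_metabolite, 0.0) < 0:
                post_bounds[r] = (0.0, 0.0)
    cache: dict[tuple[float, bool], dict[str, tuple[float, float]]] = {}

    def enzyme_evidence(mu: float, post: bool):
        key = (max(0.0, round(mu, 12)), post)
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cache[key] = bounds_from_growth(
                    met, key[0], bounds=post_bounds if post else None,
                    sd_min=sd_min)
        return cache[key]

    shift = growth.shift_time if growth.shift_detected else math.inf
    evidence: dict[tuple[str, int], tuple[float, float]] = {}
    for t in range(1, n_steps + 1):
        post = t * dt > shift
        rate = growth.post_rate if post else growth.pre_rate
        for g, ms in enzyme_evidence(rate, post).items():
            if g not in model.knocked_out:
                evidence[(g, t)] = ms
    return evidence


def adactive_rank(model: HybridModel, observed: GrowthParameters,
                  horizon: float, dt: float,
                  candidates: Sequence[str] | None = None,
                  sd_min: float = SD_MIN,
                  mode: str = "sum") -> tuple[list[tuple[str, float]], DivergenceScore]:
    """Rank knockout candidates by forward/backward state divergence.

    Returns (ranked [(gene, D)] sorted by descending divergence with
    lexicographic tie-break, full DivergenceScore). Knocked-out genes and
    rule-clamped (gene, time) pairs are excluded from the sums; candidate
    genes default to the model's regulators."""
    sim = simulate_strain(model, horizon, dt)
    n_steps = len(sim.states) - 1
    predicted = predicted_growth_params(sim)
    ev_pred = _growth_evidence(model, predicted, n_steps, dt, sd_min)
    ev_obs = _growth_evidence(model, observed, n_steps, dt, sd_min)
    # metabolite-rule-clamped states are known givens of the simulation, not
    # inferable quantities: pin them in both posteriors so divergence cannot
    # leak through them to their descendants
    for (g, t) in sim.rule_clamped:
        i = sim.trajectory.index(g)
        pin = (float(sim.trajectory.means[t, i]),
               float(sim.trajectory.sds[t, i]))
        ev_pred[(g, t)] = pin
        ev_obs[(g, t)] = pin
    fwd = backward_infer(model.regulatory, ev_pred, n_steps,
                         knockouts=model.knocked_out)
    bwd = backward_infer(model.regulatory, ev_obs, n_steps,
                         knockouts=model.knocked_out)
    genes = fwd.genes
    G = len(genes)
    D = np.zeros((n_steps + 1, G))
    for t in range(n_steps + 1):
        for i, g in enumerate(genes):
            if g in model.knocked_out or (g, t) in sim.rule_clamped:
                continue
            D[t, i] = gaussian_kl(fwd.means[t, i],
                                  max(fwd.sds[t, i], sd_min),
                                  bwd.means[t, i],
                                  max(bwd.sds[t, i], sd_min))
    if mode == "sum":
        total = D.sum(axis=0)
    elif mode == "max":
        total = D.max(axis=0)
    else:
        raise ValueError("mode must be 'sum' or 'max'")
    score = DivergenceScore(genes, D, {g: float(total[i])
                                       for i, g in enumerate(genes)})
    # secondary key: phenotype-coupling information gain - how strongly the
    # growth evidence constrains each gene relative to the (rule-aware)
    # simulated forward trajectory. When the model already explains the
    # observations (all divergences ~0) the most phenotype-coupled genes are
    # still the most informative knockouts.
    prior = sim.trajectory
    info = np.zeros(len(genes))
    for t in range(n_steps + 1):
        for i, g in enumerate(genes):
            if g in model.knocked_out or (g, t) in sim.rule_clamped:
                continue
            info[i] += gaussian_kl(bwd.means[t, i],
                                   max(bwd.sds[t, i], sd_min),
                                   prior.means[t, i],
                                   max(prior.sds[t, i], sd_min))
    if candidates is None:
        candidates = [g for g in model.regulatory.regulators()
                      if g not in model.knocked_out]
    gidx = {g: i for i, g in enumerate(genes)}
    ranked = sorted(((g, score.total[g]) for g in candidates),
                    key=lambda kv: (-kv[1], -info[gidx[kv[0]]], kv[0]))
    return ranked, score


# ---------------------------------------------------------------------------
# CoRegMine (simplified coregulation miner)
# ---------------------------------------------------------------------------

def influence_profiles(data: ExpressionDataset,
                       targets: Mapping[str, tuple[set, set]],
                       shift_index: int | None = None
                       ) -> dict[str, InfluenceProfile]:
    """Signed influence of each regulator over time.

    Influence(t) = mean standardized expression of activated targets minus
    mean standardized expression of repressed targets; the binary label is
    influence > 0 and the transition class compares the majority label
    before vs after ``shift_index`` (dataset midpoint by default)."""
    S = data.n_samples
    mid = shift_index if shift_index is not None else S // 2
    z = data.values - data.values.mean(axis=1, keepdims=True)
    sd = data.values.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, z / sd, 0.0)
    gi = {g: i for i, g in enumerate(data.genes)}
    out: dict[str, InfluenceProfile] = {}
    for reg, (act, rep) in targets.items():
        act_i = [gi[g] for g in act if g in gi]
        rep_i = [gi[g] for g in rep if g in gi]
        if not act_i and not rep_i:
            warnings.warn(f"regulator {reg} has no expressed targets")
            infl = np.zeros(S)
        else:
            a = z[act_i].mean(axis=0) if act_i else np.zeros(S)
            r = z[rep_i].mean(axis=0) if rep_i else np.zeros(S)
            infl = a - r
        labels = infl > 0
        pre = labels[:mid].mean() > 0.5 if mid > 0 else False
        post = labels[mid:].mean() > 0.5 if mid < S else False
        if pre and not post:
            cls = "active->inactive"
        elif post and not pre:
            cls = "inactive->active"
        else:
            cls = "stable"
        out[reg] = InfluenceProfile(reg, infl, labels, cls)
    return out


def _dense_cores(graph: nx.Graph, members: list[str],
                 d_min: float) -> list[set[str]]:
    """Greedy min-degree peeling of each connected component until the
    induced subgraph reaches density >= d_min (pairs count as density 1)."""
    cores = []
    sub = graph.subgraph(members).copy()
    for comp in nx.connected_components(sub):
        h = sub.subgraph(comp).copy()
        while h.number_of_nodes() > 2:
            n, m = h.number_of_nodes(), h.number_of_edges()
            if 2 * m / (n * (n - 1)) >= d_min:
                break
            drop = min(h.degree, key=lambda kv: (kv[1], kv[0]))[0]
            h.remove_node(drop)
        if h.number_of_nodes() >= 2:
            cores.append(set(h.nodes))
    return cores


def coregmine_select(profiles: Mapping[str, InfluenceProfile],
                     targets: Mapping[str, tuple[set, set]],
                     j_min: float = 0.3, d_min: float = 0.6) -> list[str]:
    """Border regulators between antagonistic dense coregulation subgraphs.

    Builds the coregulation graph (target-set Jaccard >= j_min), extracts
    dense cores uniform in transition class, and for every antagonistic core
    pair joined by at least one edge returns the active->inactive side's
    nodes adjacent to the other side, ordered by cross-edge count."""
    regs = sorted(set(profiles) & set(targets))
    if len(regs) < 2:
        raise ValueError("need at least 2 regulators")
    tsets = {r: set(targets[r][0]) | set(targets[r][1]) for r in regs}
    g = nx.Graph()
    g.add_nodes_from(regs)
    for i, u in enumerate(regs):
        for v in regs[i + 1:]:
            union = tsets[u] | tsets[v]
            if union:
                jac = len(tsets[u] & tsets[v]) / len(union)
                if jac >= j_min:
                    g.add_edge(u, v)
    ai = [r for r in regs if profiles[r].transition == "active->inactive"]
    ia = [r for r in regs if profiles[r].transition == "inactive->active"]
    cores_ai = _dense_cores(g, ai, d_min)
    cores_ia = _dense_cores(g, ia, d_min)
    border_count: dict[str, int] = {}
    for ca in cores_ai:
        for cb in cores_ia:
            for u in ca:
                n_cross = sum(1 for v in cb if g.has_edge(u, v))
                if n_cross:
                    border_count[u] = border_count.get(u, 0) + n_cross
    return sorted(border_count, key=lambda r: (-border_count[r], r))


# ---------------------------------------------------------------------------
# Adana (discriminative design & gene importance)
# ---------------------------------------------------------------------------

def _postshift(model: HybridModel, genes: frozenset, horizon: float,
               dt: float) -> float:
    from .models import apply_knockout

    m = apply_knockout(model, genes) if genes else model
    return predicted_growth_params(simulate_strain(m, horizon, dt)).post_rate


def adana_disagreement(model_a: HybridModel, model_b: HybridModel,
                       candidates: Sequence[str], k: int,
                       horizon: float = 45.0,
                       dt: float = 0.5) -> list[tuple[str, float]]:
    """Top-k deletant strains with the largest predicted post-shift
    growth-rate disagreement between two rival models."""
    scores = []
    for g in sorted(candidates):
        try:
            d = abs(_postshift(model_a, frozenset({g}), horizon, dt) -
                    _postshift(model_b, frozenset({g}), horizon, dt))
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"skipping strain d{g}: {exc}")
            continue
        scores.append((g, float(d)))
    scores.sort(key=lambda kv: (-kv[1], kv[0]))
    return scores[:k]


def adana_importance(model: HybridModel, genes: Sequence[str],
                     horizon: float = 45.0, dt: float = 0.5,
                     lambda_c: float = 0.1,
                     w_display: float = 0.3) -> list[tuple[str, float]]:
    """Gene importance: knockout effect on post-shift growth plus
    lambda_c times the summed magnitude of strong outgoing edges
    (|w| > w_display)."""
    wt = _postshift(model, frozenset(), horizon, dt)
    out_w: dict[str, float] = {}
    for e in model.regulatory.edges:
        if abs(e.weight) > w_display:
            out_w[e.parent] = out_w.get(e.parent, 0.0) + abs(e.weight)
    scores = []
    for g in sorted(genes):
        imp = abs(wt - _postshift(model, frozenset({g}), horizon, dt))
        imp += lambda_c * out_w.get(g, 0.0)
        scores.append((g, float(imp)))
    scores.sort(key=lambda kv: (-kv[1], kv[0]))
    return scores


def random_design(candidates: Sequence[str], k: int,
                  seed: int | None = None) -> list[str]:
    """Uniform sample of k strains without replacement (seeded)."""
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    rng = np.random.default_rng(seed)
    return [str(g) for g in rng.choice(sorted(candidates), size=k,
                                       replace=False)]
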