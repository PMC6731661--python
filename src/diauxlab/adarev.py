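"""Greedy validated model refinement from knockout growth phenotypes.

The error currency is the post-shift (respiratory) specific growth rate:
for every observed deletant strain the model's prediction error is
|predicted - observed| post-shift rate. A cheap prior scoring step ranks
regulatory edges for removal - an edge is a candidate for a strain when it
touches the descendant cone of the strain's deleted gene(s) or the ancestor
cone of a metabolite-rule target, weighted by |w| and summed over the
worst-predicted quartile of strains. Removals are then validated greedily:
an edge is deleted only if re-simulating every observed strain lowers the
mean absolute error by at least ``min_gain``; the ranking is recomputed
after each accepted removal. Simulations are memoized on
(removed edge set, strain), so re-ranking passes stay affordable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .models import HybridModel, apply_knockout
from .phenotype import GrowthParameters
from .simulate import simulate_strain, predicted_growth_params

MIN_GAIN = 1e-4  # h^-1; guards acceptance against float noise


@dataclass
class StrainObservation:
    genes: frozenset
    params: GrowthParameters
    replicates: int = 1
    source: str = "virtual"

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass
class RevisionStep:
    edge: tuple[str, str]
    accepted: bool
    error_before: float
    error_after: float


@dataclass
class RevisionTrace:
    steps: list[RevisionStep] = field(default_factory=list)
    initial_error: float = math.nan
    final_error: float = math.nan

    def accepted_edges(self) -> list[tuple[str, str]]:
        return [s.edge for s in self.steps if s.accepted]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([{"parent": s.edge[0], "child": s.edge[1],
                       "accepted": s.accepted,
                       "error_before": s.error_before,
                       "error_after": s.error_after}
                      for s in self.steps]).to_csv(path, sep="\t", index=False)


class _PredictionCache:
    """Memoize post-shift predictions on (removed edges, knockout set)."""

    def __init__(self, base: HybridModel, horizon: float, dt: float):
        self.base = base
        self.horizon = horizon
        self.dt = dt
        self._memo: dict[tuple, float] = {}

    def postshift(self, removed: frozenset, genes: frozenset) -> float:
        key = (removed, genes)
        if key not in self._memo:
            model = self.base.copy()
            for p, c in removed:
                model.regulatory.remove_edge(p, c)
            if genes:
                model = apply_knockout(model, genes)
            params = predicted_growth_params(
                simulate_strain(model, self.horizon, self.dt))
            self._memo[key] = params.post_rate
        return self._memo[key]


def postshift_error(model: HybridModel,
                    observations: Sequence[StrainObservation],
                    horizon: float = 45.0, dt: float = 0.5,
                    _cache: _PredictionCache | None = None,
                    _removed: frozenset = frozenset()
                    ) -> tuple[dict[frozenset, float], float]:
    """Per-strain |predicted - observed| post-shift growth rate and its mean.

    Strains whose simulation fails are excluded (with a warning) and do not
    enter the mean."""
    if not observations:
        raise ValueError("need at least one observation")
    cache = _cache or _PredictionCache(model, horizon, dt)
    errors: dict[frozenset, float] = {}
    for obs in observations:
        try:
            pred = cache.postshift(_removed, obs.genes)
        except Exception as exc:
            warnings.warn(f"simulation failed for strain "
                          f"{sorted(obs.genes)}: {exc}; excluded")
            continue
        errors[obs.genes] = abs(pred - obs.params.post_rate)
    mae = sum(errors.values()) / len(errors) if errors else math.nan
    return errors, mae


def score_candidate_removals(model: HybridModel,
                             observations: Sequence[StrainObservation],
                             errors: dict[frozenset, float] | None = None,
                             horizon: float = 45.0, dt: float = 0.5
                             ) -> list[tuple[tuple[str, str], float]]:
    """Rank regulatory edges for removal without any new simulation.

    Only the worst-predicted quartile of strains contributes; an edge scores
    |w| per such strain when it touches the deleted genes' descendant cone
    or the ancestor cone of the phenotype-coupled genes (metabolite-rule
    targets and gene-reaction-rule enzymes). All-zero errors yield no
    candidates."""
    if errors is None:
        errors, _ = postshift_error(model, observations, horizon, dt)
    worst = [s for s, e in sorted(errors.items(),
                                  key=lambda kv: -kv[1]) if e > 1e-9]
    worst = worst[: max(1, math.ceil(len(errors) / 4))] if worst else []
    if not worst:
        return []
    g = nx.DiGraph()
    g.add_nodes_from(model.regulatory.nodes)
    g.add_edges_from((e.parent, e.child) for e in model.regulatory.edges)
    # phenotype-relevant cone: ancestors of metabolite-rule targets and of
    # the enzymes wired into gene-reaction rules
    from .models import rule_genes

    relevant = {r.target for r in model.rules}
    for rule in model.metabolic.gene_rules.values():
        relevant |= rule_genes(rule)
    anc = set(relevant)
    for t in relevant:
        if t in g:
            anc |= nx.ancestors(g, t)
    scores: dict[tuple[str, str], float] = {}
    desc_cache: dict[frozenset, set] = {}
    for strain in worst:
        if strain not in desc_cache:
            cone = set(strain)
            for gene in strain:
                if gene in g:
                    cone |= nx.descendants(g, gene)
            desc_cache[strain] = cone
        cone = desc_cache[strain]
        for e in model.regulatory.edges:
            touches = (e.parent in cone or e.child in cone or
                       e.parent in anc or e.child in anc)
            if touches:
                key = (e.parent, e.child)
                scores[key] = scores.get(key, 0.0) + abs(e.weight)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked


def refine(model: HybridModel, observations: Sequence[StrainObservation],
           max_evals: int = 20, min_gain: float = MIN_GAIN,
           horizon: float = 45.0, dt: float = 0.5
           ) -> tuple[HybridModel, RevisionTrace]:
    """Greedy validated edge removal.

    Iterates the removal ranking, re-simulating all observed strains for each
    tentative removal; accepts when the mean absolute post-shift error drops
    by at least ``min_gain``, re-ranks after each acceptance, and stops when
    ``max_evals`` tentative removals have been simulated or no candidate
    improves. A rejected edge is not retried (the simulation budget is spent
    on untested candidates)."""
    if max_evals < 1:
        raise ValueError("max_evals must be >= 1")
    cache = _PredictionCache(model, horizon, dt)
    removed: frozenset = frozenset()
    errors, err = postshift_error(model, observations, horizon, dt,
                                  _cache=cache, _removed=removed)
    trace = RevisionTrace(initial_error=err)
    evals = 0
    current = model.copy()
    rejected: set[tuple[str, str]] = set()

    def trial_error(trial: frozenset):
        """Mean error for a tentative removal, aborting as soon as the
        running total guarantees rejection (same decision, fewer sims)."""
        budget = len(observations) * (err - min_gain) + 1e-15
        total = 0.0
        out: dict[frozenset, float] = {}
        for obs in observations:
            try:
                pred = cache.postshift(trial, obs.genes)
            except Exception as exc:
                warnings.warn(f"simulation failed for strain "
                              f"{sorted(obs.genes)}: {exc}; excluded")
                continue
            e = abs(pred - obs.params.post_rate)
            out[obs.genes] = e
            total += e
            if total > budget:
                return None, math.inf
        n = len(out)
        return out, (total / n if n else math.nan)

    while evals < max_evals:
        candidates = score_candidate_removals(current, observations,
                                              errors=errors)
        improved = False
        for (edge, _s) in candidates:
            if edge in rejected:
                continue
            if evals >= max_evals:
                break
            trial = removed | {edge}
            errors2, err2 = trial_error(trial)
            evals += 1
            accept = errors2 is not None and err - err2 >= min_gain
            trace.steps.append(RevisionStep(edge, accept, err, err2))
            if accept:
                removed = trial
                current.regulatory.remove_edge(*edge)
                errors, err = errors2, err2
                improved = True
                break
            rejected.add(edge)
        if not improved:
            break
    trace.final_error = err
    return current, trace
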