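"""Closed-loop improvement cycles: design -> experiment -> refine -> evaluate.

One cycle takes a working model and a source of experiments (here the
virtual laboratory standing in for a robotic platform), selects ``k``
knockout strains with a design method, observes their growth phenotypes,
refines the model by validated edge removal against those observations, and
scores the refinement on a held-out strain set disjoint from the training
strains (post-shift growth-rate MAE, error-reduction ratio and a paired
Wilcoxon test). Every stage is seeded, so a report is reproducible from
(config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .models import HybridModel
from .virtual_lab import LabConfig, observe_strain, generate_expression_dataset
from .design import (adactive_rank, adana_disagreement, coregmine_select,
                     influence_profiles, random_design)
from .adarev import StrainObservation, refine, postshift_error, RevisionTrace
from .phenotype import compare_models

METHODS = ("adactive", "coregmine", "adana", "random")


@dataclass
class CycleConfig:
    seed: int
    method: str = "adactive"
    k: int = 20
    max_evals: int = 10
    candidates: list[str] | None = None      # default: model regulators
    eval_strains: list[str] | None = None    # default: candidates not selected
    rival_model: HybridModel | None = None   # for method == "adana"


@dataclass
class CycleReport:
    method: str
    seed: int
    selected: list[str]
    eval_strains: list[str]
    n_revisions: int
    error_before: float
    error_after: float
    ratio: float
    wilcoxon_p: float
    per_strain_before: dict[str, float] = field(default_factory=dict)
    per_strain_after: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _targets_from_model(model: HybridModel) -> dict[str, tuple[set, set]]:
    """Regulator -> (activated targets, repressed targets) from edge signs."""
    targets: dict[str, tuple[set, set]] = {}
    for e in model.regulatory.edges:
        act, rep = targets.setdefault(e.parent, (set(), set()))
        (act if e.weight > 0 else rep).add(e.child)
    return targets


def design_strains(model: HybridModel, truth: HybridModel, lab: LabConfig,
                   config: CycleConfig,
                   candidates: Sequence[str]) -> list[str]:
    """Pick k training strains with the configured design method."""
    method = config.method
    if method not in METHODS:
        raise ValueError(f"unknown design method {method!r}")
    k = min(config.k, len(candidates))
    if method == "random":
        return random_design(candidates, k, seed=config.seed)
    if method == "adactive":
        observed = observe_strain(truth, set(), lab, seed=config.seed)
        ranked, _ = adactive_rank(model, observed, lab.horizon, lab.dt,
                                  candidates=list(candidates))
        return [g for g, _ in ranked[:k]]
    if method == "adana":
        if config.rival_model is None:
            raise ValueError("adana needs a rival model")
        ranked = adana_disagreement(model, config.rival_model, candidates, k,
                                    lab.horizon, lab.dt)
        return [g for g, _ in ranked]
    # coregmine: antagonistic border regulators first, random fill after
    data = generate_expression_dataset(truth, lab, seed=config.seed)
    targets = _targets_from_model(model)
    targets = {r: t for r, t in targets.items() if r in candidates}
    picked: list[str] = []
    if len(targets) >= 2:
        profiles = influence_profiles(data, targets)
        picked = [g for g in coregmine_select(profiles, targets)
                  if g in candidates][:k]
    rest = [g for g in candidates if g not in picked]
    if len(picked) < k and rest:
        picked += random_design(rest, k - len(picked), seed=config.seed)
    return picked


def run_cycle(model: HybridModel, truth: HybridModel, lab: LabConfig,
              config: CycleConfig) -> tuple[HybridModel, CycleReport, RevisionTrace]:
    """Run one full improvement cycle against the virtual laboratory.

    Evaluation strains are disjoint from the training strains by
    construction (audited)."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]
    candidates = (sorted(config.candidates) if config.candidates is not None
                  else sorted(g for g in model.regulatory.nodes
                              if g not in model.knocked_out))
    selected = design_strains(model, truth, lab, config, candidates)

    obs = [StrainObservation(frozenset({g}),
                             observe_strain(truth, {g}, lab,
                                            seed=seeds[0] + i))
           for i, g in enumerate(selected)]
    refined, trace = refine(model, obs, max_evals=config.max_evals,
                            horizon=lab.horizon, dt=lab.dt)

    eval_strains = (sorted(config.eval_strains)
                    if config.eval_strains is not None
                    else [g for g in candidates if g not in selected])
    overlap = set(eval_strains) & set(selected)
    if overlap:
        raise ValueError(f"evaluation strains overlap training: {overlap}")
    eval_obs = [StrainObservation(frozenset({g}),
                                  observe_strain(truth, {g}, lab,
                                                 seed=seeds[1] + i))
                for i, g in enumerate(eval_strains)]
    before, mae_before = postshift_error(model, eval_obs, lab.horizon, lab.dt)
    after, mae_after = postshift_error(refined, eval_obs, lab.horizon, lab.dt)
    common = sorted(set(before) & set(after))
    if len(common) >= 5:
        ratio, p = compare_models([before[s] for s in common],
                                  [after[s] for s in common])
    else:
        ratio = (0.0 if mae_before == 0
                 else (mae_before - mae_after) / mae_before)
        p = math.nan
    report = CycleReport(
        method=config.method, seed=config.seed, selected=list(selected),
        eval_strains=list(eval_strains),
        n_revisions=len(trace.accepted_edges()),
        error_before=mae_before, error_after=mae_after,
        ratio=ratio, wilcoxon_p=p,
        per_strain_before={"_".join(sorted(s)): e for s, e in before.items()},
        per_strain_after={"_".join(sorted(s)): e for s, e in after.items()})
    return refined, report, trace
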