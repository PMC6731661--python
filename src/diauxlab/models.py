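"""Domain types for hybrid regulatory-metabolic models.

A hybrid model couples a two-slice dynamic Bayesian network (DBN) with
linear-Gaussian conditionals over regulator and enzyme genes to a
constraint-based (stoichiometric) metabolic model via two bridges:

* gene->reaction rules: boolean expressions over enzyme genes that scale
  reaction flux bounds by the (clipped) gene activity;
* metabolite->gene rules: threshold rules on extracellular metabolite
  concentrations that overwrite a target gene's state on the next slice
  (e.g. glucose exhaustion activating the diauxic-shift regulator).

Models serialize to a single versioned JSON document; the metabolic part
can alternatively be imported from SBML (with fbc bounds and gene-product
associations) through cobrapy.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

MODEL_VERSION = "1.0"

REGULATOR = "regulator"
ENZYME = "enzyme"

# A gene-reaction rule is either a gene id (str) or a nested boolean
# expression encoded as ["and", r1, r2, ...] / ["or", r1, r2, ...].
Rule = Union[str, list]


class FormatError(ValueError):
    """Raised when a model file cannot be parsed into the schema."""


class ValidationError(ValueError):
    """Raised when a parsed model violates structural invariants."""

    def __init__(self, violations: Sequence[str]):
        super().__init__("; ".join(violations))
        self.violations = list(violations)


@dataclass
class Node:
    """A gene in the regulatory DBN.

    ``bias`` and ``sigma`` parameterize the linear-Gaussian conditional
    x[t+1] = bias + sum_p w_p x_p[t] + N(0, sigma^2); ``init_mean`` and
    ``init_sd`` give the state at slice 0. Activity is nominally in [0, 1]
    but states are unbounded Gaussians.
    """

    kind: str
    bias: float = 0.0
    sigma: float = 0.05
    init_mean: float = 0.0
    init_sd: float = 0.0


@dataclass
class Edge:
    parent: str
    child: str
    weight: float


@dataclass
class RegulatoryDBN:
    """Two-slice DBN: every edge connects slice t to slice t+1 (lag one)."""

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    def regulators(self) -> list[str]:
        return [g for g, n in self.nodes.items() if n.kind == REGULATOR]

    def enzymes(self) -> list[str]:
        return [g for g, n in self.nodes.items() if n.kind == ENZYME]

    def parent_map(self) -> dict[str, list[Edge]]:
        pm: dict[str, list[Edge]] = {g: [] for g in self.nodes}
        for e in self.edges:
            pm.setdefault(e.child, []).append(e)
        return pm

    def has_edge(self, parent: str, child: str) -> bool:
        return any(e.parent == parent and e.child == child for e in self.edges)

    def add_edge(self, parent: str, child: str, weight: float) -> None:
        if self.has_edge(parent, child):
            raise ValueError(f"duplicate edge {parent}->{child}")
        self.edges.append(Edge(parent, child, weight))

    def remove_edge(self, parent: str, child: str) -> None:
        before = len(self.edges)
        self.edges = [e for e in self.edges
                      if not (e.parent == parent and e.child == child)]
        if len(self.edges) == before:
            raise KeyError(f"no edge {parent}->{child}")

    def copy(self) -> "RegulatoryDBN":
        return copy.deepcopy(self)


@dataclass
class Metabolite:
    id: str
    external: bool = False


@dataclass
class Reaction:
    """Stoichiometry maps metabolite id -> coefficient (negative = consumed).

    Default bounds are in mmol gDW^-1 h^-1.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    reversible: bool = False


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction: str = ""
    gene_rules: dict[str, Rule] = field(default_factory=dict)
    # Monod/Michaelis-Menten uptake kinetics per external metabolite:
    # id -> (Vmax mmol/gDW/h, Km mM). Reactions consuming the metabolite
    # have their upper bound capped at Vmax*c/(Km+c) during dynamic FBA.
    uptake_kinetics: dict[str, tuple[float, float]] = field(default_factory=dict)
    # Experiment context: starting medium (mM) and inoculum (gDW/L).
    medium: dict[str, float] = field(default_factory=dict)
    initial_biomass: float = 0.01
    glucose_metabolite: str | None = None

    def internal_metabolites(self) -> list[str]:
        return [m for m, spec in self.metabolites.items() if not spec.external]

    def external_metabolites(self) -> list[str]:
        return [m for m, spec in self.metabolites.items() if spec.external]

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self):
        """Return (S, internal metabolite ids, reaction ids).

        One row per internal metabolite, one column per reaction.
        """
        import numpy as np

        mets = self.internal_metabolites()
        rxns = self.reaction_ids()
        midx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, r in enumerate(rxns):
            for m, coef in self.reactions[r].stoichiometry.items():
                if m in midx:
                    S[midx[m], j] = coef
        return S, mets, rxns

    def exchange_reactions(self) -> list[str]:
        ext = set(self.external_metabolites())
        return [r for r, rx in self.reactions.items()
                if ext.intersection(rx.stoichiometry)]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


@dataclass
class MetaboliteRule:
    """Threshold rule: when `metabolite` `comparator` `threshold` holds on the
    culture state, the target gene's state is overwritten with
    (set_mean, set_sd) for the next slice."""

    metabolite: str
    comparator: str  # "<" or ">="
    threshold: float
    target: str
    set_mean: float
    set_sd: float

    def holds(self, concentration: float) -> bool:
        if self.comparator == "<":
            return concentration < self.threshold
        if self.comparator == ">=":
            return concentration >= self.threshold
        raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass
class HybridModel:
    regulatory: RegulatoryDBN
    metabolic: MetabolicModel
    rules: list[MetaboliteRule] = field(default_factory=list)
    knocked_out: set[str] = field(default_factory=set)

    def copy(self) -> "HybridModel":
        return copy.deepcopy(self)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def rule_genes(rule: Rule) -> set[str]:
    """All gene ids referenced by a gene-reaction rule."""
    if isinstance(rule, str):
        return {rule}
    if isinstance(rule, (list, tuple)) and rule and rule[0] in ("and", "or"):
        out: set[str] = set()
        for sub in rule[1:]:
            out |= rule_genes(sub)
        return out
    raise FormatError(f"malformed gene rule: {rule!r}")


def evaluate_rule(rule: Rule, activities: Mapping[str, float]) -> float:
    """Evaluate a gene rule on continuous activities (AND -> min, OR -> max)."""
    if isinstance(rule, str):
        return activities[rule]
    op = rule[0]
    vals = [evaluate_rule(sub, activities) for sub in rule[1:]]
    return min(vals) if op == "and" else max(vals)


def validate_model(model: HybridModel) -> ValidationReport:
    """Collect every structural invariant violation; never raises on content."""
    v: list[str] = []
    dbn = model.regulatory
    nodes = dbn.nodes
    for g, n in nodes.items():
        if n.kind not in (REGULATOR, ENZYME):
            v.append(f"node {g}: unknown kind {n.kind!r}")
        if n.sigma < 0:
            v.append(f"node {g}: negative noise SD")
        if n.init_sd < 0:
            v.append(f"node {g}: negative initial SD")
    seen: set[tuple[str, str]] = set()
    for e in dbn.edges:
        if e.parent not in nodes:
            v.append(f"edge {e.parent}->{e.child}: unknown parent")
        elif nodes[e.parent].kind != REGULATOR:
            v.append(f"edge {e.parent}->{e.child}: enzyme cannot have children")
        if e.child not in nodes:
            v.append(f"edge {e.parent}->{e.child}: unknown child")
        if (e.parent, e.child) in seen:
            v.append(f"duplicate edge {e.parent}->{e.child}")
        seen.add((e.parent, e.child))

    met = model.metabolic
    if not met.biomass_reaction:
        v.append("no biomass reaction defined")
    elif met.biomass_reaction not in met.reactions:
        v.append(f"biomass reaction {met.biomass_reaction} not in reactions")
    for r, rx in met.reactions.items():
        if rx.lower_bound > rx.upper_bound:
            v.append(f"reaction {r}: lower bound exceeds upper bound")
        for m in rx.stoichiometry:
            if m not in met.metabolites:
                v.append(f"reaction {r}: unknown metabolite {m}")
    for r, rule in met.gene_rules.items():
        if r not in met.reactions:
            v.append(f"gene rule for unknown reaction {r}")
        try:
            for g in rule_genes(rule):
                if g not in nodes:
                    v.append(f"gene rule for {r}: unknown gene {g}")
                elif nodes[g].kind != ENZYME:
                    v.append(f"gene rule for {r}: gene {g} is not an enzyme")
        except FormatError as exc:
            v.append(str(exc))
    for m in met.medium:
        if m not in met.metabolites:
            v.append(f"medium entry for unknown metabolite {m}")
    for i, rule in enumerate(model.rules):
        label = f"rule[{i}] ({rule.metabolite} {rule.comparator} {rule.threshold})"
        if rule.metabolite not in met.metabolites:
            v.append(f"{label}: unknown metabolite")
        if rule.comparator not in ("<", ">="):
            v.append(f"{label}: unknown comparator")
        if rule.threshold < 0:
            v.append(f"{label}: negative threshold")
        if rule.target not in nodes:
            v.append(f"{label}: target gene {rule.target} not in DBN")
        if rule.set_sd < 0:
            v.append(f"{label}: negative set-state SD")
    for g in model.knocked_out:
        if g not in nodes:
            v.append(f"knocked-out gene {g} not in DBN")
    return ValidationReport(v)


def apply_knockout(model: HybridModel, genes: Iterable[str]) -> HybridModel:
    """Return a copy with `genes` added to the knockout set.

    During simulation a knocked-out gene is clamped to state (0, 0) at every
    slice and evaluates as 0 in gene-reaction rules. Idempotent and
    commutative over gene sets.
    """
    genes = set(genes)
    unknown = genes - set(model.regulatory.nodes)
    if unknown:
        raise KeyError(f"unknown gene(s): {sorted(unknown)}")
    out = model.copy()
    out.knocked_out |= genes
    return out


# ---------------------------------------------------------------------------
# JSON serialization (canonical: sorted keys, sorted collections)
# ---------------------------------------------------------------------------

def _model_to_dict(model: HybridModel) -> dict:
    dbn = model.regulatory
    met = model.metabolic
    return {
        "model_version": MODEL_VERSION,
        "regulatory": {
            "nodes": [{"id": g, "kind": dbn.nodes[g].kind}
                      for g in sorted(dbn.nodes)],
            "edges": sorted(
                [[e.parent, e.child, float(e.weight)] for e in dbn.edges],
                key=lambda t: (t[0], t[1])),
            "conditionals": {
                g: {"bias": float(n.bias), "sigma": float(n.sigma),
                    "init_mean": float(n.init_mean),
                    "init_sd": float(n.init_sd)}
                for g, n in sorted(dbn.nodes.items())},
        },
        "metabolic": {
            "metabolites": [{"id": m, "external": met.metabolites[m].external}
                            for m in sorted(met.metabolites)],
            "reactions": [
                {"id": r,
                 "stoichiometry": {m: float(v) for m, v in
                                   sorted(rx.stoichiometry.items())},
                 "lower_bound": float(rx.lower_bound),
                 "upper_bound": float(rx.upper_bound),
                 "reversible": rx.reversible}
                for r, rx in sorted(met.reactions.items())],
            "biomass_reaction": met.biomass_reaction,
            "gene_rules": {r: met.gene_rules[r] for r in sorted(met.gene_rules)},
            "uptake_kinetics": {m: [float(v) for v in met.uptake_kinetics[m]]
                                for m in sorted(met.uptake_kinetics)},
            "medium": {m: float(v) for m, v in sorted(met.medium.items())},
            "initial_biomass": float(met.initial_biomass),
            "glucose_metabolite": met.glucose_metabolite,
        },
        "rules": [
            {"metabolite": r.metabolite, "comparator": r.comparator,
             "threshold": float(r.threshold), "target": r.target,
             "set_mean": float(r.set_mean), "set_sd": float(r.set_sd)}
            for r in model.rules],
        "knocked_out": sorted(model.knocked_out),
    }


def _model_from_dict(doc: dict) -> HybridModel:
    try:
        reg = doc["regulatory"]
        nodes = {n["id"]: Node(kind=n["kind"]) for n in reg["nodes"]}
        for g, c in reg.get("conditionals", {}).items():
            if g not in nodes:
                raise FormatError(f"conditional for unknown node {g}")
            nodes[g].bias = float(c.get("bias", 0.0))
            nodes[g].sigma = float(c.get("sigma", 0.0))
            nodes[g].init_mean = float(c.get("init_mean", 0.0))
            nodes[g].init_sd = float(c.get("init_sd", 0.0))
        edges = [Edge(p, c, float(w)) for p, c, w in reg.get("edges", [])]
        dbn = RegulatoryDBN(nodes=nodes, edges=edges)

        md = doc["metabolic"]
        mets = {m["id"]: Metabolite(m["id"], bool(m.get("external", False)))
                for m in md.get("metabolites", [])}
        rxns = {}
        for r in md.get("reactions", []):
            rxns[r["id"]] = Reaction(
                id=r["id"],
                stoichiometry={k: float(v)
                               for k, v in r.get("stoichiometry", {}).items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                reversible=bool(r.get("reversible", False)))
        met = MetabolicModel(
            metabolites=mets, reactions=rxns,
            biomass_reaction=md.get("biomass_reaction", ""),
            gene_rules=dict(md.get("gene_rules", {})),
            uptake_kinetics={k: (float(v[0]), float(v[1]))
                             for k, v in md.get("uptake_kinetics", {}).items()},
            medium={k: float(v) for k, v in md.get("medium", {}).items()},
            initial_biomass=float(md.get("initial_biomass", 0.01)),
            glucose_metabolite=md.get("glucose_metabolite"))

        rules = [MetaboliteRule(r["metabolite"], r["comparator"],
                                float(r["threshold"]), r["target"],
                                float(r["set_mean"]), float(r["set_sd"]))
                 for r in doc.get("rules", [])]
        ko = set(doc.get("knocked_out", []))
    except FormatError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed model document: {exc}") from exc
    return HybridModel(regulatory=dbn, metabolic=met, rules=rules,
                       knocked_out=ko)


def save_hybrid_model(model: HybridModel, path: str | Path) -> None:
    """Write the canonical JSON form (stable byte-for-byte per model)."""
    doc = _model_to_dict(model)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_hybrid_model(path: str | Path) -> HybridModel:
    """Load and validate a hybrid model from its JSON document.

    Raises FormatError on parse failure and ValidationError (listing all
    violations) on invariant violations.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "model_version" not in doc:
        raise FormatError("missing model_version")
    model = _model_from_dict(doc)
    report = validate_model(model)
    if not report.ok:
        raise ValidationError(report.violations)
    return model


def load_metabolic_sbml(path: str | Path) -> MetabolicModel:
    """Import the metabolic part from an SBML file (fbc bounds + GPRs).

    Gene products become enzyme genes; boolean gene-product associations map
    onto nested and/or rules. Extracellular metabolites (compartment 'e') and
    boundary species are flagged external.
    """
    import ast as _ast

    import cobra

    cm = cobra.io.read_sbml_model(str(path))
    mets = {m.id: Metabolite(m.id, external=(m.compartment in ("e", "ext",
                                                               "extracellular")))
            for m in cm.metabolites}
    rxns: dict[str, Reaction] = {}
    rules: dict[str, Rule] = {}

    def convert(node) -> Rule:
        if isinstance(node, _ast.Name):
            return node.id
        if isinstance(node, _ast.BoolOp):
            op = "and" if isinstance(node.op, _ast.And) else "or"
            return [op] + [convert(v) for v in node.values]
        raise FormatError(f"unsupported GPR construct: {_ast.dump(node)}")

    for r in cm.reactions:
        rxns[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            reversible=r.lower_bound < 0)
        if r.gpr is not None and r.gpr.body is not None:
            rules[r.id] = convert(r.gpr.body)

    biomass = ""
    for r in cm.reactions:
        if r.objective_coefficient:
            biomass = r.id
            break
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          biomass_reaction=biomass, gene_rules=rules)
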