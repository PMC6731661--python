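"""Flux balance analysis and dynamic culture stepping.

The dynamic scheme is the static optimization approach: at each step the
reaction bounds are derived from the current gene states (gene-reaction
rules, AND -> min, OR -> max, activities clipped to [0, 1], linear scaling of
the default bounds), uptake bounds are capped by Michaelis-Menten kinetics
and by metabolite availability, a growth-maximizing LP is solved, and biomass
and extracellular concentrations are integrated over the step.

Degeneracy handling: `solve_fba` breaks ties with an exact secondary
parsimonious step (minimize total |v| at the optimal objective);
`dfba_step` folds the same preference into a single LP as a tiny penalty
(1e-7 per unit flux) on total |v|, which keeps trajectories deterministic at
half the LP count.

`bounds_from_growth` is the inverse mode: the biomass flux is pinned to an
observed growth rate, a parsimonious flux distribution is found, and
flux-variability ranges (under the parsimonious total-flux budget) for each
rule-bearing reaction are translated into Gaussian activity evidence for the
enzyme genes gating it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .models import MetabolicModel, rule_genes, evaluate_rule
from .dbn import GeneStateSlice

Bounds = Mapping[str, tuple[float, float]]

DEFAULT_VMAX = 10.0   # mmol gDW^-1 h^-1
DEFAULT_KM = 0.5      # mM


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective: float | None
    status: str  # optimal | infeasible | unbounded | infeasible_fallback

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class CultureState:
    """Batch-culture state: biomass (gDW/L) and extracellular pools (mM)."""

    time: float
    biomass: float
    concentrations: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "CultureState":
        return CultureState(self.time, self.biomass, dict(self.concentrations))


def default_bounds(model: MetabolicModel) -> dict[str, tuple[float, float]]:
    return {r: (rx.lower_bound, rx.upper_bound)
            for r, rx in model.reactions.items()}


def gene_states_to_bounds(model: MetabolicModel,
                          state: GeneStateSlice | Mapping[str, float],
                          knockouts: Iterable[str] = ()) -> dict[str, tuple[float, float]]:
    """Scale default bounds of rule-bearing reactions by gene activity.

    Activity = rule evaluation (AND -> min, OR -> max) over parent gene
    means clipped to [0, 1]; knocked-out genes count as 0.
    """
    means = state.mean if isinstance(state, GeneStateSlice) else dict(state)
    ko = set(knockouts)
    bounds = default_bounds(model)
    for r, rule in model.gene_rules.items():
        acts = {}
        for g in rule_genes(rule):
            if g in ko:
                acts[g] = 0.0
            else:
                if g not in means:
                    raise KeyError(f"rule for {r}: gene {g} missing from state")
                acts[g] = float(np.clip(means[g], 0.0, 1.0))
        a = evaluate_rule(rule, acts)
        lb, ub = bounds[r]
        bounds[r] = (lb * a, ub * a)
    return bounds


def _lp_arrays(model: MetabolicModel, bounds: Bounds):
    S, _, rxns = model.stoichiometric_matrix()
    lo = np.array([bounds[r][0] for r in rxns])
    hi = np.array([bounds[r][1] for r in rxns])
    if np.any(lo > hi + 1e-12):
        bad = [r for r, l, h in zip(rxns, lo, hi) if l > h + 1e-12]
        raise ValueError(f"lower bound exceeds upper bound for {bad}")
    return S, rxns, lo, hi


def solve_fba(model: MetabolicModel, bounds: Bounds | None = None,
              objective: str | None = None, sense: str = "max",
              parsimonious: bool = True) -> FluxDistribution:
    """Optimize one reaction flux subject to S v = 0 and bounds.

    The default objective is growth (biomass reaction) maximization. With
    ``parsimonious`` a second LP minimizes total |v| at the fixed optimum so
    the returned flux vector is deterministic under degeneracy.
    """
    if bounds is None:
        bounds = default_bounds(model)
    objective = objective or model.biomass_reaction
    S, rxns, lo, hi = _lp_arrays(model, bounds)
    j = rxns.index(objective)
    n = len(rxns)
    c = np.zeros(n)
    c[j] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lo, hi)), method="highs")
    if res.status == 2:
        return FluxDistribution({}, None, "infeasible")
    if res.status == 3:
        return FluxDistribution({}, None, "unbounded")
    if res.status != 0:
        return FluxDistribution({}, None, f"solver_error_{res.status}")
    opt = float(res.x[j])
    x = res.x
    if parsimonious:
        x2 = _parsimonious_solve(S, lo, hi, fixed={j: opt})
        if x2 is not None:
            x = x2
    return FluxDistribution({r: float(v) for r, v in zip(rxns, x)},
                            opt, "optimal")


def _parsimonious_solve(S, lo, hi, fixed: dict[int, float],
                        budget: float | None = None, obj_col=None,
                        obj_sense: float = 1.0):
    """Split-variable LP: v = p - q, p,q >= 0.

    With ``budget`` None: minimize sum(p+q) subject to S v = 0, bounds and
    the fixed fluxes. With a budget: optimize obj_col under the additional
    constraint sum(p+q) <= budget (flux variability at fixed parsimony).
    Returns v or None on solver failure.
    """
    m, n = S.shape
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    rows = []
    vals = []
    for j, v in fixed.items():
        row = np.zeros(2 * n)
        row[j] = 1.0
        row[n + j] = -1.0
        rows.append(row)
        vals.append(v)
    if rows:
        A_eq = np.vstack([A_eq] + rows)
        b_eq = np.concatenate([b_eq, vals])
    bnds = [(0.0, max(h, 0.0)) for h in hi] + [(0.0, max(-l, 0.0)) for l in lo]
    A_ub = b_ub = None
    if budget is None:
        c = np.ones(2 * n)
    else:
        c = np.zeros(2 * n)
        c[obj_col] = obj_sense
        c[n + obj_col] = -obj_sense
        A_ub = np.ones((1, 2 * n))
        b_ub = np.array([budget])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                  bounds=bnds, method="highs")
    if res.status != 0:
        return None
    return res.x[:n] - res.x[n:]


def apply_uptake_caps(model: MetabolicModel, bounds: Bounds,
                      state: CultureState, dt: float) -> dict[str, tuple[float, float]]:
    """Cap uptake of each external metabolite by Michaelis-Menten kinetics
    and by what the pool can supply over the step: min(Vmax*c/(Km+c), c/(X*dt))."""
    out = {r: tuple(b) for r, b in bounds.items()}
    X = state.biomass
    for m in model.external_metabolites():
        c_m = state.concentrations.get(m, 0.0)
        vmax, km = model.uptake_kinetics.get(m, (DEFAULT_VMAX, DEFAULT_KM))
        cap = min(vmax * c_m / (km + c_m) if c_m > 0 else 0.0,
                  c_m / (X * dt) if X > 0 else 0.0)
        for r, rx in model.reactions.items():
            coef = rx.stoichiometry.get(m, 0.0)
            if coef < 0:  # consumes m
                lb, ub = out[r]
                ub = min(ub, cap / abs(coef))
                out[r] = (min(lb, ub), ub)
    return out


def dfba_step(model: MetabolicModel, state: CultureState,
              bounds: Bounds | None = None, dt: float = 0.5,
              tie_break: float = 1e-7) -> tuple[CultureState, FluxDistribution]:
    """One dynamic-FBA step: cap uptakes, maximize growth, integrate.

    Biomass follows X' = X exp(mu dt); pools are updated with the
    interval-average biomass and clipped at zero. An infeasible LP yields a
    zero-growth fallback state flagged `infeasible_fallback`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if bounds is None:
        bounds = default_bounds(model)
    bounds = apply_uptake_caps(model, bounds, state, dt)
    S, rxns, lo, hi = _lp_arrays(model, bounds)
    j = rxns.index(model.biomass_reaction)
    n = len(rxns)
    # single blended LP: max v_bio - tie_break * sum |v|
    A_eq = np.hstack([S, -S])
    c = np.full(2 * n, tie_break)
    c[j] -= 1.0
    c[n + j] += 1.0
    bnds = [(0.0, max(h, 0.0)) for h in hi] + [(0.0, max(-l, 0.0)) for l in lo]
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), bounds=bnds,
                  method="highs")
    if res.status != 0:
        new = state.copy()
        new.time = state.time + dt
        return new, FluxDistribution({r: 0.0 for r in rxns}, 0.0,
                                     "infeasible_fallback")
    v = res.x[:n] - res.x[n:]
    mu = float(v[j])
    X = state.biomass
    X_new = X * float(np.exp(mu * dt))
    X_bar = (X_new - X) / (mu * dt) if abs(mu) > 1e-12 else X
    conc = dict(state.concentrations)
    ext = set(model.external_metabolites())
    for m in ext:
        rate = 0.0
        for k, r in enumerate(rxns):
            coef = model.reactions[r].stoichiometry.get(m, 0.0)
            if coef:
                rate += coef * v[k]
        if m in conc or rate:
            conc[m] = max(0.0, conc.get(m, 0.0) + rate * X_bar * dt)
    new = CultureState(state.time + dt, X_new, conc)
    flux = FluxDistribution({r: float(v[k]) for k, r in enumerate(rxns)},
                            mu, "optimal")
    return new, flux


def _activity_range(vmin: float, vmax: float, lb: float, ub: float):
    ref = max(abs(lb), abs(ub))
    if ref <= 0:
        return 0.0, 0.0
    lo_abs = 0.0 if vmin <= 0.0 <= vmax else min(abs(vmin), abs(vmax))
    hi_abs = max(abs(vmin), abs(vmax))
    return (float(np.clip(lo_abs / ref, 0, 1)),
            float(np.clip(hi_abs / ref, 0, 1)))


def bounds_from_growth(model: MetabolicModel, observed_mu: float,
                       bounds: Bounds | None = None,
                       sd_min: float = 1e-3) -> dict[str, tuple[float, float]]:
    """Enzyme-gene activity evidence implied by an observed growth rate.

    The biomass flux is fixed at ``observed_mu`` (projected onto the feasible
    maximum when it exceeds it, with a warning); a parsimonious flux vector
    sets the total-flux budget; per rule-bearing reaction the admissible flux
    range at that budget maps to a required-activity interval relative to the
    default bound; each gene in the rule receives a Gaussian with mean the
    interval midpoint and SD a quarter of its width (floored at sd_min).
    Genes gating several reactions get the intersection of their intervals.
    """
    if observed_mu < 0:
        raise ValueError("observed growth rate must be >= 0")
    if bounds is None:
        bounds = default_bounds(model)
    S, rxns, lo, hi = _lp_arrays(model, bounds)
    j = rxns.index(model.biomass_reaction)
    # feasibility ceiling
    fba = solve_fba(model, bounds, parsimonious=False)
    mu_max = fba.objective if fba.ok else 0.0
    mu = observed_mu
    if mu > mu_max + 1e-9:
        warnings.warn(
            f"observed growth {observed_mu:.4g} exceeds feasible maximum "
            f"{mu_max:.4g}; using the maximum-growth solution")
        mu = mu_max
    v_p = _parsimonious_solve(S, lo, hi, fixed={j: mu})
    if v_p is None:
        raise RuntimeError("parsimonious LP failed at fixed growth")
    budget = float(np.sum(np.abs(v_p))) + 1e-7

    intervals: dict[str, list[tuple[float, float]]] = {}
    for r, rule in model.gene_rules.items():
        k = rxns.index(r)
        vlo = _parsimonious_solve(S, lo, hi, fixed={j: mu}, budget=budget,
                                  obj_col=k, obj_sense=1.0)
        vhi = _parsimonious_solve(S, lo, hi, fixed={j: mu}, budget=budget,
                                  obj_col=k, obj_sense=-1.0)
        vmin = float(vlo[k]) if vlo is not None else float(v_p[k])
        vmax = float(vhi[k]) if vhi is not None else float(v_p[k])
        a_lo, a_hi = _activity_range(vmin, vmax,
                                     model.reactions[r].lower_bound,
                                     model.reactions[r].upper_bound)
        for g in rule_genes(rule):
            intervals.setdefault(g, []).append((a_lo, a_hi))

    evidence: dict[str, tuple[float, float]] = {}
    for g, ivs in intervals.items():
        lo_g = max(a for a, _ in ivs)
        hi_g = min(b for _, b in ivs)
        if hi_g < lo_g:  # inconsistent requirements: keep the binding one
            hi_g = lo_g
        evidence[g] = ((lo_g + hi_g) / 2.0, max((hi_g - lo_g) / 4.0, sd_min))
    return evidence


def carbon_balance(model: MetabolicModel, flux: FluxDistribution,
                   carbon: Mapping[str, float]) -> float:
    """Net carbon production rate over external pools + biomass drain.

    ``carbon`` maps metabolite ids (and optionally the biomass reaction id)
    to carbon content; with a mass-balanced stoichiometry the result is ~0.
    """
    total = 0.0
    for m in model.external_metabolites():
        cm = carbon.get(m, 0.0)
        if not cm:
            continue
        for r, v in flux.fluxes.items():
            coef = model.reactions[r].stoichiometry.get(m, 0.0)
            total += cm * coef * v
    total += carbon.get(model.biomass_reaction, 0.0) * \
        flux.fluxes.get(model.biomass_reaction, 0.0)
    return total
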