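"""Virtual laboratory: synthetic ground truth and in-silico experiments.

This module replaces a robotic culture platform at desk scale. It generates
a hidden ground-truth hybrid model of the yeast diauxic shift, executes
knockout growth experiments on it (replicate OD560 curves plus glucose
depletion curves with observation noise) and emits expression compendia, so
that every stage of the closed improvement loop - inference, design,
refinement, evaluation - can be exercised and scored against a known truth.

The generated model has a fixed diauxic core and randomized periphery:

* metabolism: glucose uptake -> fermentation (fast, low yield, secretes
  ethanol) and ethanol uptake -> respiration (slow, high yield), each gated
  by enzyme genes through gene-reaction rules; stoichiometry is
  carbon-balanced (glucose 6 C, ethanol 2 C, CO2 1 C, biomass 10 C per unit);
* regulation: a constitutive glucose-repression regulator (MIG1-like)
  represses the respiratory enzymes; a shift regulator (CAT8-like) activates
  them and is itself driven by two metabolite rules (glucose below threshold
  activates it, glucose above deactivates it);
* periphery: additional regulators and enzymes with randomized
  linear-Gaussian edges (regulators only as parents), stable by construction.

Wild-type simulations are verified to exhibit a diauxic shift (biphasic
growth with glucose depleted before the slower respiratory phase) before a
model is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import (ENZYME, REGULATOR, Edge, HybridModel, MetabolicModel,
                     Metabolite, MetaboliteRule, Node, Reaction,
                     RegulatoryDBN, validate_model)
from .dbn import ExpressionDataset
from .simulate import simulate_strain, predicted_growth_params
from .phenotype import GrowthCurve, GrowthParameters, growth_parameters, \
    preprocess_curve


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LabConfig:
    """Study conditions of the virtual laboratory.

    Defaults mirror a 45 h batch growth assay sampled every 30 min with
    eight replicate wells and small additive OD observation noise.
    """

    seed: int
    regulators: int = 6           # includes the two core regulators
    enzymes: int = 8              # includes the four core enzymes
    horizon: float = 45.0         # h
    dt: float = 0.5               # h
    replicates: int = 8
    od_noise_sd: float = 0.02     # OD560 units
    glucose_noise_sd: float = 0.1  # mM
    expression_noise_sd: float = 0.02
    episodes: int = 30            # replicate cultures in expression compendia
    episode_horizon: float | None = 7.5  # h per episode (None: full horizon)
    glucose_mM: float = 20.0
    initial_biomass: float = 0.01  # gDW/L
    od_per_gdw: float = 2.0
    sigma_range: tuple[float, float] = (0.05, 0.1)
    weight_range: tuple[float, float] = (0.4, 0.85)
    max_retries: int = 5


CORE_REGULATORS = ("MIG1", "CAT8")
CORE_ENZYMES = ("HXT1", "PDC1", "ADH2", "CIT1", "KGD1")
GLC = "glc_e"
ETH = "eth_e"


def _core_metabolism(cfg: LabConfig) -> MetabolicModel:
    mets = {m: Metabolite(m, external=True) for m in (GLC, ETH, "co2_e")}
    mets.update({m: Metabolite(m) for m in ("glc_c", "eth_c", "co2_c",
                                            "biom_c")})
    mets["akg_c"] = Metabolite("akg_c")
    # carbon-balanced toy stoichiometry (C per unit: glc 6, eth 2, akg 2,
    # co2 1, biomass 10): 6 = 1.6*2 + 2.45 + 0.035*10 ; 2 = 1.6 + 0.04*10.
    # Respiration is two gated steps (TCA entry, then oxidation driving
    # biomass); capacities make the gene-gated steps the binding constraints.
    rxns = {
        "GLCup": Reaction("GLCup", {GLC: -1, "glc_c": 1}, 0, 10),
        "FERM": Reaction("FERM", {"glc_c": -1, "eth_c": 1.6, "co2_c": 2.45,
                                  "biom_c": 0.035}, 0, 12),
        "ETHsec": Reaction("ETHsec", {"eth_c": -1, ETH: 1}, 0, 50),
        "ETHup": Reaction("ETHup", {ETH: -1, "eth_c": 1}, 0, 3),
        "RESP1": Reaction("RESP1", {"eth_c": -1, "akg_c": 1}, 0, 3),
        "RESP2": Reaction("RESP2", {"akg_c": -1, "co2_c": 1.6,
                                    "biom_c": 0.04}, 0, 2.8),
        "CO2out": Reaction("CO2out", {"co2_c": -1, "co2_e": 1}, 0, 50),
        "BIOMASS": Reaction("BIOMASS", {"biom_c": -1}, 0, 5),
    }
    return MetabolicModel(
        metabolites=mets, reactions=rxns, biomass_reaction="BIOMASS",
        gene_rules={"GLCup": "HXT1", "FERM": "PDC1",
                    "ETHup": "ADH2", "RESP1": "CIT1", "RESP2": "KGD1"},
        uptake_kinetics={GLC: (10.0, 0.5), ETH: (3.0, 0.5),
                         "co2_e": (0.0, 0.5)},
        medium={GLC: cfg.glucose_mM, ETH: 0.0, "co2_e": 0.0},
        initial_biomass=cfg.initial_biomass,
        glucose_metabolite=GLC)


CARBON = {GLC: 6.0, ETH: 2.0, "co2_e": 1.0, "BIOMASS": 10.0}
"""Carbon content used by the toy model's conservation bookkeeping."""


def _core_regulation() -> RegulatoryDBN:
    nodes = {
        # constitutive glucose-repression regulator
        "MIG1": Node(REGULATOR, bias=0.8, sigma=0.05, init_mean=0.8),
        # diauxic-shift regulator, driven by the metabolite rules
        "CAT8": Node(REGULATOR, bias=0.0, sigma=0.05, init_mean=0.0),
        "HXT1": Node(ENZYME, bias=0.9, sigma=0.05, init_mean=0.9),
        "PDC1": Node(ENZYME, bias=0.9, sigma=0.05, init_mean=0.9),
        "ADH2": Node(ENZYME, bias=0.3, sigma=0.05, init_mean=0.0),
        "CIT1": Node(ENZYME, bias=0.3, sigma=0.05, init_mean=0.0),
        "KGD1": Node(ENZYME, bias=0.3, sigma=0.05, init_mean=0.0),
    }
    edges = [
        Edge("CAT8", "ADH2", 0.9), Edge("CAT8", "CIT1", 0.9),
        Edge("CAT8", "KGD1", 0.9),
        Edge("MIG1", "ADH2", -0.4), Edge("MIG1", "CIT1", -0.4),
        Edge("MIG1", "KGD1", -0.4),
    ]
    return RegulatoryDBN(nodes=nodes, edges=edges)


def _diauxic_rules() -> list[MetaboliteRule]:
    return [
        MetaboliteRule(GLC, "<", 0.25, "CAT8", 1.0, 0.05),
        MetaboliteRule(GLC, ">=", 0.25, "CAT8", 0.0, 0.05),
    ]


def _random_periphery(dbn: RegulatoryDBN, cfg: LabConfig,
                      rng: np.random.Generator) -> None:
    n_extra_reg = max(0, cfg.regulators - len(CORE_REGULATORS))
    n_extra_enz = max(0, cfg.enzymes - len(CORE_ENZYMES))
    extra_regs = [f"TF{i+1:02d}" for i in range(n_extra_reg)]
    extra_enzs = [f"ENZ{i+1:02d}" for i in range(n_extra_enz)]
    lo, hi = cfg.sigma_range
    wlo, whi = cfg.weight_range

    def rand_sigma():
        return float(rng.uniform(lo, hi))

    def rand_weight():
        return float(rng.uniform(wlo, whi)) * (1 if rng.random() < 0.5 else -1)

    for g in extra_regs:
        dbn.nodes[g] = Node(REGULATOR, bias=float(rng.uniform(0.1, 0.9)),
                            sigma=rand_sigma())
    for g in extra_enzs:
        dbn.nodes[g] = Node(ENZYME, bias=float(rng.uniform(0.1, 0.5)),
                            sigma=rand_sigma())
    regs = list(CORE_REGULATORS) + extra_regs
    # each extra regulator: at most one regulator parent (sparse upstream)
    for g in extra_regs:
        if rng.random() < 0.5:
            p = regs[rng.integers(len(regs))]
            if p != g and not dbn.has_edge(p, g):
                dbn.add_edge(p, g, rand_weight())
    # each extra enzyme: one or two regulator parents
    for g in extra_enzs:
        k = int(rng.integers(1, 3))
        parents = rng.choice(regs, size=min(k, len(regs)), replace=False)
        for p in parents:
            if not dbn.has_edge(p, g):
                dbn.add_edge(str(p), g, rand_weight())
    # keep the regulator subsystem stable: total |w| into any regulator < 1
    pm = dbn.parent_map()
    for g in regs:
        tot = sum(abs(e.weight) for e in pm.get(g, []))
        if tot >= 0.95:
            for e in pm[g]:
                e.weight *= 0.9 / tot
    # fixed-point-consistent initial states for the periphery
    for g in extra_regs + extra_enzs:
        dbn.nodes[g].init_mean = dbn.nodes[g].bias


ISO_REACTIONS = ("ETHup", "RESP1", "RESP2")


def _wire_isoenzymes(model: HybridModel) -> None:
    """Give the post-shift reactions weakly-expressed isoenzyme OR-partners.

    The first extra enzymes become silent isoenzymes (low basal expression,
    no regulators), so each post-shift step is formally redundant but the
    bypass carries almost no flux in the wild type - the substrate on which
    over-permissive model defects (spurious activation of a bypass) are
    planted and repaired."""
    dbn = model.regulatory
    extra = sorted(g for g in dbn.enzymes() if g.startswith("ENZ"))
    for rxn, iso in zip(ISO_REACTIONS, extra):
        core_gene = model.metabolic.gene_rules[rxn]
        model.metabolic.gene_rules[rxn] = ["or", core_gene, iso]
        dbn.edges = [e for e in dbn.edges if e.child != iso]
        dbn.nodes[iso].bias = 0.05
        dbn.nodes[iso].init_mean = 0.05


def diauxic_check(params: GrowthParameters, result=None,
                  g_min: float = 0.1) -> bool:
    """Biphasic wild-type phenotype: detected shift, faster pre- than
    post-shift growth, and a real respiratory phase."""
    if not params.shift_detected:
        return False
    if not (params.pre_rate > params.post_rate > 0.01):
        return False
    if result is not None and result.glucose_metabolite:
        glc = result.concentration(result.glucose_metabolite)
        if glc.min() >= g_min:
            return False
        # depletion precedes the post-shift phase onset
        t_dep = result.times[np.nonzero(glc < g_min)[0][0]]
        if t_dep > params.shift_time + 1e-9:
            return False
    return True


def generate_ground_truth(config: LabConfig) -> HybridModel:
    """Deterministically generate a valid, diauxie-verified hybrid model."""
    if config.regulators < 1 or config.enzymes < 1:
        raise ValueError("need at least one regulator and one enzyme")
    for attempt in range(config.max_retries):
        rng = np.random.default_rng((config.seed, attempt))
        dbn = _core_regulation()
        _random_periphery(dbn, config, rng)
        model = HybridModel(regulatory=dbn, metabolic=_core_metabolism(config),
                            rules=_diauxic_rules())
        _wire_isoenzymes(model)
        report = validate_model(model)
        if not report.ok:
            continue
        sim = simulate_strain(model, config.horizon, config.dt,
                              od_per_gdw=config.od_per_gdw)
        params = predicted_growth_params(sim)
        if diauxic_check(params, sim):
            return model
    raise GenerationError(
        f"no diauxic model found in {config.max_retries} attempts "
        f"(seed {config.seed})")


def run_virtual_experiment(truth: HybridModel, knockout: set[str] | frozenset,
                           config: LabConfig,
                           seed: int | None = None) -> list[GrowthCurve]:
    """Grow a deletant strain in silico: replicate OD560 curves (+ glucose)
    with i.i.d. Gaussian observation noise, clipped at zero."""
    from .models import apply_knockout

    strain = apply_knockout(truth, knockout)
    sim = simulate_strain(strain, config.horizon, config.dt,
                          od_per_gdw=config.od_per_gdw)
    base = sim.growth_curve()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    name = "WT" if not knockout else "d" + "_d".join(sorted(knockout))
    out = []
    for r in range(config.replicates):
        od = np.clip(base.od + rng.normal(0, config.od_noise_sd,
                                          size=base.od.shape), 0, None)
        glc = None
        if base.glucose is not None:
            glc = np.clip(base.glucose +
                          rng.normal(0, config.glucose_noise_sd,
                                     size=base.glucose.shape), 0, None)
        out.append(GrowthCurve(base.time.copy(), od, glc, strain=name,
                               replicate=r + 1))
    return out


def observe_strain(truth: HybridModel, knockout: set[str] | frozenset,
                   config: LabConfig, seed: int | None = None,
                   g_min: float = 0.1) -> GrowthParameters:
    """Run the experiment and extract growth parameters through the same
    preprocessing path used for any observed curve."""
    reps = run_virtual_experiment(truth, knockout, config, seed)
    mean_curve = preprocess_curve(reps, min_reps=min(config.replicates, 8))
    try:
        return growth_parameters(mean_curve, g_min=g_min)
    except ValueError:
        return GrowthParameters(0.0, 0.0, float("nan"),
                                float(mean_curve.time[-1]),
                                float(mean_curve.od[-1]), False)


def generate_expression_dataset(truth: HybridModel, config: LabConfig,
                                seed: int | None = None) -> ExpressionDataset:
    """Expression compendium: sampled gene-state trajectories across the
    wild-type diauxic simulation plus measurement noise.

    Episode 1 starts from the model's initial state; further episodes
    restart from randomized initial gene states (short replicate cultures
    sampled from varied preconditions, the way a multi-condition compendium
    spans regulator activity levels), so transitions within each episode
    carry the regulatory dynamics while restarts break the chain (time
    stamps reset).
    """
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng((base_seed, 7919))
    genes = sorted(truth.regulatory.nodes)
    blocks = []
    times = []
    for ep in range(config.episodes):
        model = truth
        if ep > 0:
            model = truth.copy()
            for g, node in model.regulatory.nodes.items():
                node.init_mean = float(rng.uniform(0.0, 1.0))
                node.init_sd = 0.0
        ep_h = config.episode_horizon or config.horizon
        sim = simulate_strain(model, ep_h, config.dt,
                              seed=int(rng.integers(2 ** 31)),
                              od_per_gdw=config.od_per_gdw)
        vals = sim.trajectory.means.T  # (G, T+1), sampled trajectory
        order = [sim.trajectory.genes.index(g) for g in genes]
        blocks.append(vals[order])
        times.append(sim.times)
    values = np.hstack(blocks)
    values = values + rng.normal(0, config.expression_noise_sd,
                                 size=values.shape)
    return ExpressionDataset(genes, np.concatenate(times), values)
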