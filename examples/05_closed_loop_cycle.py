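"""One full closed-loop improvement cycle: design -> experiments -> refine
-> held-out evaluation, comparing active against random experiment design.

The working model over-predicts post-shift growth: silent isoenzyme bypasses
were spuriously activated (the classic failure mode of an over-permissive
literature-derived network). Active design spends its 15-strain budget on
the knockouts that expose these defects; random design mostly does not.
"""

import warnings

import numpy as np

from diauxlab import (CycleConfig, LabConfig, generate_ground_truth,
                      run_cycle, simulate_strain)
from diauxlab.virtual_lab import ISO_REACTIONS

warnings.filterwarnings("ignore")
seed = 5
cfg = LabConfig(seed=seed, regulators=16, enzymes=16, horizon=24.0, dt=0.75,
                glucose_mM=8.0)
truth = generate_ground_truth(cfg)

# corrupt: constitutively activate the silent bypass isoenzymes
rng = np.random.default_rng((seed, 23))
sim = simulate_strain(truth, cfg.horizon, cfg.dt)
tr = sim.trajectory
post = {g: tr.means[-2, tr.index(g)] for g in truth.regulatory.nodes}
model = truth.copy()
regs = sorted(r for r in truth.regulatory.regulators()
              if r != "CAT8" and post[r] >= 0.45)
for rxn in ISO_REACTIONS:
    iso = model.metabolic.gene_rules[rxn][2]
    avail = [r for r in regs if not model.regulatory.has_edge(r, iso)]
    p = str(rng.choice(avail))
    model.regulatory.add_edge(p, iso, min(0.9, 0.65 / post[p]))
    print(f"planted bypass activation: {p} -> {iso} (gates {rxn})")

for method in ("adactive", "random"):
    c = CycleConfig(seed=seed, method=method, k=15, max_evals=8)
    refined, report, trace = run_cycle(model, truth, cfg, c)
    print(f"\n[{method}] trained on: {', '.join(report.selected[:8])} ...")
    print(f"[{method}] revisions: {report.n_revisions}; held-out post-shift "
          f"MAE {report.error_before:.4f} -> {report.error_after:.4f} /h "
          f"(ratio {report.ratio:.2f}, Wilcoxon p {report.wilcoxon_p:.3g})")
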