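"""Socratic agents: an individual-level intervention against echo chambers.

Socratic agents exchange information only with agents whose views are far
from their own (outside their acceptance window) but whose belief
distributions still overlap theirs.  This script runs paired simulations
(same seeds) with 0% and 20% Socratic agents and reports the relative
reduction in final global belief purity they cause.
"""

import numpy as np

from echochambers import SimulationConfig, run

SEEDS = range(5)
BETA = 1.0

purity = {0.0: [], 0.2: []}
for seed in SEEDS:
    for fraction in (0.0, 0.2):
        cfg = SimulationConfig(
            n_agents=300, beta=BETA, socratic_fraction=fraction, horizon=200,
            seed=seed, metrics_every=200,
        )
        state = run(cfg)
        purity[fraction].append(state.metrics.df.purity.iloc[-1])

base = np.mean(purity[0.0])
soc = np.mean(purity[0.2])
drop = 100 * (base - soc) / base
print(f"mean final purity, no Socratic agents : {base:.6f}")
print(f"mean final purity, 20% Socratic       : {soc:.6f}")
print(f"relative purity reduction             : {drop:.3f}%")
print()
print("A small reduction means echo chambers absorb the perturbation: the")
print("anti-confirmatory minority attaches into clusters without breaking them.")
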