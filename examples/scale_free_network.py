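"""Scale-free social structure: growth, degree exponent, and a short run.

Grows a 1000-agent network by sequential attachment with redirection so
the degree distribution follows a power law with exponent ~ gamma = 2.5
(real social networks typically show 2 < gamma < 3), verifies the fitted
exponent, then runs a short simulation on the scale-free topology where
pruned links are replaced by preferential re-wiring.
"""

from collections import Counter

from echochambers import (
    SimulationConfig,
    TopologyConfig,
    fit_powerlaw_exponent,
    grow_scale_free,
    run,
)

graph = grow_scale_free(TopologyConfig(n_agents=1000, gamma=2.5), rng=7)
degrees = [d for _, d in graph.degree()]
fitted = fit_powerlaw_exponent(degrees)
hist = Counter(degrees)

print(f"nodes/links                  : {graph.number_of_nodes()} / {graph.number_of_edges()}")
print(f"max degree                   : {max(degrees)}")
print(f"fitted power-law exponent    : {fitted:.2f}  (target gamma = 2.5)")
print(f"degree histogram (head)      : {dict(sorted(hist.items())[:6])}")

state = run(SimulationConfig(topology="scale_free", n_agents=200, horizon=50, seed=7))
final = state.metrics.df.iloc[-1]
print(f"\nafter 50 steps on the scale-free topology (n=200):")
print(f"belief purity = {final.purity:.4f}, links = {int(final.n_links)}, "
      f"mean P(H|E) = {final.mean_p_h:.3f}")
print("\nHub-dominated structure concentrates exchange; pruning + preferential")
print("re-wiring keeps the heavy-tailed link distribution while beliefs purify.")
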