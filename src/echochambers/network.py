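"""Social-network structures: random spatial placement and scale-free growth.

Two topologies are supported.  In the random model agents sit at fixed
uniform positions on a square grid and can interact with every other agent
within a Euclidean reach radius set by the search parameter ``alpha`` (the
fraction of the arena an agent can cover).  In the scale-free model agents
have no positions; the network is grown sequentially, one agent at a time,
so that the degree distribution follows a power law p(k) ~ k^-gamma, and
pruned links are replaced by preferential re-wiring toward well-connected
agents so the scale-free shape is maintained.

Graphs are plain :class:`networkx.Graph` objects carrying a graph-level
``topology`` tag (``"random_spatial"`` or ``"scale_free"``) and, for the
spatial model, per-node ``pos`` attributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Union

import networkx as nx
import numpy as np
from scipy import optimize, special

__all__ = [
    "ALL",
    "TopologyConfig",
    "SocialGraph",
    "TopologyMismatchError",
    "reach_radius",
    "random_spatial_graph",
    "neighbors_in_reach",
    "grow_scale_free",
    "attachment_probabilities",
    "rewire_preferential",
    "fit_powerlaw_exponent",
]

#: Sentinel radius meaning "every other agent is reachable" (alpha == 1).
ALL = math.inf

RANDOM_SPATIAL = "random_spatial"
SCALE_FREE = "scale_free"

SocialGraph = nx.Graph


class TopologyMismatchError(RuntimeError):
    """An operation was applied to a graph of the wrong topology."""


@dataclass
class TopologyConfig:
    """Free parameters of the social structure.

    alpha : reach, fraction of the arena searchable (random model) and the
        population scaling factor for the scale-free model (n_SF = alpha * n_R).
    gamma : power-law exponent targeted by scale-free growth (default 2.5;
        empirical social networks typically show 2 < gamma < 3).
    n_agents : population size (default 1000 for the random model).
    sf_dialect : "target_exponent" grows a network whose fitted degree
        exponent is approximately gamma (uniform attachment with
        redirection); "literal_rule" attaches with probability
        proportional to k^-gamma over existing agents.
    """

    alpha: float = 1.0
    gamma: float = 2.5
    n_agents: int = 1000
    sf_dialect: str = "target_exponent"
    grid_side: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.gamma <= 1:
            raise ValueError(f"gamma must be > 1, got {self.gamma}")
        if self.n_agents < 2:
            raise ValueError(f"n_agents must be >= 2, got {self.n_agents}")
        if self.sf_dialect not in ("target_exponent", "literal_rule"):
            raise ValueError(f"unknown sf_dialect {self.sf_dialect!r}")


def reach_radius(alpha: float, grid_side: float = 100.0) -> float:
    """Radius of the circular search area covering a fraction ``alpha`` of the arena.

    Solves pi * r**2 = alpha * grid_side**2.  ``alpha == 1`` means total
    range and returns the :data:`ALL` sentinel (a circle of equal area
    would not cover the square's corners).
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha == 1:
        return ALL
    return math.sqrt(alpha * grid_side * grid_side / math.pi)


def random_spatial_graph(
    n_agents: int,
    rng: Union[int, np.random.Generator, None] = None,
    grid_side: float = 100.0,
) -> SocialGraph:
    """Place ``n_agents`` at uniform random positions on the square arena.

    The returned graph has no links; in the random model an agent's
    network at any instant is its reach set filtered by acceptance, and
    the explicit link set is maintained by the simulation engine.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pos = gen.uniform(0.0, grid_side, size=(n_agents, 2))
    g = nx.Graph(topology=RANDOM_SPATIAL, grid_side=grid_side)
    for i in range(n_agents):
        g.add_node(i, pos=(float(pos[i, 0]), float(pos[i, 1])))
    return g


def neighbors_in_reach(graph: SocialGraph, agent: int, radius: float) -> Set[int]:
    """All other agents within Euclidean distance ``radius`` of ``agent``.

    Distances are plain Euclidean on the grid — no toroidal wrapping, so
    agents near an edge genuinely reach fewer peers.  ``radius == ALL``
    returns every other agent.
    """
    if graph.graph.get("topology") != RANDOM_SPATIAL:
        raise TopologyMismatchError("neighbors_in_reach requires a random_spatial graph")
    if radius is ALL or math.isinf(radius):
        return set(graph.nodes) - {agent}
    x0, y0 = graph.nodes[agent]["pos"]
    out = set()
    for j, data in graph.nodes(data=True):
        if j == agent:
            continue
        x, y = data["pos"]
        if (x - x0) ** 2 + (y - y0) ** 2 <= radius * radius:
            out.add(j)
    return out


def attachment_probabilities(degrees: Sequence[int], gamma: float) -> np.ndarray:
    """Literal-rule attachment weights p(k) ~ k^-gamma, normalized.

    Note this rule *favors low-degree nodes* for gamma > 0; it is kept as
    a dialect for comparison with the outcome-driven generator.
    """
    k = np.asarray(degrees, dtype=float)
    k = np.maximum(k, 1.0)  # isolated seed nodes attach with weight 1
    w = k ** (-gamma)
    return w / w.sum()


def grow_scale_free(
    config: TopologyConfig, rng: Union[int, np.random.Generator, None] = None
) -> SocialGraph:
    """Grow a connected network by sequential attachment of single agents.

    Each new agent spawns attached to exactly one existing agent, so the
    graph is connected at every instant of growth.  In the default
    ``target_exponent`` dialect a new agent picks an existing agent
    uniformly and, with redirection probability r = 1/(gamma - 1), attaches
    to that agent's (uniformly chosen) neighbor instead; redirection makes
    attachment effectively preferential and yields a degree distribution
    with power-law exponent approximately gamma.  The ``literal_rule``
    dialect attaches with probability proportional to k^-gamma.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = config.n_agents
    g = nx.Graph(topology=SCALE_FREE)
    g.add_node(0)
    g.add_node(1)
    g.add_edge(0, 1)
    redirect = 1.0 / (config.gamma - 1.0)
    for new in range(2, n):
        existing = new  # nodes 0..new-1 exist
        if config.sf_dialect == "literal_rule":
            degs = [g.degree(i) for i in range(existing)]
            probs = attachment_probabilities(degs, config.gamma)
            target = int(gen.choice(existing, p=probs))
        else:
            target = int(gen.integers(existing))
            if gen.random() < redirect:
                nbrs = list(g.adj[target])
                target = int(nbrs[gen.integers(len(nbrs))])
        g.add_node(new)
        g.add_edge(new, target)
    return g


def rewire_preferential(
    graph: SocialGraph,
    agent: int,
    candidates: Iterable[int],
    n_new: int,
    rng: Union[int, np.random.Generator, None] = None,
) -> SocialGraph:
    """Re-contact acceptable agents, preferring the well-connected.

    Adds up to ``n_new`` links from ``agent`` to members of ``candidates``
    (which must exclude the agent and its current neighbors), sampled
    without replacement with probability proportional to current degree;
    degree-0 candidates get weight 1.  An empty candidate set leaves the
    graph unchanged — the agent is "starved".  The graph is mutated in
    place and returned.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pool = [c for c in candidates]
    if n_new <= 0 or not pool:
        return graph
    for _ in range(min(n_new, len(pool))):
        weights = np.array([max(graph.degree(c), 1) for c in pool], dtype=float)
        probs = weights / weights.sum()
        pick = int(gen.choice(len(pool), p=probs))
        graph.add_edge(agent, pool[pick])
        pool.pop(pick)
    return graph


def fit_powerlaw_exponent(
    degrees: Sequence[int], k_min: int = 2, bounds: tuple = (1.05, 6.0)
) -> float:
    """Discrete maximum-likelihood power-law exponent of a degree sequence.

    Fits p(k) = k^-a / zeta(a, k_min) to the degrees >= ``k_min`` by
    maximizing the zeta likelihood numerically.  For networks grown with a
    single link per new agent the degree-1 mass is dominated by freshly
    attached leaves, so the tail (k >= 2) is the standard fitting range.
    """
    k = np.asarray([d for d in degrees if d >= k_min], dtype=float)
    if k.size < 2:
        raise ValueError("need at least 2 degrees >= k_min to fit an exponent")
    mean_log_k = float(np.mean(np.log(k)))

    def neg_loglik(a: float) -> float:
        return a * mean_log_k + math.log(special.zeta(a, k_min))

    res = optimize.minimize_scalar(neg_loglik, bounds=bounds, method="bounded")
    return float(res.x)
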