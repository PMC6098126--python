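"""Time-stepped simulation engine.

Each step, agents act in a seeded-shuffled order.  An agent determines its
candidate set (everyone within spatial reach in the random model; its
linked neighbors in the scale-free model), filters it through its
acceptance rule (the beta-window for confirmatory agents, no filter for
stochastic agents, the far-but-overlapping rule for Socratic agents),
pulls each accepted peer's stated belief as evidence, revises its
confidence by Bayes' theorem and its belief mean/SD by perfect-memory
averaging, and — in the scale-free model — prunes mutually unacceptable
links and re-wires preferentially toward well-connected acceptable agents.

All likelihood ratios and the acceptance filter for one agent's turn are
evaluated against the agent's state at the start of its turn; the turn's
evidence is integrated as a single batch.  Memory statistics are
order-invariant so this is exact for mu/sigma, and the clamped posterior
``min(1, p * prod(LR))`` applied ratio-by-ratio has the closed form

    log p_final = log p0 + S_k - max(0, max_j (log p0 + S_j)),

with S_j the running sum of log likelihood ratios, which the engine uses
to vectorize whole turns.  The population state lives in flat numpy
arrays (belief mean, memory count, M2, log-confidence); per-agent
:class:`~echochambers.belief.BeliefState` views are available for
inspection, and ``track_memory=True`` keeps full evidence lists.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import networkx as nx
import numpy as np

from .belief import BeliefState, WorldTruth
from .config import RANDOM_SPATIAL, SCALE_FREE, SimulationConfig
from .metrics import MetricsSeries
from .network import TopologyConfig, grow_scale_free, reach_radius, rewire_preferential

__all__ = [
    "NOT_CONVERGED",
    "SimulationState",
    "initialize",
    "step",
    "broadcast",
    "run",
    "detect_stable_state",
    "snapshot_graph",
    "final_states_frame",
]

logger = logging.getLogger(__name__)

#: Returned by :func:`detect_stable_state` when no stable window exists.
NOT_CONVERGED = None

KIND_CONFIRMATORY, KIND_STOCHASTIC, KIND_SOCRATIC = 0, 1, 2
KIND_NAMES = {0: "confirmatory", 1: "stochastic", 2: "socratic"}

_LOG_2PI_HALF = 0.5 * math.log(2.0 * math.pi)


@dataclass
class SimulationState:
    """Full mutable state of a running simulation."""

    config: SimulationConfig
    world: WorldTruth
    step_index: int
    mu: np.ndarray  # belief means
    count: np.ndarray  # memory sizes
    m2: np.ndarray  # sum of squared deviations of memory
    sigma: np.ndarray  # sample SD of memory, floored at sigma_floor
    log_p_h: np.ndarray  # log confidence, <= 0
    kind: np.ndarray  # int8 agent kinds
    beta: np.ndarray  # per-agent window width; nan = unused
    rng: np.random.Generator
    metrics: MetricsSeries
    pos: Optional[np.ndarray] = None  # (n, 2) positions, random model only
    reach_mask: Optional[np.ndarray] = None  # bool (n, n); None = full reach
    graph: Optional[nx.Graph] = None  # persistent links, scale-free only
    memory: Optional[List[List[float]]] = None
    broadcast_log: List[dict] = field(default_factory=list)

    @property
    def n_agents(self) -> int:
        return self.mu.shape[0]

    @property
    def p_h(self) -> np.ndarray:
        return np.exp(self.log_p_h)

    def belief_state(self, i: int) -> BeliefState:
        """Per-agent view (memory included only when tracked)."""
        mem = list(self.memory[i]) if self.memory is not None else []
        return BeliefState(
            mu_own=float(self.mu[i]),
            sigma_own=float(self.sigma[i]),
            p_h=float(np.exp(self.log_p_h[i])),
            memory=mem,
        )

    @property
    def agents(self):
        return [
            (self.belief_state(i), KIND_NAMES[int(self.kind[i])], _beta_of(self, i))
            for i in range(self.n_agents)
        ]


def _beta_of(state: SimulationState, i: int) -> Optional[float]:
    b = float(state.beta[i])
    return None if math.isnan(b) else b


def _extremist_sigma_ref(state: SimulationState) -> float:
    c = state.config
    mode = c.extremist_sigma_ref
    if mode == "initial_belief_sd":
        return c.sigma_true / math.sqrt(c.n_init_samples)
    if mode == "sigma_true":
        return c.sigma_true
    return float(np.std(state.mu, ddof=1))  # population


def initialize(config: SimulationConfig) -> SimulationState:
    """Seeded construction of the initial population, beliefs, and topology.

    RNG consumption order is fixed (initial belief draws, Socratic
    selection, topology construction) so identical seeds give identical
    runs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    world = WorldTruth(config.mu_true, config.sigma_true)
    n, k = config.n_agents, config.n_init_samples

    draws = rng.normal(world.mu_true, world.sigma_true, size=(n, k))
    mu = draws.mean(axis=1)
    m2 = ((draws - mu[:, None]) ** 2).sum(axis=1)
    count = np.full(n, k, dtype=np.int64)
    sigma = np.maximum(np.sqrt(m2 / (k - 1)), config.sigma_floor)
    with np.errstate(divide="ignore"):
        log_p_h = np.full(n, np.log(config.initial_p_h) if config.initial_p_h > 0 else -np.inf)

    kind = np.full(n, KIND_STOCHASTIC if config.beta is None else KIND_CONFIRMATORY, dtype=np.int8)
    n_soc = int(round(config.socratic_fraction * n))
    if n_soc > 0:
        soc_idx = rng.choice(n, size=n_soc, replace=False)
        kind[soc_idx] = KIND_SOCRATIC
    beta = np.full(n, np.nan if config.beta is None else float(config.beta))

    pos = reach = graph = None
    if config.topology == RANDOM_SPATIAL:
        pos = rng.uniform(0.0, config.grid_side, size=(n, 2))
        radius = reach_radius(config.alpha, config.grid_side)
        if math.isfinite(radius):
            d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            reach = d2 <= radius * radius
            np.fill_diagonal(reach, False)
    else:
        topo = TopologyConfig(
            alpha=config.alpha,
            gamma=config.gamma,
            n_agents=n,
            sf_dialect=config.sf_dialect,
            grid_side=config.grid_side,
        )
        graph = grow_scale_free(topo, rng)

    memory = [list(map(float, draws[i])) for i in range(n)] if config.track_memory else None

    state = SimulationState(
        config=config,
        world=world,
        step_index=0,
        mu=mu,
        count=count,
        m2=m2,
        sigma=sigma,
        log_p_h=log_p_h,
        kind=kind,
        beta=beta,
        rng=rng,
        metrics=MetricsSeries(),
        pos=pos,
        reach_mask=reach,
        graph=graph,
        memory=memory,
    )
    _record_metrics(state, full=True, max_abs_dmu=0.0)
    return state


# ---------------------------------------------------------------------------
# acceptance machinery (vectorized over "others" for one focal agent)

def _acceptance_row(
    state: SimulationState,
    i: int,
    mu_ref: np.ndarray,
    sigma_ref: np.ndarray,
) -> np.ndarray:
    """Boolean mask over all agents: does ``i`` accept each one's stated belief?

    ``mu_ref``/``sigma_ref`` are the arrays the focal agent observes
    (live arrays in asynchronous mode, frozen copies in synchronous mode).
    """
    c = state.config
    d = np.abs(mu_ref - state.mu[i])
    k = int(state.kind[i])
    if k == KIND_STOCHASTIC and c.stochastic_beta_mode == "ignore":
        mask = np.ones(state.n_agents, dtype=bool)
    else:
        b = float(state.beta[i])
        half = math.inf if math.isnan(b) else b * float(state.sigma[i])
        inside = d <= half
        if k == KIND_SOCRATIC:
            mask = (~inside) & (d <= c.overlap_k * (state.sigma[i] + sigma_ref))
        else:
            mask = inside
    mask[i] = False
    return mask


def _accepts_scalar(state: SimulationState, i: int, j: int) -> bool:
    """Does agent ``i`` accept agent ``j``, per i's kind and current state?"""
    c = state.config
    k = int(state.kind[i])
    d = abs(float(state.mu[j]) - float(state.mu[i]))
    if k == KIND_STOCHASTIC and c.stochastic_beta_mode == "ignore":
        return True
    b = float(state.beta[i])
    half = math.inf if math.isnan(b) else b * float(state.sigma[i])
    inside = d <= half
    if k == KIND_SOCRATIC:
        return (not inside) and d <= c.overlap_k * (float(state.sigma[i]) + float(state.sigma[j]))
    return inside


def _apply_evidence_batch(state: SimulationState, i: int, x: np.ndarray) -> None:
    """Integrate a turn's accepted evidence values for agent ``i``.

    Confidence: clamped running product of likelihood ratios (exact via
    the running-ceiling scan identity).  Belief: Chan batch merge of
    (count, mean, M2), then the sample-SD with the certainty floor.
    """
    if x.size == 0:
        return
    c = state.config
    mu_i, sig_i = float(state.mu[i]), float(state.sigma[i])
    # log N(x; mu_own, sigma_own) - log N(x; mu_true, sigma_true)
    zo = (x - mu_i) / sig_i
    zt = (x - state.world.mu_true) / state.world.sigma_true
    log_lr = (math.log(state.world.sigma_true) - math.log(sig_i)) - 0.5 * (zo * zo - zt * zt)
    run = state.log_p_h[i] + np.cumsum(log_lr)
    state.log_p_h[i] = run[-1] - max(0.0, float(run.max()))

    nb = x.size
    na = int(state.count[i])
    if c.belief_update_mode == "conjugate":
        # precision-weighted Gaussian update with known evidence noise sigma_true
        tau0 = 1.0 / (sig_i * sig_i)
        tau_e = 1.0 / (state.world.sigma_true**2)
        tau1 = tau0 + nb * tau_e
        state.mu[i] = (mu_i * tau0 + float(x.sum()) * tau_e) / tau1
        state.sigma[i] = max(math.sqrt(1.0 / tau1), c.sigma_floor)
        state.count[i] = na + nb
    else:
        mean_b = float(x.mean())
        m2_b = float(((x - mean_b) ** 2).sum())
        delta = mean_b - float(state.mu[i])
        n_tot = na + nb
        state.mu[i] += delta * nb / n_tot
        state.m2[i] += m2_b + delta * delta * na * nb / n_tot
        state.count[i] = n_tot
        state.sigma[i] = max(math.sqrt(state.m2[i] / (n_tot - 1)), c.sigma_floor)
    if state.memory is not None:
        state.memory[i].extend(x.tolist())


def _prune_and_rewire(state: SimulationState, i: int) -> None:
    """Scale-free maintenance after agent ``i``'s turn.

    A link is dropped only on mutual rejection; each dropped link is
    replaced (at most) by one preferential re-contact among agents ``i``
    currently accepts, keeping the total link count from growing.
    """
    g = state.graph
    removed = 0
    for b in list(g.adj[i]):
        if not _accepts_scalar(state, i, b) and not _accepts_scalar(state, b, i):
            g.remove_edge(i, b)
            removed += 1
    if removed == 0:
        return
    acceptable = _acceptance_row(state, i, state.mu, state.sigma)
    acceptable[list(g.adj[i])] = False
    candidates = np.nonzero(acceptable)[0].tolist()
    rewire_preferential(g, i, candidates, removed, state.rng)


def step(state: SimulationState, config: Optional[SimulationConfig] = None, *, full_metrics: Optional[bool] = None) -> SimulationState:
    """Advance the simulation by one time step (in place).

    ``full_metrics`` overrides the ``metrics_every`` cadence for the
    appended row (purity / link count / degree histogram are the costly
    fields; belief-change and confidence summaries are always recorded).
    """
    c = config or state.config
    n = state.n_agents
    prev_mu = state.mu.copy()

    if c.stochastic_beta_mode == "random":
        stoch = state.kind == KIND_STOCHASTIC
        state.beta[stoch] = state.rng.uniform(0.1, 2.0, size=int(stoch.sum()))

    synchronous = c.update_order == "synchronous"
    mu_ref = state.mu.copy() if synchronous else state.mu
    sigma_ref = state.sigma.copy() if synchronous else state.sigma
    order = state.rng.permutation(n)

    sf = state.graph is not None
    for i in order:
        i = int(i)
        if sf:
            nbrs = np.fromiter(state.graph.adj[i], dtype=np.int64, count=state.graph.degree(i))
            if nbrs.size:
                row = _acceptance_row(state, i, mu_ref, sigma_ref)
                accepted = nbrs[row[nbrs]]
            else:
                accepted = nbrs
            x = mu_ref[accepted]
        else:
            mask = _acceptance_row(state, i, mu_ref, sigma_ref)
            if state.reach_mask is not None:
                mask &= state.reach_mask[i]
            x = mu_ref[mask]
        _apply_evidence_batch(state, i, np.asarray(x, dtype=float))
        if sf:
            _prune_and_rewire(state, i)

    state.step_index += 1
    dmu = float(np.max(np.abs(state.mu - prev_mu))) if n else 0.0
    if full_metrics is None:
        full_metrics = state.step_index % c.metrics_every == 0
    _record_metrics(state, full=full_metrics, max_abs_dmu=dmu)
    if logger.isEnabledFor(logging.DEBUG):
        row = state.metrics.df.iloc[-1]
        checksum = zlib.crc32(repr(state.rng.bit_generator.state).encode())
        logger.debug(
            "step=%d mean_p_h=%.6f purity=%s extremists=%d links=%s rng=%08x",
            state.step_index, row.mean_p_h, row.purity, row.n_extremists, row.n_links, checksum,
        )
    return state


def broadcast(state: SimulationState, config: Optional[SimulationConfig] = None) -> SimulationState:
    """Educational broadcast: every agent receives the true state as evidence.

    The signal value is ``mu_true``; by default it bypasses the acceptance
    filter (it reaches every agent), with a filtered mode available.  The
    mean confidence drop among the agents who were extremists just before
    the signal is recorded in ``state.broadcast_log``.
    """
    c = config or state.config
    n = state.n_agents
    x = state.world.mu_true
    if c.broadcast_bypasses_filter:
        targets = np.ones(n, dtype=bool)
    else:
        targets = np.array([_accepts_scalar_value(state, i, x) for i in range(n)])

    sigma_ref = _extremist_sigma_ref(state)
    extremists = np.abs(state.mu - state.world.mu_true) > c.extremist_k_sd * sigma_ref
    p_before = np.exp(state.log_p_h)

    zo = (x - state.mu[targets]) / state.sigma[targets]
    log_lr = np.log(state.world.sigma_true) - np.log(state.sigma[targets]) - 0.5 * zo * zo
    state.log_p_h[targets] = np.minimum(0.0, state.log_p_h[targets] + log_lr)

    if c.belief_update_mode == "conjugate":
        tau0 = 1.0 / state.sigma[targets] ** 2
        tau_e = 1.0 / (state.world.sigma_true**2)
        tau1 = tau0 + tau_e
        state.mu[targets] = (state.mu[targets] * tau0 + x * tau_e) / tau1
        state.sigma[targets] = np.maximum(np.sqrt(1.0 / tau1), c.sigma_floor)
        state.count[targets] += 1
    else:
        na = state.count[targets].astype(float)
        delta = x - state.mu[targets]
        state.mu[targets] += delta / (na + 1)
        state.m2[targets] += delta * (x - state.mu[targets])
        state.count[targets] += 1
        # sample SD over na + 1 memory items has denominator na
        state.sigma[targets] = np.maximum(np.sqrt(state.m2[targets] / na), c.sigma_floor)
    if state.memory is not None:
        for i in np.nonzero(targets)[0]:
            state.memory[int(i)].append(float(x))

    p_after = np.exp(state.log_p_h)
    hit = extremists & targets
    drop = float(np.mean(p_before[hit] - p_after[hit])) if hit.any() else float("nan")
    state.broadcast_log.append(
        dict(step=state.step_index + 1, n_extremists=int(extremists.sum()), mean_p_h_drop=drop)
    )
    return state


def _accepts_scalar_value(state: SimulationState, i: int, value: float) -> bool:
    c = state.config
    k = int(state.kind[i])
    if k == KIND_STOCHASTIC and c.stochastic_beta_mode == "ignore":
        return True
    d = abs(value - float(state.mu[i]))
    b = float(state.beta[i])
    half = math.inf if math.isnan(b) else b * float(state.sigma[i])
    if k == KIND_SOCRATIC:
        # the broadcast has no belief distribution of its own; treat its
        # spread as zero so overlap means within overlap_k * sigma_own
        return d > half and d <= c.overlap_k * float(state.sigma[i])
    return d <= half


def run(config: SimulationConfig) -> SimulationState:
    """Execute a full simulation: ``horizon`` steps with scheduled broadcasts.

    Broadcasts fire at the start of step t whenever ``t mod round(1/nu) == 0``
    (t > 0).  The run is bitwise-reproducible for a given seed.  The final
    step always records the full metrics row regardless of cadence.
    """
    config.validate()
    state = initialize(config)
    period = config.broadcast_period
    for t in range(1, config.horizon + 1):
        if period is not None and t % period == 0:
            broadcast(state, config)
        step(state, config, full_metrics=(t % config.metrics_every == 0) or t == config.horizon)
    return state


def detect_stable_state(metrics: MetricsSeries, tol: float = 1e-4, window: int = 10):
    """First step t at which no agent's belief mean moves by >= ``tol``
    for ``window`` consecutive recorded steps; :data:`NOT_CONVERGED` if none.

    Row t of the series records the largest per-agent belief change during
    step t (0 at t=0), so an all-frozen series returns 0.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    dmu = metrics.df["max_abs_dmu"].to_numpy()
    below = dmu < tol
    for t in range(len(below) - window + 1):
        if below[t : t + window].all():
            return t
    return NOT_CONVERGED


# ---------------------------------------------------------------------------
# metrics recording and snapshots

def _acceptance_matrix(state: SimulationState) -> np.ndarray:
    """acc[i, j] — does agent i currently accept agent j's stated belief?"""
    c = state.config
    mu, sigma = state.mu, state.sigma
    d = np.abs(mu[:, None] - mu[None, :])
    half = state.beta * sigma
    if c.stochastic_beta_mode == "ignore":
        half = np.where(state.kind == KIND_STOCHASTIC, np.inf, half)
    half = np.where(np.isnan(half), np.inf, half)
    inside = d <= half[:, None]
    acc = inside
    soc = state.kind == KIND_SOCRATIC
    if soc.any():
        overlap = d <= c.overlap_k * (sigma[:, None] + sigma[None, :])
        acc = np.where(soc[:, None], (~inside) & overlap, inside)
    np.fill_diagonal(acc, False)
    return acc


def _link_mask(state: SimulationState) -> np.ndarray:
    """Symmetric link matrix for the random model: a link exists between a
    pair in mutual reach when at least one endpoint accepts the other."""
    acc = _acceptance_matrix(state)
    links = acc | acc.T
    if state.reach_mask is not None:
        links &= state.reach_mask
    return links


def _record_metrics(state: SimulationState, full: bool, max_abs_dmu: float) -> None:
    p = np.exp(state.log_p_h)
    c = state.config
    sigma_ref = _extremist_sigma_ref(state)
    n_ext = int(
        np.count_nonzero(np.abs(state.mu - state.world.mu_true) > c.extremist_k_sd * sigma_ref)
    )
    purity = n_links = float("nan")
    hist = None
    if full:
        if state.graph is not None:
            edges = np.asarray(state.graph.edges, dtype=np.int64)
            n_links = edges.shape[0]
            if n_links:
                purity = 1.0 - float(np.abs(state.mu[edges[:, 0]] - state.mu[edges[:, 1]]).mean())
            degrees = np.zeros(state.n_agents, dtype=np.int64)
            for node, deg in state.graph.degree():
                degrees[node] = deg
        else:
            links = _link_mask(state)
            iu = np.triu(links)
            n_links = int(iu.sum())
            if n_links:
                d = np.abs(state.mu[:, None] - state.mu[None, :])
                purity = 1.0 - float(d[iu].sum()) / n_links
            degrees = links.sum(axis=1)
        vals, counts = np.unique(degrees, return_counts=True)
        hist = {int(v): int(cnt) for v, cnt in zip(vals, counts)}
    state.metrics.append(
        step=state.step_index,
        mean_p_h=float(p.mean()),
        sd_p_h=float(p.std(ddof=1)) if state.n_agents > 1 else 0.0,
        purity=purity,
        n_extremists=n_ext,
        n_links=float(n_links),
        max_abs_dmu=max_abs_dmu,
        degree_hist=hist,
    )


def snapshot_graph(state: SimulationState) -> nx.Graph:
    """Materialize the current social graph with belief attributes.

    For the random model the edge set is the current acceptance-filtered
    reach structure; for the scale-free model it is the maintained link
    set.  Node attributes: mu_own, sigma_own, p_h, agent_kind (and x, y
    for spatial runs).
    """
    if state.graph is not None:
        g = nx.Graph(topology=SCALE_FREE)
        g.add_nodes_from(range(state.n_agents))
        g.add_edges_from(state.graph.edges)
    else:
        g = nx.Graph(topology=RANDOM_SPATIAL)
        g.add_nodes_from(range(state.n_agents))
        links = _link_mask(state)
        ii, jj = np.nonzero(np.triu(links))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    p = np.exp(state.log_p_h)
    for i in range(state.n_agents):
        g.nodes[i]["mu_own"] = float(state.mu[i])
        g.nodes[i]["sigma_own"] = float(state.sigma[i])
        g.nodes[i]["p_h"] = float(p[i])
        g.nodes[i]["agent_kind"] = KIND_NAMES[int(state.kind[i])]
        if state.pos is not None:
            g.nodes[i]["x"] = float(state.pos[i, 0])
            g.nodes[i]["y"] = float(state.pos[i, 1])
    return g


def final_states_frame(state: SimulationState):
    """Final agent states as a tidy table (one row per agent)."""
    import pandas as pd

    g = snapshot_graph(state)
    p = np.exp(state.log_p_h)
    return pd.DataFrame(
        dict(
            agent_id=np.arange(state.n_agents),
            kind=[KIND_NAMES[int(k)] for k in state.kind],
            mu_own=state.mu,
            sigma_own=state.sigma,
            p_h=p,
            degree=[g.degree(i) for i in range(state.n_agents)],
        )
    )
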