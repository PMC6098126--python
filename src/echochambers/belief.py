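"""Single-agent Bayesian belief machinery.

Each agent holds a Gaussian belief about a scalar world state: a point
estimate ``mu_own``, an uncertainty ``sigma_own`` (the SD of its
belief-state distribution), and a confidence ``p_h`` — the posterior
probability P(H|E) that its estimate equals the objective truth.

Agents are honest and error-free: evidence is another agent's stated
estimate, integrated with perfect memory.  Confidence is revised by the
likelihood-ratio form of Bayes' theorem,

    P(H|E) = P(H) * P(E|H) / P(E),

where P(E) is the Gaussian density of the evidence under the *true*
distribution N(mu_true, sigma_true) and P(E|H) its density under the
agent's own belief distribution N(mu_own, sigma_own).  Because the ratio
of two densities is unbounded, the posterior is clamped to [0, 1].

The point estimate and uncertainty themselves evolve as the running mean
and sample SD (ddof=1) of everything the agent has ever accepted — the
"memory mode" of belief revision, which is the same rule that defines the
initial state (mean/SD of the first five samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "UNUSED",
    "BeliefState",
    "WorldTruth",
    "EvidenceUpdate",
    "DegenerateBeliefError",
    "gaussian_density",
    "initialize_belief",
    "bayes_confidence_update",
    "integrate_evidence",
    "accepts",
    "socratic_accepts",
]

#: Sentinel for a disabled acceptance window ("stochastic" agents ignore beta).
UNUSED = None

#: Smallest admissible belief SD; an agent at the floor is subjectively certain.
SIGMA_FLOOR = 1e-6


class DegenerateBeliefError(ValueError):
    """Raised when a belief distribution has zero spread and a density is needed."""


def gaussian_density(x: float, mu: float, sigma: float) -> float:
    """Normal probability density of ``x`` under N(mu, sigma).

    This is the likelihood machinery for both P(E) (densities under the
    true distribution) and P(E|H) (under the agent's belief distribution).

    Parameters
    ----------
    x : float
        Point at which to evaluate the density (the evidence value).
    mu, sigma : float
        Mean and standard deviation of the distribution; ``sigma`` must be
        strictly positive.

    Returns
    -------
    float
        The density, strictly positive and maximal at ``x == mu``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    z = (x - mu) / sigma
    return math.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


@dataclass
class WorldTruth:
    """The objective state of the world.

    ``mu_true`` is the quantity every agent is trying to estimate
    (default 0.5 on the [0, 1] belief scale); ``sigma_true`` is the SD of
    the noisy sampling distribution around it, used both for the initial
    draws and as the reference distribution in P(E).
    """

    mu_true: float = 0.5
    sigma_true: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma_true <= 0:
            raise ValueError(f"sigma_true must be > 0, got {self.sigma_true}")


@dataclass
class EvidenceUpdate:
    """One Bayesian confidence-revision event.

    Records the communicated value ``x``, the two Gaussian densities, their
    likelihood ratio, and the clamped posterior confidence.
    """

    x: float
    p_e: float
    p_e_given_h: float
    likelihood_ratio: float
    p_h_posterior: float


@dataclass
class BeliefState:
    """An agent's epistemic state.

    ``memory`` holds every evidence value the agent has ever integrated
    (the initial samples plus each accepted communication); ``mu_own`` and
    ``sigma_own`` are always the arithmetic mean and sample SD (ddof=1) of
    that memory.
    """

    mu_own: float
    sigma_own: float
    p_h: float
    memory: list = field(default_factory=list)

    @classmethod
    def from_memory(cls, memory: Sequence[float], p_h: float = 0.5) -> "BeliefState":
        """Build a state whose summary statistics are derived from ``memory``."""
        mem = [float(v) for v in memory]
        if len(mem) < 2:
            raise ValueError("memory must hold at least 2 values to define a sample SD")
        arr = np.asarray(mem)
        return cls(
            mu_own=float(arr.mean()),
            sigma_own=float(arr.std(ddof=1)),
            p_h=float(p_h),
            memory=mem,
        )


def initialize_belief(
    world: WorldTruth,
    n_samples: int = 5,
    rng: Union[int, np.random.Generator, None] = None,
    initial_p_h: float = 0.5,
) -> BeliefState:
    """Draw an agent's initial belief from noisy samples of the truth.

    The agent samples ``n_samples`` values from N(mu_true, sigma_true); the
    mean of those samples is its initial hypothesis and their sample SD its
    initial uncertainty.  The averaging biases initial beliefs toward the
    central value, so the population of initial estimates has SD
    approximately sigma_true / sqrt(n_samples).

    Raises
    ------
    ValueError
        If ``n_samples`` < 2 (the sample SD would be undefined).
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    draws = gen.normal(world.mu_true, world.sigma_true, size=n_samples)
    return BeliefState.from_memory(draws.tolist(), p_h=initial_p_h)


def bayes_confidence_update(
    state: BeliefState, x: float, world: WorldTruth
) -> EvidenceUpdate:
    """Revise confidence P(H|E) for one piece of evidence ``x``.

    Computes P(E) under the true distribution, P(E|H) under the agent's
    belief distribution, and the posterior ``min(1, p_h * ratio)``.  If the
    evidence is more likely under the agent's hypothesis than under the
    true distribution the ratio exceeds 1 and confidence rises; otherwise
    it falls.

    Raises
    ------
    DegenerateBeliefError
        If ``state.sigma_own`` is zero; callers should floor the SD at
        :data:`SIGMA_FLOOR` before updating.
    """
    if state.sigma_own <= 0:
        raise DegenerateBeliefError(
            "belief SD is zero; apply the certainty floor before updating"
        )
    p_e = gaussian_density(x, world.mu_true, world.sigma_true)
    p_e_given_h = gaussian_density(x, state.mu_own, state.sigma_own)
    ratio = p_e_given_h / p_e
    posterior = min(1.0, state.p_h * ratio)
    return EvidenceUpdate(
        x=float(x),
        p_e=p_e,
        p_e_given_h=p_e_given_h,
        likelihood_ratio=ratio,
        p_h_posterior=posterior,
    )


def integrate_evidence(state: BeliefState, x: float) -> BeliefState:
    """Commit evidence ``x`` to memory and refresh the summary statistics.

    Returns a new state; ``mu_own``/``sigma_own`` are recomputed from the
    full memory, so integration order never matters for them.
    """
    if not math.isfinite(x):
        raise ValueError(f"evidence must be finite, got {x}")
    memory = state.memory + [float(x)]
    arr = np.asarray(memory)
    return BeliefState(
        mu_own=float(arr.mean()),
        sigma_own=float(arr.std(ddof=1)),
        p_h=state.p_h,
        memory=memory,
    )


def accepts(state: BeliefState, mu_other: float, beta: Optional[float]) -> bool:
    """Acceptance-window test for confirmatory information search.

    The agent engages with a stated belief ``mu_other`` iff it lies in the
    closed interval ``mu_own ± beta * sigma_own``.  Smaller ``beta`` means
    stronger confirmatory pruning; ``beta is UNUSED`` disables the filter
    entirely (stochastic agents accept everything).
    """
    if beta is UNUSED:
        return True
    half_width = beta * state.sigma_own
    return (state.mu_own - half_width) <= mu_other <= (state.mu_own + half_width)


def socratic_accepts(
    state: BeliefState,
    other: BeliefState,
    beta: Optional[float],
    overlap_k: float = 3.0,
) -> bool:
    """Anti-confirmatory acceptance rule.

    A Socratic agent engages only with agents whose views are *outside* its
    own acceptance window but whose belief distributions still overlap its
    own: ``|mu_own - mu_other| <= overlap_k * (sigma_own + sigma_other)``.
    """
    if overlap_k <= 0:
        raise ValueError(f"overlap_k must be > 0, got {overlap_k}")
    if accepts(state, other.mu_own, beta):
        return False
    return abs(state.mu_own - other.mu_own) <= overlap_k * (
        state.sigma_own + other.sigma_own
    )
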