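# Methods

## Model

A population of n agents estimates an objective scalar world state
μ_true (default 0.5). Agent i's epistemic state is (μ_own, σ_own,
P(H|E), memory): a Gaussian belief with mean μ_own and SD σ_own, a
bounded confidence that μ_own equals μ_true, and the full list of
evidence values ever integrated. All agents are honest (they transmit
their current μ_own), fully trusting, cognitively identical, and update
by Bayes' rule — by construction, any polarization the model produces
cannot be blamed on bias, dishonesty, or memory limits.

**Initialization.** Each agent draws `n_init_samples` = 5 values from
N(μ_true, σ_true); μ_own and σ_own are their mean and sample SD
(ddof = 1), and the draws seed the memory. The belief scale is [0, 1]
and σ_true defaults to 0.25, so initial belief means are distributed
≈ N(0.5, 0.25/√5). Initial confidence is 0.5 (uninformative,
configurable).

**Confidence update.** For evidence X, the likelihood ratio is the
Gaussian density of X under the agent's own belief distribution divided
by its density under the true distribution; the posterior is
min(1, P(H)·ratio). Confidence rises when evidence is more plausible
under the agent's hypothesis than under the truth-centered reference
distribution, and is clamped because density ratios are unbounded.

**Belief update ("memory mode", default).** μ_own and σ_own are the
running mean and sample SD of the memory. This is the same rule that
defines the initial state, and it makes the belief literally the
sufficient statistic of everything the agent has accepted under perfect
memory. A conjugate-Gaussian alternative
(`agents.belief_update_mode: conjugate`) performs the textbook
precision-weighted update with known evidence noise σ_true; it shares
the 1/N-weighting of new evidence and therefore similar long-run
dynamics.

**Acceptance.** A confirmatory agent engages with a stated belief
μ_other iff μ_own − βσ_own ≤ μ_other ≤ μ_own + βσ_own. β spans strongly
confirmatory (0.1) to very open-minded (2); "unused" disables the filter
("stochastic" agents; an alternative mode re-draws β ~ U(0.1, 2) each
step, both printed readings of the stochastic condition). Socratic
agents invert the rule: they engage only with peers *outside* their
window whose belief distributions still overlap their own,
|Δμ| ≤ overlap_k·(σ_own + σ_other). The overlap notion is not uniquely
determined by a verbal description of "overlapping distributions", so
`overlap_k` is an explicit parameter (default 3) rather than a hidden
constant. Pruning is driven by the σ_own-based window — the
formula-level definition — not by P(H|E) directly; because σ_own shrinks
as agents accrue evidence, rising confidence narrows the window
indirectly, which reproduces the intended "more confident, less
receptive" coupling without making confidence a second filter.

**Scheduling.** Each step processes agents in a seeded-shuffled order
(asynchronous; a synchronous mode exists for sensitivity checks). On its
turn an agent collects all accepted candidates — its spatial reach set
in the random model, its linked neighbors in the scale-free model — and
integrates one evidence item per accepted peer (the peer's μ_own at that
moment). Acceptance filtering and all likelihood ratios of a turn are
evaluated against the agent's turn-start state, and the turn's evidence
enters memory as one batch: memory statistics are order-invariant, so
μ/σ are exact, and the ratio-by-ratio clamped confidence product has the
closed form log p_final = log p₀ + S_k − max(0, max_j(log p₀ + S_j))
over the running sum S of log likelihood ratios, which the engine
vectorizes. Whether an agent's own state evolves *between* peers inside
a single turn is not observable to the peers (their states cannot change
mid-turn), and we fix it as frozen-within-turn.

**Topologies.**
*Random spatial*: agents sit at fixed uniform positions on a 100×100
arena; the reach radius solves πr² = α·100², with α = 1 meaning total
range. Distances are plain Euclidean (no toroidal wrap; edge agents
genuinely reach fewer peers, which is the literal reading of distance on
a bounded grid). The network at any instant is the acceptance-filtered
reach structure; for the purity and degree metrics a link exists between
a pair in mutual reach when at least one endpoint accepts the other (a
link dies only on mutual rejection).
*Scale-free*: grown by sequential single-link attachment with
redirection probability r = 1/(γ−1), which yields a degree exponent ≈ γ
(2.5 by default); the literal attachment rule p(k) ∝ k^−γ is retained as
a dialect (`literal_rule`) but favors low-degree nodes and cannot
produce a scale-free graph, so the outcome-targeting generator is the
default. Scale-free agents have no positions; population scaling
n_SF = α·n_R in sweeps equalizes expected contact numbers across
topologies. Pruned links are replaced by sampling acceptable
non-neighbors without replacement with probability ∝ degree (degree-0
weight 1), keeping the heavy-tailed link distribution; an agent with no
acceptable candidates is starved and keeps its reduced degree.

**Broadcasts.** With frequency ν > 0, at every step t with
t mod round(1/ν) = 0 the true value μ_true is delivered to every agent
as ordinary evidence before that step's exchanges. By default the signal
bypasses the acceptance window (it reaches everyone); a filtered mode
delivers it only to agents whose window admits μ_true. Each broadcast
logs the mean confidence drop among the agents who were extremists just
before it fired.

**Stopping.** Runs execute a fixed horizon (default 200 steps) so
replicate series align; `detect_stable_state` reports the first step
from which no agent's belief mean moves by ≥ tol (default 1e-4) for a
trailing window (default 10 steps), and is reported rather than used for
early exit.

## Metrics

*Belief purity* ε = 1 − (Σ|μ_a − μ_b| / n_L) over the n_L current links;
differences are absolute (signed differences would not bound ε in
[0, 1]), normalization is global (per-component normalization is a
possible variant we do not use). ε is undefined (error, not 1.0) on a
linkless graph. ε measures within-link agreement, not consensus: two
internally unanimous clusters at opposite ends of the scale still score
1, which is exactly what makes it an echo-chamber indicator.

*Extremists*: agents with |μ_own − μ_true| strictly greater than
k_sd (default 2) reference SDs. The reference SD defaults to
σ_true/√n_init_samples — the SD of the *initial belief-mean
distribution*, which is the scale beliefs actually occupy and is fixed
over time so counts are comparable across steps. (Using σ_true itself
would put the threshold at 0.5, outside the reachable belief range, and
no agent could ever qualify; both that mode and a time-varying
population-SD mode remain configurable.)

*Replicate summaries*: per-step mean and normal-approximation 95% CI
(mean ± 1.96·SE) across replicates, as in the reference experimental
design of 100 replicates per parameter combination.

## Numerical choices

- Sample SD uses ddof = 1 everywhere (stated for reproducibility).
- σ_own is floored at 1e-6; an agent at the floor is treated as
  subjectively certain, keeping the likelihood machinery defined.
- Confidence is held in log space; the clamp at 1 uses the exact
  running-ceiling identity above, so vectorized turns equal the scalar
  sequential rule to rounding.
- Memory statistics use Chan's batch merge of (count, mean, M2); full
  memory lists are optional (`run.track_memory`) because an α = 1,
  n = 1000 run accumulates ~10⁸ evidence values. Statistics are exact
  either way, and invariant tests recompute them from tracked memory.
- All randomness flows from one `numpy` Generator per run with a fixed
  consumption order (initial draws, Socratic selection, topology, then
  steps), so equal seeds give bitwise-equal outputs.
- Serialized numbers are written at 12 significant digits so sweep
  checksums are stable.

## Problem sizes

Baseline study conditions are n = 1000 agents, α = 1, β = 1,
σ_true = 0.25, horizon 200. The acceptance script uses 10 replicates for
the stability quantity and 20 common-seed pairs for the Socratic
comparison. In the test suite, claims tied to the n = 1000 scale run at
that scale; ordering and calibration properties that are not
scale-specific run at n = 250–300 with 10–30 replicates.

## What the model does and does not capture — known limitations

The simulation is a stylized laboratory, not a calibrated model of any
real platform: agents are static, links are unweighted and undirected,
there is no content, no recommendation algorithm, no entry/exit, and the
"truth" is a single scalar. Passing tests show the *mechanism* —
confirmatory pruning plus Bayesian certainty growth producing persistent,
purified clusters — not predictions about real social-media data.

Two structural consequences of the dense-exchange design deserve
emphasis. Because an agent integrates one item per accepted peer per
step, evidence flux scales with cluster size: large clusters
hyper-converge (within-link differences reach ~1e-4, so ε saturates very
near 1), agents between clusters merge into them on a slow ~1/t
schedule, and confidence rebuilds to 1 within a single step after any
perturbation. This compresses the purity scale (making relative effects
of interventions on ε small at weak pruning and large at strong
pruning), delays the last agents' convergence past the point where the
belief *histogram* is visually stable, and makes each broadcast's
confidence impact on surviving extremists total rather than waning.
Variants of this model family in which agents sample only a bounded
number of partners per step decouple evidence flux from cluster size and
can behave differently on all three counts; such a bound is not part of
this model's definition, and we do not introduce one.
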