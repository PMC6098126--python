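# echochambers

Agent-based simulation of echo-chamber formation among **honest,
error-free Bayesian agents** on social networks.

Echo chambers — enclosed epistemic circles in which like-minded agents
reinforce shared beliefs — are usually attributed to cognitive biases.
This package implements a model in which they emerge without any: agents
reason by Bayes' rule, communicate honestly, trust each other fully, and
remember everything. The only social ingredients are a limited search
range, a confirmatory acceptance window, and link pruning. The package
is for computational social scientists and opinion-dynamics researchers
who want a reproducible, scriptable implementation of this class of
bounded-confidence model, with its two stylized interventions
(anti-confirmatory "Socratic" agents and truthful educational broadcasts)
and the associated outcome metrics.

## The model

The objective state of the world is μ_true = 0.5. Each agent holds a
Gaussian belief with mean μ_own and uncertainty σ_own, initialized from
the mean and sample SD of 5 noisy draws from N(μ_true, σ_true). Agents
also carry a confidence P(H|E) — the posterior probability that
μ_own = μ_true — updated for each received evidence value X by

    P(H|E) = P(H) · P(E|H) / P(E),      clamped to [0, 1],

where P(E) is the Gaussian density of X under N(μ_true, σ_true) and
P(E|H) its density under N(μ_own, σ_own). Each time step, every agent
(in seeded-shuffled order):

1. finds candidate partners — everyone within spatial reach on a
   100×100 arena (reach radius set by the search fraction α via
   πr² = α·100²) in the random model, or linked neighbors in the
   scale-free model (grown with degree exponent γ ≈ 2.5);
2. keeps those whose stated belief falls inside its acceptance window
   μ_own ± β·σ_own (smaller β = more confirmatory; "unused" disables
   the filter; Socratic agents instead keep only *outside-window* peers
   whose belief distributions still overlap their own);
3. integrates each accepted peer's μ_own as evidence: confidence by the
   likelihood-ratio rule above, belief by perfect-memory averaging
   (μ_own, σ_own are always the mean and sample SD of everything ever
   accepted);
4. prunes links that have become mutually unacceptable (scale-free runs
   re-wire preferentially toward well-connected acceptable agents).

Optional periodic broadcasts transmit μ_true to every agent with
frequency ν (period 1/ν steps). The headline outcome is **belief
purity** ε = 1 − (Σᵢ Δᵢ / n_L), the complement of the mean absolute
belief difference across the n_L network links: ε → 1 as links come to
join only agents with near-identical beliefs — purified echo chambers —
while **extremists** (agents further than 2 reference SDs from μ_true)
may persist indefinitely.

## Worked example

```bash
python examples/baseline_echo_chambers.py
```

```
final belief purity (epsilon)   : 0.9999
mean confidence P(H|E)          : 1.0000
extremists (>2 ref SD from 0.5) : 1
stable state reached at step    : 57
agents > 0.05 off the truth     : 27 / 300
population mean belief          : 0.4999  (truth = 0.5)
```

Reading: after 200 steps, linked agents agree almost perfectly
(ε ≈ 0.9999) and everyone is subjectively certain (P(H|E) ≈ 1), yet 27
of 300 agents hold beliefs visibly off the truth — they sit in small,
internally unanimous clusters that pruning has sealed off from contrary
information. The population *mean* is on the truth; the *distribution*
is not. The other example scripts explore each capability:
`socratic_agents.py`, `educational_broadcasts.py`,
`scale_free_network.py`, `parameter_sweep.py`.

## Library, CLI, configs

The primary surface is the Python API (`SimulationConfig`, `run`,
`detect_stable_state`, `belief_purity`, `grow_scale_free`, `run_sweep`,
…). A thin CLI wraps it:

```bash
echochambers run --config config.yml --seed 1 --out results/
echochambers sweep --spec sweep.yml --out sweep_out/
echochambers metrics --states results/final_states.csv --graph results/network.graphml
echochambers validate-config config.yml
```

Configs are nested YAML (`world`, `topology`, `agents`,
`interventions`, `run` sections); unknown keys are errors and
`validate-config` exits 2 naming the offending key. Runs are
bit-reproducible per seed; sweeps derive every replicate's seed from the
cell parameters and write checksummed manifests.

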