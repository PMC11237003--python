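# torchsearch

Simulation and analysis tools for **gaze-contingent "torchlight" search
experiments**, in which participants (toddlers and adults) explore a dark
screen with an eye-controlled spotlight to find a hidden target. The
paradigm contrasts a predictable environment (*Skewed*: the target hides in
the same column throughout a block) with an unpredictable one (*Uniform*:
the target column changes every trial, and only an informative cue — a
treasure chest in the target's column — reveals it). The package is aimed at
researchers in developmental and computational cognitive science who want to
simulate, benchmark, and analyze adaptive information-seeking in this kind
of task without needing raw eye-tracking recordings.

## What it does

**1. Cue-gated Q-learning simulator** (`torchsearch.environment`,
`torchsearch.qlearning`). Search is modeled as movement between 8 screen
locations *S* = {0..7} (4 possible hiding locations above 4 cue locations,
4-connected). A tabular agent learns action values *Q(s, a, c)* — state,
move destination, cue location — by temporal difference:

    Q(s,a,c) ← Q(s,a,c) + α [ r + γ max_a' Q(s',a',c) − Q(s,a,c) ]

with an ε-greedy policy (ε = 0.5). In the Skewed condition the reward fires
on entering the predetermined target; in the Uniform condition it fires only
if the cue location was visited earlier in the episode — a non-Markovian
gate that forces the agent to learn the value of *information* rather than
of a fixed place. A grid search over (α, γ) identifies the most efficient
searcher.

**2. Scan-path complexity** (`torchsearch.markov`). Any sequence of AOI
visits — human fixations or agent states — is summarized by an 8×8 Markov
transition matrix *P* whose entropy

    H(P) = − Σ_{i,j} P_ij ln P_ij

quantifies how unpredictable the exploration is; results are reported as
log-entropy, ln H(P). Unstructured search (every transition at 12.5%)
attains the maximum, ln(8·ln 8) ≈ 2.81; systematic strategies score lower.
Matrices are estimated by a fixed-emission Markov model run with 30 random
initializations (each carrying a randomized Dirichlet pseudocount), and a
logistic contrast of two matrices tests *where* two groups differ — e.g.
whether toddlers transition into cue locations more than adults do.

**3. Synthetic cohort generator** (`torchsearch.cohort`). A biased-walk gaze
model produces a full study — 60 toddlers (18–36 months), 42 adults, 2
conditions × 2 blocks × 4 test trials each — with per-trial fixation
sequences and the four derived dependent variables: successful search
(200 ms target dwell, 150 ms cue dwell first in Uniform, 10 s timeout),
time-to-target, between-column scanning movements, and anticipatory looks.
Adaptivity ramps up with toddler age (logistic ramp centered at 24 months),
so condition effects emerge in older toddlers and adults but not younger
toddlers.

**4. Trial-level statistics** (`torchsearch.stats`). Logistic, linear, and
Poisson GLMs with participant-clustered robust standard errors, an AIC model
ladder (null / condition / condition+age / condition×age), Wald condition
contrasts per group, and Johnson–Neyman probing of the condition×age
interaction (at which age does the condition effect become significant?).

## Worked example

```python
import numpy as np
import torchsearch as ts

layout = ts.build_layout()
rng = np.random.default_rng(0)

# 1. Train the best-performing agent in each condition and measure search cost
params = ts.AgentParams(alpha=0.12, gamma=0.83, epsilon=0.5)
for name, spec in [("Skewed", ts.ConditionSpec("Skewed", skewed_target=0)),
                   ("Uniform", ts.ConditionSpec("Uniform"))]:
    Q, episodes = ts.train_agent(params, spec, layout, rng, n_train=300)
    steps = ts.evaluate_agent(Q, spec, params, layout, rng, n_test=1000)
    est, _ = ts.efficient_search_entropy(spec, params, layout, rng)
    print(f"{name:8s} mean test steps {steps:4.2f}   log-entropy {est.log_entropy:.3f}")
print(f"random baseline log-entropy {ts.random_baseline().log_entropy:.3f}")

# 2. Generate a synthetic cohort and probe the condition-by-age interaction
trials, seqs = ts.generate_cohort(ts.CohortConfig(), layout, rng)
toddlers = ts.trials_to_frame(trials, collapse_toddlers=True).query("group == 'toddler'")
model = ts.fit_glm(toddlers, "scanning_count", "poisson",
                   "condition * age_months", cluster_by="participant_id")
jn = ts.johnson_neyman(model)
print(f"scanning condition-by-age interaction: JN boundary {jn.boundary:.1f} months ({jn.side})")
```

prints

```
Skewed   mean test steps 4.37   log-entropy 2.121
Uniform  mean test steps 5.23   log-entropy 2.311
random baseline log-entropy 2.812
scanning condition-by-age interaction: JN boundary 25.1 months (above)
```

Read: the agent solves the predictable Skewed environment in fewer steps and
with a simpler (lower log-entropy) exploration pattern than the cue-gated
Uniform environment, and both trained strategies are far more systematic
than random search (2.81). In the synthetic cohort, the Uniform-versus-
Skewed difference in scanning becomes statistically detectable from roughly
two years of age onward — the age at which the generator's adaptivity ramp
is centered.

## Command line

```sh
torchsearch --seed 7 --out results run-all          # full pipeline + manifest
torchsearch --seed 7 --out results simulate-rl      # grid search + sequences
torchsearch --seed 7 --out results gen-cohort       # synthetic study CSVs
torchsearch --seed 7 --out results analyze-behavior # GLMs, AIC ladder, JN
torchsearch --seed 7 --out results entropy --source model
```

All artifacts are plain CSV/JSON, accompanied by data dictionaries, and are
byte-identical across reruns with the same seed and config (YAML config via
`--config`, any key overridable by flags).

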