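# aegng

An active-inference simulator of the **Avoid/Escape Go/No-Go task**, built
for computational-psychiatry work on how hopelessness, Pavlovian bias and
active-escape bias can arise from a single drive to maximise model
evidence. It is aimed at researchers who want a seeded, testable agent
whose clinically interpretable parameters — stress weight, belief-decay
threshold, stress sensitivity, controllability threshold — can be perturbed
one at a time to generate behavioral predictions.

## The model in brief

A discrete POMDP agent faces four cues (2 × 2: Go/No-Go × Avoid/Escape)
with probabilistic feedback (`y = 0.8`) and a mid-session reversal. Three
policies compete — instrumental Go, instrumental No-Go, and a rigid
Pavlovian mapping (withhold under distal threat, act under proximal
threat). With an unambiguous (one-hot) likelihood, policy evaluation
reduces to KL control:

```
pi ∝ E · exp(−γ · D_KL[ Q(o₃ | p) ‖ σ(C) ])
```

Transition beliefs are Dirichlet concentration parameters updated with a
valence-dependent learning rate and surprise-gated forgetting:

```
bᵢ(u) = bᵢ₋₁(u) + η Σₚ π^p s₃ᵖ ⊗ s₂ᵖ − (bᵢ₋₁(u) − 1)/λ
η  = 1 + k·|C(o)|
λ  = λ_min + (λ_max − λ_min) / (1 + e^{g·(SAPE − m)})
SAPE = D_KL[ S₃ᵗ ‖ S₃ᵗ⁻¹ ]       (policy-averaged final-state beliefs)
```

and perceived stressor controllability attenuates the stress response:

```
w_n = Σ_{i∈{6,8}} o₃(oᵢ),    w = 1/(1 + e^{−g_w(w_n − w₀)}),    c′ = c^{1−w}
```

Weak instrumental beliefs that any action reaches the neutral outcome
(*hopelessness*) raise the Pavlovian policy's relative model evidence,
which shows up behaviorally as an **active-escape bias**: higher accuracy
on Go-to-Escape than on No-Go-to-Escape trials. See `docs/methods.md` for
the full account, defaults and design choices.

## Worked example

Run the healthy-agent configuration (k = 0.1) for 50 replicate sessions of
200 trials with a reversal at trial 100:

```
aegng replicates --seed 0 --n 50 --out out/healthy
```

`out/healthy/aggregate.json` then contains (mean ± s.e.m. over replicates):

```
overall_accuracy      0.780 ± 0.009
active_escape_bias    0.279 ± 0.031
mean_pavlovian_prob   0.143 ± 0.004
mean_neutral_belief   0.534 ± 0.004
acc_pre_GA            0.764 ± 0.033      acc_pre_NGA  0.943 ± 0.008
acc_pre_GE            0.964 ± 0.007      acc_pre_NGE  0.709 ± 0.038
```

Read: the agent performs well above chance on every cue before the
reversal, but Escape-condition accuracy is higher when Go is correct (GE)
than when No-Go is correct (NGE) — the positive `active_escape_bias` of
0.28 — because the Pavlovian policy (14% of the posterior on average)
pushes Go whenever the aversive stimulus is playing. Raising the stress
weight to `k = 1` (put `k: 1.0` in a YAML file and pass `--config`)
weakens the neutral-transition beliefs (0.53 → ~0.40, hopelessness),
roughly doubles the Pavlovian probability and enlarges the bias — the
profile associated with suicidal thoughts and behaviors.

Other entry points:

```
aegng run --seed 7 --out out/single          # one session: trace.csv per trial
aegng sweep --preset w0 --seed 0 --out out/w0sweep
aegng trajectories --preset low-decay --seed 0 --out out/traj
```

`sweep` presets (`k`, `m`, `c`, `w0`) reproduce the four one-parameter
hypothesis-space sweeps (400 trials, reversal at 200, 50 replicates per
grid point, published fixed companion values). `trajectories` presets
(`low-decay`, `low-controllability`, `high-stress-weight`,
`high-stress-sensitivity`) trace beliefs and a counterfactual Pavlovian
posterior for the initially-NGE cue, separating gradual from spiking risk
dynamics. Every output directory includes a `manifest.json` sufficient for
bit-identical replay.

Python API:

```python
from aegng import Config, run_session, run_replicates, summarize

cfg = Config(k=1.0)                     # healthy defaults, raised stress weight
trace = run_session(cfg, seed=0)        # pandas DataFrame, one row per trial
stats = summarize(trace, cfg.reversal_trial)
print(stats.active_escape_bias)
```

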