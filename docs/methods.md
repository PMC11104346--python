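# Model and methods

## The task

The simulator implements an Avoid/Escape Go/No-Go task. Four cues cross the
required response (Go / No-Go) with the threat condition (Avoid: no aversive
stimulus during the decision; Escape: the aversive stimulus plays until the
outcome). On each trial one cue is drawn i.i.d. uniformly; the agent emits Go
or No-Go; the response that maximises the frequency of the neutral outcome
("correct") yields it with probability `y = 0.8`, the other with `1 - y`.
Halfway through the session every cue's correct response flips (reversal);
conditions never change. Cue labels (GA, NGA, GE, NGE) are contingency-
relative: after the reversal the cue whose correct response is now Go in the
Escape condition is the GE cue. The *active-escape bias* is
accuracy(GE) − accuracy(NGE).

Trials have three time points over 12 hidden states and 9 observations:
pre-cue states s1–s4 (uninformative o1), cue states s5–s8 (o2–o5), and
response+outcome states s9–s12 (o6–o9), with s9/s11 the neutral and s10/s12
the aversive outcomes of Go/No-Go respectively. The likelihood **A** is
one-hot (the stimuli are unambiguous) and identical in the generative
process and the generative model; it is never learned.

## The agent

The agent is a discrete active-inference agent with three single-step
policies: instrumental Go, instrumental No-Go, and a Pavlovian policy that
rigidly maps Avoid cues to No-Go and Escape cues to Go. Because outcomes
identify states unambiguously, the expected-free-energy score of a policy
reduces to KL control: the ambiguity term is identically zero under a
one-hot likelihood, so

```
G(p) = D_KL[ Q(o_3 | p) || sigma(C) ],        pi ∝ E · exp(-gamma · G(p))
```

where `Q(o_3 | p)` is the policy's predicted outcome distribution (the
normalized Dirichlet mean of its transition beliefs, or the fixed Pavlovian
model `B0` with neutral-outcome probability `z`), `sigma(C)` is the softmax
of the preference vector (−c at the four aversive observations o4, o5, o7,
o9; 0 elsewhere), `E` is the uniform policy prior and `gamma = 1/beta` is a
fixed policy precision. The already-observed t=2 outcome contributes a
policy-independent constant that cancels in the softmax; the full softmax
normaliser of `sigma(C)` likewise cancels. The action is sampled from the
precision-sharpened marginal action probabilities,
`P(Go) ∝ (pi_Go + pi_Pav·[Escape])^alpha`.

Policy precision is held fixed at `1/beta` rather than iteratively updated;
the precision dynamics of the full variational scheme are omitted to keep
the model identifiable, and `gamma` is exposed in the configuration.

## Learning

Instrumental transition beliefs are Dirichlet concentration parameters,
stored only on their structural support (Go reaches s9/s10, No-Go s11/s12;
other entries are exact zeros and never represented). After each trial

```
b_i(u) = b_{i-1}(u) + eta · pi(u) · (s_3 ⊗ s_2) − (b_{i-1}(u) − 1) / lambda
```

with the policy sum restricted to the two instrumental policies and `pi`
the post-action policy posterior (policies inconsistent with the taken
action are zeroed and the remainder renormalized). Increment and decay are
both evaluated at the pre-update concentrations, and decay relaxes every
supported entry of both matrices toward 1 on every trial, so unvisited
associations also fade.

The decay rate is gated by the state–action prediction error

```
SAPE = D_KL[ S_3(post) || S_3(pre) ],
lambda = lambda_min + (lambda_max − lambda_min) / (1 + exp(g·(SAPE − m)))
```

where the two `S_3` are the policy-averaged (BMA) final-state beliefs just
after and just before the outcome, both under the post-action posterior.
Large surprises shrink `lambda` (fast forgetting), which is what drives
re-learning after the reversal. The pre-outcome mixture is floored at
1e-16 before the log so structural zeros cannot produce infinities.

The learning rate depends on outcome valence:

```
eta = 1 + k · |C(o)|
```

with `C(o) = −c_eff` for aversive and 0 for neutral outcomes. The stress
weight `k` is the model's affective-bias dial: `k = 0` switches
valence-dependent learning off entirely.

## Controllability

Perceived stressor controllability attenuates the stress response. During
the decision phase the pre-action BMA is mapped through the likelihood to
expected outcomes; the mass on the two neutral outcomes is the raw estimate
`w_n`, transformed by a logistic with threshold `w0` and gradient `g_w`,
and the effective stress sensitivity is `c_eff = c^(1−w)`, so complete
perceived control collapses the stress response to 1 and no control leaves
it at the baseline `c`.

Two design choices here were genuinely open:

* **Where `c_eff` acts.** By default `c_eff` modulates only the
  valence-dependent learning rate (the stress *response* to outcomes);
  policies are evaluated with the baseline preference magnitude `c`. The
  alternative — feeding `c_eff` back into the preferences used for policy
  evaluation on the same trial — is available via
  `controllability_same_trial`, but it is self-defeating as a default: task
  mastery raises `w_n`, which collapses `c_eff` toward 1, flattens the
  policy posterior, and hands control back to the Pavlovian policy, so a
  competent agent talks itself out of caring and its accuracy drops well
  below the reported healthy range. The learning-rate-only reading also
  matches the interpretation of controllability as inhibiting the
  amygdala-mediated response to aversive outcomes, and it preserves the
  documented property that disabling the cascade leaves the headline
  results intact.
* **The gradient `g_w = 4`.** `w_n` lives on the unit interval, so the
  logistic should act as a threshold without saturating inside it: at
  `g_w = 4` the estimate spans w ≈ 0.12–0.88 over `w_n = w0 ± 0.5`. Much
  steeper gradients pin `w` to ~1 whenever the agent performs well, which
  suppresses the high-stress-sensitivity learning channel responsible for
  the right arm of the stress-sensitivity sweep's inverted-U accuracy
  profile.

The decay-logistic gradient `g = 5` nats⁻¹ is likewise a package default
(steep enough that surprising aversive outcomes under confident beliefs
produce near-minimal `lambda`, shallow enough that the midpoint `m` is
meaningful over its swept range 0.5–2.5); both gradients are configuration
knobs.

## Default configuration and protocols

Defaults are the healthy-agent configuration: `k=0.1, m=1.3, c=8, w0=0.5,
z=0.4, lambda_min=2, lambda_max=50, alpha=3, beta=1, y=0.8`, 200 trials
with a reversal at trial 100. The initial learnable columns hold total
concentration `init_scale = 1` at mean 0.5 — the weakest-information prior
consistent with the uniform initial transition belief; early learning speed
scales with this mass, so it is exposed in the configuration.

Shipped protocols:

* **Sweeps** (`k`, `m`, `c`, `w0`): 400 trials, reversal at 200, 50
  replicates by default, grids k ∈ {0.1…1.3}, m ∈ {0.5…2.5},
  c ∈ {1…20}, w0 ∈ {0.2…0.8}, each with its published fixed companion
  values (e.g. the k sweep fixes m=1.3, c=8, w0=0.6).
* **Trajectories** (`low-decay` m=2, `low-controllability` w0=0.8,
  `high-stress-weight` k=1.1, `high-stress-sensitivity` c=20): single
  sessions tracking the cue that starts as NGE, recording a counterfactual
  policy posterior for that cue re-evaluated from the current beliefs after
  every trial. "Trial-to-trial variance" of such a trace is computed on its
  first differences, which separates spiking from gradual dynamics
  independently of slow drift.

The test suite scales these protocols to 50 replicates × 200 trials for the
single-agent contrasts, 25 replicates × 400 trials per sweep grid point,
and 15 matched seeds for the trajectory-variance comparison; these sizes
give standard errors an order of magnitude below the effects asserted.

## Randomness and reproducibility

A session seed spawns two independent RNG streams (environment: cue order
and feedback; agent: action sampling), so either source of randomness can
be varied alone. Replicate r of base seed s uses `SeedSequence(s,
spawn_key=(r,))`; sweeps share the base seed across grid points, so
replicate r sees identical task randomness at every grid value (matched
seeds). Every CLI invocation writes a manifest echoing the full
configuration and seed, which suffices for bit-identical replay.

## Numerical choices and degenerate inputs

* Logistic arguments are clipped at ±700 before `exp` to avoid overflow.
* Policy scores are shifted by their minimum before exponentiation.
* A concentration parameter driven below 1e-6 (possible only with
  `lambda < 1`, outside the validated range) is clipped there with a
  runtime warning.
* `alpha = 0` yields uniform action choice; `alpha = inf` picks the argmax
  with ties broken uniformly at random.
* An action inconsistent with every surviving policy (zero posterior mass)
  falls back to a delta on the instrumental policy matching the action.
* Zero-length sessions return an empty trace; summarising one is an error.

## What the simulator does and does not show

All inputs are generated internally; there is no empirical data path. The
simulations show that the *mechanisms* — valence-weighted learning,
surprise-gated forgetting, stress-sensitivity scaling and its
controllability modulation — are each sufficient, within this task, to
produce the co-occurrence of weak instrumental beliefs ("hopelessness"),
elevated Pavlovian control and an active-escape bias, and that the
belief-decay route produces gradual whereas the stress routes produce
spiking Pavlovian dynamics. They do not show that human participants
implement these mechanisms, calibrate any parameter against behavioral
data, or model reaction times, within-trial stimulus dynamics, or
cue-order structure beyond i.i.d. sampling.

## Known limitations

* Single-step policies only; no epistemic (information-seeking) value, no
  habit learning over the policy prior, and no learning of the likelihood
  or initial-state prior.
* Fixed policy precision (no within-trial precision dynamics).
* The Pavlovian-facilitated instrumental learning variant (folding
  Pavlovian response posteriors into the instrumental update) is not
  implemented.
* Sweep grids and the two logistic gradients are package choices;
  conclusions are trend-level (rank correlations, orderings), not point
  predictions.
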