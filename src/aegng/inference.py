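"""Per-trial state inference, policy evaluation, model averaging and action selection.

Because the likelihood is one-hot, state inference at the observed time
point is exact (a delta on the observation's preimage) and the full
active-inference policy evaluation reduces to KL control: policies are
scored by the divergence between their predicted outcome distribution at
t=3 and the preference distribution sigma(C) (the softmax of C), with the
already-observed t=2 outcome contributing a policy-independent constant
that cancels in the policy softmax.  Posterior policy probabilities are

    pi  propto  E * exp(-gamma * G(p)),

with G(p) = D_KL[Q(o | p) || sigma(C)] over the outcome observations and
gamma the (fixed) policy precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .agent import AgentState, AVERSIVE_OBSERVATIONS, N_OBSERVATIONS, N_STATES
from .environment import ESCAPE, CUE_CONDITIONS, GO, NOGO

__all__ = [
    "GO_POLICY", "NOGO_POLICY", "PAVLOVIAN_POLICY", "POLICY_NAMES",
    "predicted_final_states", "log_preference_distribution", "policy_divergence",
    "evaluate_policies", "bma_states", "action_marginals", "select_action",
    "condition_on_action", "StatePosteriors", "infer_states",
    "pavlovian_action",
]

GO_POLICY, NOGO_POLICY, PAVLOVIAN_POLICY = 0, 1, 2
POLICY_NAMES = ("Go", "No-Go", "Pavlovian")

# number of preference-neutral observations (o1, o2, o3, o6, o8) used by the
# softmax normaliser of C; the remaining 4 carry -c_eff
_N_NEUTRAL_OBS = N_OBSERVATIONS - len(AVERSIVE_OBSERVATIONS)


def pavlovian_action(condition: str) -> int:
    """The action the Pavlovian policy implies: Go under Escape, No-Go under Avoid."""
    return GO if condition == ESCAPE else NOGO


def predicted_final_states(agent: AgentState, cue: int) -> np.ndarray:
    """Per-policy predicted t=3 state distributions for the observed cue.

    Returns a 3x4 array (policy x final state s9..s12): the normalized
    ``b_go`` / ``b_nogo`` columns for the instrumental policies and the fixed
    Pavlovian ``B0`` column.
    """
    preds = np.zeros((3, 4))
    bg0 = agent.b_go[0, cue]
    bg1 = agent.b_go[1, cue]
    tot = bg0 + bg1
    preds[GO_POLICY, 0] = bg0 / tot
    preds[GO_POLICY, 1] = bg1 / tot
    bn0 = agent.b_nogo[0, cue]
    bn1 = agent.b_nogo[1, cue]
    tot = bn0 + bn1
    preds[NOGO_POLICY, 2] = bn0 / tot
    preds[NOGO_POLICY, 3] = bn1 / tot
    preds[PAVLOVIAN_POLICY] = agent.pavlovian_prediction(cue)
    return preds


def log_preference_distribution(c_eff: float) -> np.ndarray:
    """log sigma(C): the log-softmax of the preference vector over all 9 observations."""
    # C is 0 at the 5 neutral observations and -c_eff at the 4 aversive ones
    log_z = math.log(_N_NEUTRAL_OBS + len(AVERSIVE_OBSERVATIONS) * math.exp(-c_eff))
    lp = np.full(N_OBSERVATIONS, -log_z)
    lp[list(AVERSIVE_OBSERVATIONS)] -= c_eff
    return lp


def policy_divergence(pred_outcomes, c_eff: float) -> float:
    """G(p): KL divergence from a predicted t=3 outcome distribution to sigma(C).

    ``pred_outcomes`` is a length-4 distribution over (o6, o7, o8, o9); the
    preference softmax runs over all 9 observations, so a constant log-
    normaliser enters every policy's G equally and cancels in the policy
    softmax.
    """
    log_z = math.log(_N_NEUTRAL_OBS + len(AVERSIVE_OBSERVATIONS) * math.exp(-c_eff))
    g = 0.0
    for i in range(4):
        q = float(pred_outcomes[i])
        if q > 0.0:
            log_pref = (-c_eff if i in (1, 3) else 0.0) - log_z  # o7, o9 aversive
            g += q * (math.log(q) - log_pref)
    return g


def evaluate_policies(
    preds: np.ndarray,
    c_eff: float,
    E: Optional[np.ndarray] = None,
    gamma: float = 1.0,
) -> np.ndarray:
    """Posterior policy probabilities pi over (Go, No-Go, Pavlovian).

    ``preds`` is the 3x4 per-policy predicted final-state array; predicted
    outcomes equal predicted states under the one-hot likelihood.
    Deterministic given its inputs.
    """
    G = [policy_divergence(preds[p], c_eff) for p in range(3)]
    g_min = min(G)
    if E is None:
        w = [math.exp(-gamma * (g - g_min)) for g in G]
    else:
        w = [float(E[p]) * math.exp(-gamma * (G[p] - g_min)) for p in range(3)]
    total = w[0] + w[1] + w[2]
    return np.array([w[0] / total, w[1] / total, w[2] / total])


def bma_states(pi, s_per_policy) -> np.ndarray:
    """Bayesian model average of per-policy state distributions.

    ``S = sum_p pi[p] * s[p]``; the pi-weighted mixture, normalized by
    convexity whenever the inputs are.
    """
    return np.asarray(pi, dtype=float) @ np.asarray(s_per_policy, dtype=float)


def action_marginals(pi, condition: str) -> tuple[float, float]:
    """Marginal action probabilities implied by a policy posterior.

    The Pavlovian policy's mass goes to Go under Escape cues and to No-Go
    under Avoid cues.
    """
    pav = float(pi[PAVLOVIAN_POLICY])
    p_go = float(pi[GO_POLICY])
    p_nogo = float(pi[NOGO_POLICY])
    if pavlovian_action(condition) == GO:
        p_go += pav
    else:
        p_nogo += pav
    return p_go, p_nogo


def select_action(pi, condition: str, alpha: float, rng: np.random.Generator) -> int:
    """Sample Go/No-Go from the precision-sharpened marginal action probabilities.

    The action is drawn from the softmax of ``alpha * log(marginal)``:
    ``P(Go) = p_go^alpha / (p_go^alpha + p_nogo^alpha)``.  ``alpha = 0``
    gives a uniform action; ``alpha = inf`` picks the argmax with ties
    broken uniformly at random.
    """
    p_go, p_nogo = action_marginals(pi, condition)
    if math.isinf(alpha):
        if p_go > p_nogo:
            return GO
        if p_nogo > p_go:
            return NOGO
        return GO if rng.random() < 0.5 else NOGO
    if alpha == 0.0 or (p_go == 0.0 and p_nogo == 0.0):
        p = 0.5
    else:
        a = p_go ** alpha
        b = p_nogo ** alpha
        p = a / (a + b)
    return GO if rng.random() < p else NOGO


def condition_on_action(pi, action: int, condition: str) -> np.ndarray:
    """Zero out policies inconsistent with the taken action and renormalize.

    The instrumental policy matching the action always survives; the
    Pavlovian policy survives iff its implied action (by the cue's
    condition) equals the taken action.  If the surviving mass is zero, the
    posterior falls back to a delta on the instrumental policy matching the
    action.
    """
    out = np.zeros(3)
    inst = GO_POLICY if action == GO else NOGO_POLICY
    out[inst] = float(pi[inst])
    if pavlovian_action(condition) == action:
        out[PAVLOVIAN_POLICY] = float(pi[PAVLOVIAN_POLICY])
    total = out.sum()
    if total <= 0.0:
        out[:] = 0.0
        out[inst] = 1.0
        return out
    return out / total


@dataclass
class StatePosteriors:
    """Exact state posteriors at an observed time point.

    ``current`` is the delta over the 12 states on the observation's
    preimage (exact because the likelihood is one-hot).  At t=2,
    ``per_policy_final`` additionally carries each policy's predicted t=3
    state distribution (3x4 over s9..s12).
    """

    t: int
    current: np.ndarray
    per_policy_final: Optional[np.ndarray] = None


def infer_states(agent: AgentState, observation: int, t: int) -> StatePosteriors:
    """Posterior state beliefs after an observation at time point ``t``.

    The one-hot likelihood makes the posterior at the observed time point a
    delta on the observation's preimage; at t=2 the per-policy t=3
    predictions are the normalized transition-belief columns for the
    observed cue (instrumental) or the Pavlovian column.
    """
    column = agent.A[observation]
    if column.sum() == 0.0:
        raise ValueError(f"observation o{observation + 1} has no generating state")
    current = column / column.sum()
    expected_t = 0 if observation == 0 else (1 if observation <= 4 else 2)
    if t - 1 != expected_t:
        raise ValueError(f"observation o{observation + 1} is inconsistent with t={t}")
    per_policy = None
    if t == 2:
        cue = observation - 1  # o2..o5 -> cue 0..3
        per_policy = predicted_final_states(agent, cue)
    return StatePosteriors(t=t, current=current, per_policy_final=per_policy)
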