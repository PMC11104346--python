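"""End-of-trial belief updating.

Three quantities govern each update of the Dirichlet transition
concentrations:

* the state-action prediction error (SAPE), the KL divergence between the
  policy-averaged final-state beliefs after and before observing the
  outcome;
* the decay parameter ``lambda``, a decreasing logistic function of SAPE
  (large surprises accelerate forgetting of stale beliefs):
  ``lambda = lambda_min + (lambda_max - lambda_min) / (1 + exp(g*(SAPE - m)))``;
* the valence-dependent learning rate ``eta = 1 + k*|C(o)|``, which boosts
  learning after aversive outcomes in proportion to the stress weight ``k``
  and the effective stress sensitivity.

The update itself is

    b_i(u) = b_{i-1}(u) + eta * pi(u) * (s_3 (x) s_2)  -  (b_{i-1}(u) - 1) / lambda

per control state u in {Go, No-Go}, with the policy sum restricted to the
two instrumental policies, the increment masked to the structural support,
and increment and decay both computed from the pre-update concentrations.
Decay relaxes every supported entry of both matrices toward 1 on every
trial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .inference import GO_POLICY, NOGO_POLICY

__all__ = [
    "LearningParams", "compute_sape", "decay_lambda", "learning_eta",
    "update_beliefs", "CONCENTRATION_FLOOR", "SAPE_EPS",
]

SAPE_EPS = 1e-16           # floor for the pre-outcome BMA before the log
CONCENTRATION_FLOOR = 1e-6  # clip for (pathological) negative concentrations


@dataclass(frozen=True)
class LearningParams:
    """Learning-rate and belief-decay parameters.

    ``k`` scales the aversive learning-rate boost; ``g`` (nats^-1) and ``m``
    (nats) are the gradient and midpoint of the SAPE -> lambda logistic;
    ``lambda_min``/``lambda_max`` bound the decay parameter (small lambda =
    fast forgetting).
    """

    k: float = 0.1
    g: float = 5.0
    m: float = 1.3
    lambda_min: float = 2.0
    lambda_max: float = 50.0

    def __post_init__(self) -> None:
        if self.k < 0.0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.lambda_min <= 0.0 or self.lambda_max < self.lambda_min:
            raise ValueError("need 0 < lambda_min <= lambda_max")


def compute_sape(s_post, s_pre, eps: float = SAPE_EPS) -> float:
    """D_KL[s_post || s_pre] in nats between successive BMA final-state beliefs.

    ``s_pre`` entries are floored at ``eps`` wherever ``s_post`` has mass, so
    structural zeros in the pre-outcome mixture cannot produce infinities.
    Nonnegative; zero iff the distributions coincide.
    """
    total = 0.0
    for p, q in zip(np.asarray(s_post, dtype=float), np.asarray(s_pre, dtype=float)):
        if p > 0.0:
            total += p * (math.log(p) - math.log(max(q, eps)))
    return max(total, 0.0)


def decay_lambda(sape: float, params: LearningParams) -> float:
    """Decay parameter lambda as a decreasing logistic function of SAPE."""
    arg = params.g * (sape - params.m)
    arg = min(max(arg, -700.0), 700.0)  # avoid overflow in exp
    return params.lambda_min + (params.lambda_max - params.lambda_min) / (1.0 + math.exp(arg))


def learning_eta(c_value_at_outcome: float, k: float) -> float:
    """Valence-dependent learning rate: eta = 1 + k * |C(o)|.

    ``c_value_at_outcome`` is the preference entry of the observed t=3
    outcome: 0 for neutral outcomes, -c_eff for aversive ones.  eta >= 1,
    with equality iff k = 0 or the outcome is neutral.
    """
    return 1.0 + k * abs(c_value_at_outcome)


def update_beliefs(
    b_go: np.ndarray,
    b_nogo: np.ndarray,
    pi_post: np.ndarray,
    cue: int,
    final_state: int,
    eta: float,
    lam: float,
    floor: float = CONCENTRATION_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the Dirichlet update with decay in place; returns the arrays.

    ``pi_post`` is the post-action policy posterior; the observed cue and
    final state are deltas, so the instrumental increment touches exactly
    one supported cell of the acting control state's matrix:
    ``eta * pi_post[u]`` at (final state, cue).  Every supported entry of
    both matrices then relaxes toward 1 by ``(b - 1) / lambda``, computed
    from the pre-update concentrations simultaneously with the increment.
    Structural zeros are not represented and therefore never touched.
    """
    new_go = b_go - (b_go - 1.0) / lam
    new_nogo = b_nogo - (b_nogo - 1.0) / lam
    if final_state < 2:  # s9/s10: reachable only under Go
        new_go[final_state, cue] += eta * float(pi_post[GO_POLICY])
    else:                # s11/s12: reachable only under No-Go
        new_nogo[final_state - 2, cue] += eta * float(pi_post[NOGO_POLICY])
    if (new_go < floor).any() or (new_nogo < floor).any():
        warnings.warn(
            "concentration parameter fell below the positive floor; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        np.maximum(new_go, floor, out=new_go)
        np.maximum(new_nogo, floor, out=new_nogo)
    b_go[:] = new_go
    b_nogo[:] = new_nogo
    return b_go, b_nogo
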