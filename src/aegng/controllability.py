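"""Stressor-controllability cascade.

Perceived controllability attenuates stress sensitivity in three monotone
steps evaluated during the decision phase (t=2), before the action:

1. the pre-action BMA over final states is mapped through the likelihood to
   expected outcomes, and the mass on the two neutral outcomes (o6, o8) is
   the raw controllability estimate ``w_n = P(o6) + P(o8)``;
2. ``w_n`` passes through a logistic with threshold ``w0`` and gradient
   ``g_w``: ``w = 1 / (1 + exp(-g_w * (w_n - w0)))``;
3. the effective stress sensitivity is ``c_eff = c^(1 - w)``, so full
   perceived control (w=1) collapses the preference magnitude to 1 and no
   control (w=0) leaves it at the baseline ``c``.

Because each step is monotone, strengthening beliefs that neutral outcomes
are reachable can never increase ``c_eff``.  The cascade can be disabled,
in which case ``c_eff`` stays at ``c`` and every other module behaves
identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .agent import likelihood_matrix

__all__ = [
    "ControllabilityParams", "expected_outcomes", "raw_controllability",
    "logistic_controllability", "modulate_stress",
]

# t=3 block of the one-hot likelihood: observations o6..o9 x states s9..s12
_A_FINAL = likelihood_matrix()[5:9, 8:12]


@dataclass(frozen=True)
class ControllabilityParams:
    """Controllability threshold (logistic midpoint) and gradient."""

    w0: float = 0.5
    g_w: float = 4.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.w0 <= 1.0:
            raise ValueError(f"w0 must lie in [0, 1], got {self.w0}")
        if self.g_w <= 0.0:
            raise ValueError(f"g_w must be > 0, got {self.g_w}")


def expected_outcomes(S_final) -> np.ndarray:
    """Expected t=3 outcome distribution over (o6..o9): A applied to the BMA states."""
    return _A_FINAL @ np.asarray(S_final, dtype=float)


def raw_controllability(o_pred) -> float:
    """w_n: predicted probability of a neutral outcome, P(o6) + P(o8)."""
    return float(o_pred[0]) + float(o_pred[2])


def logistic_controllability(w_n: float, params: ControllabilityParams) -> float:
    """Logistic-transformed controllability estimate w in (0, 1)."""
    arg = -params.g_w * (w_n - params.w0)
    arg = min(max(arg, -700.0), 700.0)
    return 1.0 / (1.0 + math.exp(arg))


def modulate_stress(c: float, w: float) -> float:
    """Effective stress sensitivity c_eff = c^(1 - w).

    ``w = 0`` leaves the baseline untouched (c_eff = c); ``w = 1`` removes
    the stress response entirely (c_eff = 1).
    """
    if c < 1.0:
        raise ValueError(f"baseline stress sensitivity must be >= 1, got {c}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"controllability w must lie in [0, 1], got {w}")
    return c ** (1.0 - w)
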