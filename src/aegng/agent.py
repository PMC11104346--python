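"""The agent's generative model of the task.

The model mirrors the 12-state / 9-observation layout of the environment:

* ``A`` -- deterministic (one-hot) likelihood, identical to the generative
  process and never learned;
* ``b_go``, ``b_nogo`` -- Dirichlet concentration parameters over the
  learnable t=2 -> t=3 transitions of the two instrumental policies.  Each
  is stored as a dense 2x4 array of the structurally allowed entries:
  rows (neutral, aversive) by cue.  Go policies reach only s9/s10, No-Go
  only s11/s12; all other transition entries are structural zeros and are
  never represented, so they cannot be perturbed by learning;
* ``B0`` -- the Pavlovian policy's fixed transition beliefs: No-Go states
  for Avoid cues and Go states for Escape cues, reaching the neutral member
  with probability ``z``;
* ``C`` -- prior preferences over observations, ``-c_eff`` at the aversive
  observations o4, o5, o7, o9 and 0 elsewhere;
* ``D``, ``E`` -- uniform priors over the initial states s1-s4 and over the
  three policies (instrumental Go, instrumental No-Go, Pavlovian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .environment import AVOID, CUE_CONDITIONS, N_CUES

__all__ = [
    "N_STATES", "N_OBSERVATIONS", "AVERSIVE_OBSERVATIONS",
    "likelihood_matrix", "preference_vector", "pavlovian_final_states",
    "normalize_beliefs", "AgentState", "init_agent",
]

N_STATES = 12
N_OBSERVATIONS = 9
# o4, o5 (aversive cue observations) and o7, o9 (aversive outcomes), 0-based
AVERSIVE_OBSERVATIONS = (3, 4, 6, 8)


def likelihood_matrix() -> np.ndarray:
    """The one-hot likelihood A (observations x states).

    s1-s4 -> o1; s5-s8 -> o2-o5; s9-s12 -> o6-o9.  Columns are one-hot.
    """
    A = np.zeros((N_OBSERVATIONS, N_STATES))
    A[0, 0:4] = 1.0
    for i in range(4):
        A[1 + i, 4 + i] = 1.0
        A[5 + i, 8 + i] = 1.0
    return A


def preference_vector(c_eff: float) -> np.ndarray:
    """Prior preferences C over the 9 observations for a given c_eff."""
    C = np.zeros(N_OBSERVATIONS)
    C[list(AVERSIVE_OBSERVATIONS)] = -float(c_eff)
    return C


def pavlovian_final_states(z: float, condition: str) -> np.ndarray:
    """The Pavlovian policy's predicted t=3 state distribution for a cue.

    Avoid cues allow only No-Go states (s11 with probability ``z``, s12 with
    ``1 - z``); Escape cues allow only Go states (s9 with ``z``, s10 with
    ``1 - z``).  Returned over (s9, s10, s11, s12).
    """
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"z must be a probability, got {z}")
    if condition == AVOID:
        return np.array([0.0, 0.0, z, 1.0 - z])
    return np.array([z, 1.0 - z, 0.0, 0.0])


def normalize_beliefs(b: np.ndarray) -> np.ndarray:
    """Column-wise Dirichlet means of a concentration array (rows sum per cue)."""
    b = np.asarray(b, dtype=float)
    totals = b.sum(axis=0)
    if np.any(totals <= 0.0):
        raise FloatingPointError("zero-mass concentration column cannot be normalized")
    return b / totals


@dataclass
class AgentState:
    """Mutable agent state: learnable concentrations plus fixed structures.

    Only ``b_go``, ``b_nogo`` and ``c_eff`` change across trials.
    """

    b_go: np.ndarray        # 2x4: rows (s9 neutral, s10 aversive) x cue
    b_nogo: np.ndarray      # 2x4: rows (s11 neutral, s12 aversive) x cue
    z: float
    c: float
    c_eff: float
    alpha: float
    beta: float
    gamma: float
    init_scale: float
    A: np.ndarray = field(default_factory=likelihood_matrix)
    D: np.ndarray = field(default_factory=lambda: np.r_[np.full(4, 0.25), np.zeros(8)])
    E: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))

    def pavlovian_prediction(self, cue: int) -> np.ndarray:
        return pavlovian_final_states(self.z, CUE_CONDITIONS[cue])

    def neutral_beliefs(self) -> np.ndarray:
        """Normalized P(neutral | cue, action), shape (2, 4): rows (Go, No-Go)."""
        return np.vstack([
            normalize_beliefs(self.b_go)[0],
            normalize_beliefs(self.b_nogo)[0],
        ])

    def preference(self) -> np.ndarray:
        return preference_vector(self.c_eff)


def init_agent(config: Config) -> AgentState:
    """Build the initial agent state from a validated configuration.

    Learnable columns start at a uniform Dirichlet mean (0.5, 0.5) with total
    concentration ``init_scale`` per column, the weakest-information prior
    consistent with the uniform initial transition belief.
    """
    half = 0.5 * config.init_scale
    b_go = np.full((2, N_CUES), half)
    b_nogo = np.full((2, N_CUES), half)
    return AgentState(
        b_go=b_go,
        b_nogo=b_nogo,
        z=config.z,
        c=config.c,
        c_eff=config.c,
        alpha=config.alpha,
        beta=config.beta,
        gamma=config.policy_precision,
        init_scale=config.init_scale,
    )
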