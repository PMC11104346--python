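"""Objective generative process of the Avoid/Escape Go/No-Go task.

The task crosses the required response (Go / No-Go) with the threat
condition (Avoid / Escape) to give four cues.  On every trial one cue is
presented uniformly at random; the agent emits Go or No-Go and receives a
neutral or aversive outcome.  The response that maximises the frequency of
the neutral outcome under the current contingency ("correct") yields the
neutral outcome with probability ``y``; the other response yields it with
probability ``1 - y``.  At the reversal trial the correct response for every
cue flips (Go becomes No-Go and vice versa) while each cue's Avoid/Escape
condition never changes.

The hidden-state / observation layout is fixed and shared with the agent's
generative model:

* s1-s4: pre-cue states (one per cue), all emitting the uninformative o1;
* s5-s8: cue states, emitting cue observations o2-o5;
* s9-s12: response+outcome states, emitting o6-o9, with
  s9 = Go + neutral, s10 = Go + aversive, s11 = No-Go + neutral,
  s12 = No-Go + aversive.

Internally cues are indexed 0..3 and final states 0..3 (s9..s12); the
1-based task names are used in all external outputs.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

__all__ = [
    "GO", "NOGO", "AVOID", "ESCAPE", "ACTION_NAMES",
    "N_CUES", "CUE_CONDITIONS",
    "S_GO_NEUTRAL", "S_GO_AVERSIVE", "S_NOGO_NEUTRAL", "S_NOGO_AVERSIVE",
    "NEUTRAL_FINAL_STATES", "Environment",
    "cue_state_name", "final_state_name", "observation_name", "cue_label",
]

GO, NOGO = 0, 1
ACTION_NAMES = ("Go", "No-Go")

AVOID, ESCAPE = "Avoid", "Escape"
N_CUES = 4
# cues 0,1 are Avoid-condition; cues 2,3 are Escape-condition (fixed forever)
CUE_CONDITIONS = (AVOID, AVOID, ESCAPE, ESCAPE)
# pre-reversal correct responses: one Go and one No-Go cue per condition
_INITIAL_CORRECT = (GO, NOGO, GO, NOGO)

# final (t=3) states, indexed 0..3 == s9..s12
S_GO_NEUTRAL, S_GO_AVERSIVE, S_NOGO_NEUTRAL, S_NOGO_AVERSIVE = range(4)
NEUTRAL_FINAL_STATES = (S_GO_NEUTRAL, S_NOGO_NEUTRAL)


def cue_state_name(cue: int) -> str:
    """Task name of the t=2 state for cue index 0..3 (s5..s8)."""
    return f"s{5 + cue}"


def final_state_name(final: int) -> str:
    """Task name of the t=3 state for final-state index 0..3 (s9..s12)."""
    return f"s{9 + final}"


def observation_name(obs: int) -> str:
    """Task name of observation index 0..8 (o1..o9)."""
    return f"o{1 + obs}"


def cue_label(cue: int, correct_action: int) -> str:
    """Contingency-relative cue label: GA, NGA, GE or NGE.

    Labels name the cue by its *current* correct response, so the same
    physical cue is relabelled after a reversal (GE <-> NGE, GA <-> NGA).
    """
    prefix = "G" if correct_action == GO else "NG"
    suffix = "A" if CUE_CONDITIONS[cue] == AVOID else "E"
    return prefix + suffix


class Environment:
    """The task's objective dynamics, with its own RNG stream.

    Parameters
    ----------
    y
        Probability that a correct response leads to the neutral outcome.
    n_trials
        Session length.
    reversal_trial
        First trial index (0-based) at which the flipped contingency holds;
        equal to ``n_trials`` for a session without reversal.
    seed
        Seed for the environment's RNG stream (ignored if ``rng`` is given).
    rng
        An explicit ``numpy.random.Generator``, e.g. spawned from a session
        seed so that environment and agent randomness vary independently.
    """

    def __init__(
        self,
        y: float = 0.8,
        n_trials: int = 200,
        reversal_trial: int = 100,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        if not 0.0 <= y <= 1.0:
            raise ValueError(f"y must be a probability, got {y}")
        if n_trials < 0:
            raise ValueError(f"n_trials must be >= 0, got {n_trials}")
        if not 0 <= reversal_trial <= n_trials:
            raise ValueError(
                f"reversal_trial must lie in [0, n_trials={n_trials}], got {reversal_trial}"
            )
        self.y = float(y)
        self.n_trials = int(n_trials)
        self.reversal_trial = int(reversal_trial)
        self._rng = rng if rng is not None else np.random.default_rng(seed)

    def condition(self, cue: int) -> str:
        """Avoid/Escape condition of a cue (never changes)."""
        return CUE_CONDITIONS[cue]

    def correct_action(self, cue: int, trial: int) -> int:
        """The neutral-frequency-maximising response under the current contingency."""
        base = _INITIAL_CORRECT[cue]
        if trial >= self.reversal_trial:
            return 1 - base
        return base

    def present_cue(self, trial: int) -> int:
        """Sample the trial's cue, i.i.d. uniform over the four cues."""
        if not 0 <= trial < self.n_trials:
            raise ValueError(f"trial {trial} outside session of {self.n_trials} trials")
        return int(self._rng.integers(N_CUES))

    def emit_outcome(self, cue: int, action: int, trial: int) -> Tuple[int, int, bool, bool]:
        """Draw the trial's final state and observation.

        Returns ``(final_state, observation, neutral, correct)`` where
        ``final_state`` indexes s9..s12 as 0..3, ``observation`` indexes
        o1..o9 as 0..8 (always one of 5..8 here), ``neutral`` flags the
        neutral outcome and ``correct`` whether the action matched the
        current correct response.
        """
        if action not in (GO, NOGO):
            raise ValueError(f"invalid action {action}")
        correct = action == self.correct_action(cue, trial)
        p_neutral = self.y if correct else 1.0 - self.y
        neutral = bool(self._rng.random() < p_neutral)
        if action == GO:
            final = S_GO_NEUTRAL if neutral else S_GO_AVERSIVE
        else:
            final = S_NOGO_NEUTRAL if neutral else S_NOGO_AVERSIVE
        observation = 5 + final  # o6..o9, the deterministic image of s9..s12
        return final, observation, neutral, correct
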