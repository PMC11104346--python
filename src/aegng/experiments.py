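"""Session orchestration, replicates, parameter sweeps and summary statistics.

A trial runs the full loop: cue presentation -> exact state inference ->
controllability update -> policy evaluation -> action selection -> outcome
-> post-action SAPE -> decay and learning-rate computation -> Dirichlet
update.  Sessions log one record per trial; replicate sets and sweeps
aggregate the per-session summaries (mean and standard error).

Shipped presets reproduce the four one-parameter sweeps (stress weight k,
decay threshold m, stress sensitivity c, controllability threshold w0) and
the four trajectory configurations used to contrast gradual versus spiking
Pavlovian dynamics, each with its published fixed parameter values and the
400-trial / reversal-at-200 / 50-replicate protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agent import AgentState, init_agent
from .config import Config
from .controllability import (
    ControllabilityParams,
    expected_outcomes,
    logistic_controllability,
    modulate_stress,
    raw_controllability,
)
from .environment import (
    ACTION_NAMES,
    CUE_CONDITIONS,
    Environment,
    GO,
    N_CUES,
    cue_label,
    cue_state_name,
    final_state_name,
    observation_name,
)
from .inference import (
    GO_POLICY,
    NOGO_POLICY,
    PAVLOVIAN_POLICY,
    action_marginals,
    bma_states,
    condition_on_action,
    evaluate_policies,
    predicted_final_states,
    select_action,
)
from .learning import LearningParams, compute_sape, decay_lambda, learning_eta, update_beliefs

__all__ = [
    "Session", "run_trial", "run_session", "summarize", "SummaryStats",
    "run_replicates", "ReplicatesResult", "run_sweep",
    "SweepPreset", "SWEEP_PRESETS", "TRAJECTORY_PRESETS", "replicate_seed",
]

_NORM_TOL = 1e-9

SUMMARY_FIELDS = (
    "overall_accuracy",
    "active_escape_bias",
    "mean_pavlovian_prob",
    "mean_neutral_belief",
    "acc_GA", "acc_NGA", "acc_GE", "acc_NGE",
    "acc_pre_GA", "acc_pre_NGA", "acc_pre_GE", "acc_pre_NGE",
    "acc_post_GA", "acc_post_NGA", "acc_post_GE", "acc_post_NGE",
)


def replicate_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic, splittable per-replicate seed derived from the base seed."""
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(index),))


class Session:
    """One agent playing one task session.

    Environment and agent draw from independent RNG streams spawned from the
    session seed, so either source of randomness can be varied on its own.
    """

    def __init__(self, config: Config, seed: Optional[int | np.random.SeedSequence] = None):
        self.config = config
        if seed is None:
            seed = config.base_seed
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
        env_ss, agent_ss = ss.spawn(2)
        self.env = Environment(
            y=config.y,
            n_trials=config.n_trials,
            reversal_trial=config.reversal_trial,
            rng=np.random.default_rng(env_ss),
        )
        self.rng = np.random.default_rng(agent_ss)
        self.agent = init_agent(config)
        self._learning = LearningParams(
            k=config.k, g=config.g, m=config.m,
            lambda_min=config.lambda_min, lambda_max=config.lambda_max,
        )
        self._control = ControllabilityParams(
            w0=config.w0, g_w=config.g_w, enabled=config.controllability_enabled,
        )
        self._c_eff_prev = config.c  # trial 1 evaluates policies with the baseline c

    def run(self, track_cue: Optional[int] = None, validate: bool = True) -> pd.DataFrame:
        """Run all trials and return the per-trial trace as a DataFrame."""
        rows = [
            self.run_trial(trial, track_cue=track_cue, validate=validate)
            for trial in range(self.config.n_trials)
        ]
        return pd.DataFrame(rows)

    def run_trial(
        self, trial: int, track_cue: Optional[int] = None, validate: bool = True
    ) -> dict:
        """Execute one full trial; mutates the agent and returns its record."""
        cfg = self.config
        agent = self.agent
        env = self.env

        cue = env.present_cue(trial)
        condition = CUE_CONDITIONS[cue]
        preds = predicted_final_states(agent, cue)

        # Policy evaluation and the controllability cascade on the pre-action
        # BMA.  By default c_eff modulates only the outcome-valence learning
        # rate (the stress *response*), so policies are evaluated with the
        # baseline preference magnitude c.  With controllability_same_trial
        # the modulated c_eff also feeds back into the preferences: policies
        # are first evaluated with the previous trial's c_eff (trial 1 uses
        # c) and re-evaluated once with the new value before acting.
        eval_c = self._c_eff_prev if cfg.controllability_same_trial else agent.c
        pi_pre = evaluate_policies(preds, eval_c, agent.E, agent.gamma)
        if self._control.enabled:
            S_decision = bma_states(pi_pre, preds)
            w_n = raw_controllability(expected_outcomes(S_decision))
            w = logistic_controllability(w_n, self._control)
            c_eff = modulate_stress(agent.c, w)
            if cfg.controllability_same_trial:
                pi = evaluate_policies(preds, c_eff, agent.E, agent.gamma)
            else:
                pi = pi_pre
        else:
            w_n = math.nan
            w = math.nan
            c_eff = agent.c
            pi = pi_pre

        action = select_action(pi, condition, agent.alpha, self.rng)
        final_state, observation, neutral, correct = env.emit_outcome(cue, action, trial)

        # SAPE: KL between the post-outcome delta and the pre-outcome BMA,
        # with the policy posterior conditioned on the taken action
        pi_post = condition_on_action(pi, action, condition)
        pi_sape = pi_post if cfg.sape_post_action else pi
        s_pre = bma_states(pi_sape, preds)
        s_post = np.zeros(4)
        s_post[final_state] = 1.0
        sape = compute_sape(s_post, s_pre)

        lam = decay_lambda(sape, self._learning)
        c_value = 0.0 if neutral else -c_eff
        eta = learning_eta(c_value, self._learning.k)
        update_beliefs(agent.b_go, agent.b_nogo, pi_post, cue, final_state, eta, lam)

        agent.c_eff = c_eff
        self._c_eff_prev = c_eff

        if validate:
            self._check_invariants(trial, pi, pi_post, s_pre, sape, lam, eta)

        nb = agent.neutral_beliefs()  # post-update snapshot, 2x4 (Go, No-Go) x cue
        p_go, _ = action_marginals(pi, condition)
        record = {
            "trial": trial,
            "cue": cue + 1,
            "cue_state": cue_state_name(cue),
            "cue_label": cue_label(cue, env.correct_action(cue, trial)),
            "condition": condition,
            "action": ACTION_NAMES[action],
            "correct": correct,
            "outcome": "neutral" if neutral else "aversive",
            "final_state": final_state_name(final_state),
            "observation": observation_name(observation),
            "p_go": p_go,
            "pi_go": float(pi[GO_POLICY]),
            "pi_nogo": float(pi[NOGO_POLICY]),
            "pi_pav": float(pi[PAVLOVIAN_POLICY]),
            "sape": sape,
            "lambda": lam,
            "eta": eta,
            "w_n": w_n,
            "w": w,
            "c_eff": c_eff,
            "mean_neutral_belief": float(nb.mean()),
        }
        for j in range(N_CUES):
            record[f"belief_neutral_go_cue{j + 1}"] = float(nb[0, j])
            record[f"belief_neutral_nogo_cue{j + 1}"] = float(nb[1, j])
        if track_cue is not None:
            # counterfactual policy posterior for a fixed cue, re-evaluated
            # from the current beliefs after every trial (smooth trajectory
            # regardless of which cue was actually shown)
            tpreds = predicted_final_states(agent, track_cue)
            tpi = evaluate_policies(tpreds, c_eff, agent.E, agent.gamma)
            record["track_pi_pav"] = float(tpi[PAVLOVIAN_POLICY])
            record["track_belief_go"] = float(nb[0, track_cue])
            record["track_belief_nogo"] = float(nb[1, track_cue])
        return record

    def _check_invariants(self, trial, pi, pi_post, s_pre, sape, lam, eta) -> None:
        cfg = self.config
        if abs(float(pi.sum()) - 1.0) > _NORM_TOL or float(pi.min()) < 0.0:
            raise RuntimeError(f"trial {trial}: policy posterior not normalized: {pi}")
        if abs(float(pi_post.sum()) - 1.0) > _NORM_TOL:
            raise RuntimeError(f"trial {trial}: post-action posterior not normalized: {pi_post}")
        if abs(float(s_pre.sum()) - 1.0) > _NORM_TOL:
            raise RuntimeError(f"trial {trial}: BMA not normalized: {s_pre}")
        if sape < 0.0:
            raise RuntimeError(f"trial {trial}: negative SAPE {sape}")
        if not cfg.lambda_min <= lam <= cfg.lambda_max:
            raise RuntimeError(f"trial {trial}: lambda {lam} outside bounds")
        if eta < 1.0:
            raise RuntimeError(f"trial {trial}: learning rate {eta} below 1")
        if float(self.agent.b_go.min()) <= 0.0 or float(self.agent.b_nogo.min()) <= 0.0:
            raise RuntimeError(f"trial {trial}: nonpositive concentration parameter")


def run_trial(agent: AgentState, env: Environment, trial: int, rng: np.random.Generator,
              config: Config) -> tuple[AgentState, dict]:
    """Functional single-trial wrapper around :meth:`Session.run_trial`."""
    session = Session.__new__(Session)
    session.config = config
    session.env = env
    session.rng = rng
    session.agent = agent
    session._learning = LearningParams(
        k=config.k, g=config.g, m=config.m,
        lambda_min=config.lambda_min, lambda_max=config.lambda_max,
    )
    session._control = ControllabilityParams(
        w0=config.w0, g_w=config.g_w, enabled=config.controllability_enabled,
    )
    session._c_eff_prev = agent.c_eff
    record = session.run_trial(trial)
    return agent, record


def run_session(
    config: Config,
    seed: Optional[int | np.random.SeedSequence] = None,
    track_cue: Optional[int] = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Run one session and return the per-trial trace; deterministic given the seed."""
    return Session(config, seed=seed).run(track_cue=track_cue, validate=validate)


@dataclass
class SummaryStats:
    """Per-session behavioral summary.

    Accuracies are contingency-relative: each trial counts toward the label
    (GA/NGA/GE/NGE) its cue carries under the contingency current at that
    trial, and the pre/post split is at the reversal.  The active-escape
    bias is accuracy(GE) - accuracy(NGE) over the whole session.
    """

    accuracy_pre: dict = field(default_factory=dict)
    accuracy_post: dict = field(default_factory=dict)
    accuracy_overall: dict = field(default_factory=dict)
    overall_accuracy: float = math.nan
    active_escape_bias: float = math.nan
    mean_pavlovian_prob: float = math.nan
    mean_neutral_belief: float = math.nan

    def to_row(self) -> dict:
        row = {
            "overall_accuracy": self.overall_accuracy,
            "active_escape_bias": self.active_escape_bias,
            "mean_pavlovian_prob": self.mean_pavlovian_prob,
            "mean_neutral_belief": self.mean_neutral_belief,
        }
        for label in ("GA", "NGA", "GE", "NGE"):
            row[f"acc_{label}"] = self.accuracy_overall.get(label, math.nan)
            row[f"acc_pre_{label}"] = self.accuracy_pre.get(label, math.nan)
            row[f"acc_post_{label}"] = self.accuracy_post.get(label, math.nan)
        return row


def _accuracy_by_label(records: pd.DataFrame) -> dict:
    if len(records) == 0:
        return {}
    return records.groupby("cue_label", observed=True)["correct"].mean().to_dict()


def summarize(records: pd.DataFrame, reversal_trial: Optional[int] = None) -> SummaryStats:
    """Compute the behavioral summary of one session trace."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record set")
    if reversal_trial is None:
        reversal_trial = int(records["trial"].max()) + 1
    pre = records[records["trial"] < reversal_trial]
    post = records[records["trial"] >= reversal_trial]
    overall = _accuracy_by_label(records)
    bias = overall.get("GE", math.nan) - overall.get("NGE", math.nan)
    return SummaryStats(
        accuracy_pre=_accuracy_by_label(pre),
        accuracy_post=_accuracy_by_label(post),
        accuracy_overall=overall,
        overall_accuracy=float(records["correct"].mean()),
        active_escape_bias=float(bias),
        mean_pavlovian_prob=float(records["pi_pav"].mean()),
        mean_neutral_belief=float(records["mean_neutral_belief"].mean()),
    )


@dataclass
class ReplicatesResult:
    """Per-replicate summaries plus their aggregate (mean and standard error)."""

    summaries: pd.DataFrame   # one row per replicate, with 'replicate' and 'seed' columns
    aggregate: pd.DataFrame   # index: summary field; columns: mean, sem

    @property
    def n_replicates(self) -> int:
        return len(self.summaries)


def _aggregate(summaries: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in SUMMARY_FIELDS if c in summaries.columns]
    mean = summaries[cols].mean()
    n = len(summaries)
    sem = summaries[cols].std(ddof=1) / math.sqrt(n) if n > 1 else mean * math.nan
    return pd.DataFrame({"mean": mean, "sem": sem})


def run_replicates(
    config: Config,
    n_replicates: Optional[int] = None,
    track_cue: Optional[int] = None,
    validate: bool = False,
) -> ReplicatesResult:
    """Run independent replicate sessions with seeds derived from the base seed."""
    n = config.n_replicates if n_replicates is None else int(n_replicates)
    if n < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for rep in range(n):
        ss = replicate_seed(config.base_seed, rep)
        records = run_session(config, seed=ss, track_cue=track_cue, validate=validate)
        row = summarize(records, config.reversal_trial).to_row()
        row["replicate"] = rep
        row["seed"] = f"{config.base_seed}:{rep}"
        rows.append(row)
    summaries = pd.DataFrame(rows)
    return ReplicatesResult(summaries=summaries, aggregate=_aggregate(summaries))


@dataclass(frozen=True)
class SweepPreset:
    """A one-parameter sweep: the grid plus the fixed companion values."""

    param: str
    grid: tuple
    fixed: Mapping[str, float]


# The four shipped one-parameter sweeps with their published fixed values;
# sweep sessions use the 400-trial protocol with a reversal at trial 200.
_SWEEP_PROTOCOL = {"n_trials": 400, "reversal_trial": 200}
SWEEP_PRESETS = {
    "k": SweepPreset("k", (0.1, 0.4, 0.7, 1.0, 1.3), {"m": 1.3, "c": 8.0, "w0": 0.6}),
    "m": SweepPreset("m", (0.5, 1.0, 1.5, 2.0, 2.5), {"k": 0.7, "c": 8.0, "w0": 0.6}),
    "c": SweepPreset("c", (1.0, 2.0, 4.0, 8.0, 20.0), {"k": 0.6, "m": 1.0, "w0": 0.5}),
    "w0": SweepPreset("w0", (0.2, 0.35, 0.5, 0.65, 0.8), {"k": 0.9, "m": 1.3, "c": 8.0}),
}

# Trajectory presets for subtype inspection (each perturbs one parameter on
# top of the corresponding sweep's fixed values); sessions track the cue
# that starts as NGE (cue 4) and becomes GE after the reversal.
TRAJECTORY_TRACK_CUE = 3
TRAJECTORY_PRESETS = {
    "low-decay": {"m": 2.0, "k": 0.7, "c": 8.0, "w0": 0.6},
    "low-controllability": {"w0": 0.8, "k": 0.9, "m": 1.3, "c": 8.0},
    "high-stress-weight": {"k": 1.1, "m": 1.3, "c": 8.0, "w0": 0.6},
    "high-stress-sensitivity": {"c": 20.0, "k": 0.6, "m": 1.0, "w0": 0.5},
}


def sweep_config(base: Config, preset: SweepPreset, value: float) -> Config:
    """Config for one grid point of a sweep preset."""
    fields = dict(_SWEEP_PROTOCOL)
    fields.update(preset.fixed)
    fields[preset.param] = value
    return base.replace(**fields)


def trajectory_config(base: Config, preset_name: str) -> Config:
    """Config for one trajectory preset."""
    if preset_name not in TRAJECTORY_PRESETS:
        raise KeyError(f"unknown trajectory preset '{preset_name}'")
    fields = dict(_SWEEP_PROTOCOL)
    fields.update(TRAJECTORY_PRESETS[preset_name])
    return base.replace(**fields)


def run_sweep(
    param: str,
    grid: Sequence[float],
    config: Config,
    n_replicates: Optional[int] = None,
    fixed: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Run a one-parameter sweep; one aggregated row per grid point.

    All grid points share the base seed, so replicate r sees the same task
    randomness at every point (matched seeds).
    """
    if len(grid) == 0:
        raise ValueError("sweep grid must be nonempty")
    rows = []
    for value in grid:
        fields = dict(fixed) if fixed else {}
        fields[param] = value
        cfg = config.replace(**fields)
        result = run_replicates(cfg, n_replicates=n_replicates)
        row = {"param": param, "value": value, "n_replicates": result.n_replicates}
        for stat, mean in result.aggregate["mean"].items():
            row[f"{stat}_mean"] = mean
            row[f"{stat}_sem"] = result.aggregate["sem"][stat]
        rows.append(row)
    return pd.DataFrame(rows)


def run_sweep_preset(
    name: str, config: Config, n_replicates: Optional[int] = None
) -> pd.DataFrame:
    """Run one of the shipped sweep presets on top of a base config."""
    if name not in SWEEP_PRESETS:
        raise KeyError(f"unknown sweep preset '{name}'")
    preset = SWEEP_PRESETS[name]
    fields = dict(_SWEEP_PROTOCOL)
    fields.update(preset.fixed)
    base = config.replace(**fields)
    return run_sweep(preset.param, preset.grid, base, n_replicates=n_replicates)
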