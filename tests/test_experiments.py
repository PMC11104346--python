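"""Session orchestration, summaries, replicates, sweeps: contracts and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aegng import Config, run_replicates, run_session, summarize
from aegng.experiments import (
    SWEEP_PRESETS,
    TRAJECTORY_PRESETS,
    replicate_seed,
    run_sweep,
    sweep_config,
    trajectory_config,
)


def test_identical_seeds_give_identical_sessions():
    cfg = Config(n_trials=60, reversal_trial=30)
    a = run_session(cfg, seed=11)
    b = run_session(cfg, seed=11)
    pd.testing.assert_frame_equal(a, b)
    c = run_session(cfg, seed=12)
    assert not a["cue"].equals(c["cue"]) or not a["outcome"].equals(c["outcome"])


def test_empty_session_returns_no_records():
    cfg = Config(n_trials=0, reversal_trial=0)
    records = run_session(cfg)
    assert len(records) == 0
    with pytest.raises(ValueError):
        summarize(records, 0)


def test_trial_records_are_internally_consistent():
    cfg = Config(n_trials=120, reversal_trial=60)
    df = run_session(cfg, seed=3)
    assert list(df["trial"]) == list(range(120))
    assert set(df["cue_label"]) <= {"GA", "NGA", "GE", "NGE"}
    # policy posterior normalized on every trial
    assert np.allclose(df[["pi_go", "pi_nogo", "pi_pav"]].sum(axis=1), 1.0)
    # Avoid cues carry A-labels, Escape cues E-labels, under both contingencies
    assert df.loc[df["condition"] == "Avoid", "cue_label"].str.endswith("A").all()
    assert df.loc[df["condition"] == "Escape", "cue_label"].str.endswith("E").all()
    # outcome/final-state/observation naming is coherent
    go_rows = df["action"] == "Go"
    assert df.loc[go_rows, "final_state"].isin(["s9", "s10"]).all()
    assert df.loc[~go_rows, "final_state"].isin(["s11", "s12"]).all()
    neutral = df["outcome"] == "neutral"
    assert df.loc[neutral, "observation"].isin(["o6", "o8"]).all()
    assert df.loc[~neutral, "observation"].isin(["o7", "o9"]).all()


def test_labels_swap_at_reversal_within_condition():
    cfg = Config(n_trials=40, reversal_trial=20)
    df = run_session(cfg, seed=5)
    pre = df[df["trial"] < 20]
    post = df[df["trial"] >= 20]
    for cue in sorted(df["cue"].unique()):
        pre_labels = set(pre.loc[pre["cue"] == cue, "cue_label"])
        post_labels = set(post.loc[post["cue"] == cue, "cue_label"])
        if pre_labels and post_labels:
            assert pre_labels.isdisjoint(post_labels)


def test_correct_action_beliefs_converge_under_deterministic_feedback():
    # y=1, k=0, controllability off: the acting policy's neutral beliefs
    # approach 1 for correct actions (Dirichlet means under deterministic reward)
    cfg = Config(y=1.0, k=0.0, controllability_enabled=False,
                 n_trials=300, reversal_trial=300)
    df = run_session(cfg, seed=2)
    last = df.iloc[-1]
    # pre-reversal correct actions: cue1 Go, cue2 No-Go, cue3 Go, cue4 No-Go
    correct = [last["belief_neutral_go_cue1"], last["belief_neutral_nogo_cue2"],
               last["belief_neutral_go_cue3"], last["belief_neutral_nogo_cue4"]]
    wrong = [last["belief_neutral_nogo_cue1"], last["belief_neutral_go_cue2"],
             last["belief_neutral_nogo_cue3"], last["belief_neutral_go_cue4"]]
    assert min(correct) > 0.8
    assert max(wrong) < min(correct)
    assert (df["eta"] == 1.0).all()  # k = 0: valence-independent learning
    assert (df["c_eff"] == cfg.c).all()  # cascade disabled


def test_summarize_arithmetic_on_constructed_records():
    # GE accuracy 0.9 and NGE accuracy 0.6 -> bias 0.3
    rows = []
    for i in range(20):
        rows.append({"trial": i, "cue_label": "GE", "correct": i < 18,
                     "pi_pav": 0.25, "mean_neutral_belief": 0.5})
    for i in range(20, 40):
        rows.append({"trial": i, "cue_label": "NGE", "correct": i < 32,
                     "pi_pav": 0.15, "mean_neutral_belief": 0.7})
    df = pd.DataFrame(rows)
    s = summarize(df, reversal_trial=40)
    assert s.accuracy_overall["GE"] == pytest.approx(0.9)
    assert s.accuracy_overall["NGE"] == pytest.approx(0.6)
    assert s.active_escape_bias == pytest.approx(0.3)
    assert s.mean_pavlovian_prob == pytest.approx(0.2)
    assert s.mean_neutral_belief == pytest.approx(0.6)
    assert s.overall_accuracy == pytest.approx(0.75)


def test_all_correct_records_give_unit_accuracy_and_zero_bias():
    rows = [{"trial": i, "cue_label": lab, "correct": True, "pi_pav": 0.1,
             "mean_neutral_belief": 0.5}
            for i, lab in enumerate(["GA", "NGA", "GE", "NGE"] * 5)]
    s = summarize(pd.DataFrame(rows), reversal_trial=10)
    assert all(v == 1.0 for v in s.accuracy_overall.values())
    assert s.active_escape_bias == 0.0


def test_replicates_aggregate_is_mean_of_summaries():
    cfg = Config(n_trials=80, reversal_trial=40, base_seed=9)
    result = run_replicates(cfg, n_replicates=6)
    assert result.n_replicates == 6
    assert result.aggregate.loc["overall_accuracy", "mean"] == pytest.approx(
        result.summaries["overall_accuracy"].mean()
    )
    expected_sem = result.summaries["overall_accuracy"].std(ddof=1) / np.sqrt(6)
    assert result.aggregate.loc["overall_accuracy", "sem"] == pytest.approx(expected_sem)


def test_replicate_seeds_are_deterministic_and_distinct():
    cfg = Config(n_trials=50, reversal_trial=25, base_seed=4)
    r1 = run_replicates(cfg, n_replicates=4)
    r2 = run_replicates(cfg, n_replicates=4)
    pd.testing.assert_frame_equal(r1.summaries, r2.summaries)
    # distinct replicates see different task randomness
    assert r1.summaries["overall_accuracy"].nunique() > 1
    assert replicate_seed(4, 0).spawn_key != replicate_seed(4, 1).spawn_key


def test_single_point_sweep_reduces_to_replicates():
    cfg = Config(n_trials=60, reversal_trial=30, base_seed=1)
    table = run_sweep("k", [0.3], cfg, n_replicates=3)
    direct = run_replicates(cfg.replace(k=0.3), n_replicates=3)
    assert len(table) == 1
    assert table.loc[0, "active_escape_bias_mean"] == pytest.approx(
        direct.aggregate.loc["active_escape_bias", "mean"]
    )
    with pytest.raises(ValueError):
        run_sweep("k", [], cfg)


def test_sweep_presets_carry_published_fixed_values():
    assert SWEEP_PRESETS["k"].fixed == {"m": 1.3, "c": 8.0, "w0": 0.6}
    assert SWEEP_PRESETS["m"].fixed == {"k": 0.7, "c": 8.0, "w0": 0.6}
    assert SWEEP_PRESETS["c"].fixed == {"k": 0.6, "m": 1.0, "w0": 0.5}
    assert SWEEP_PRESETS["w0"].fixed == {"k": 0.9, "m": 1.3, "c": 8.0}
    cfg = sweep_config(Config(), SWEEP_PRESETS["k"], 1.0)
    assert cfg.k == 1.0 and cfg.w0 == 0.6 and cfg.n_trials == 400
    assert cfg.reversal_trial == 200


def test_trajectory_presets_match_perturbation_configs():
    assert TRAJECTORY_PRESETS["low-decay"]["m"] == 2.0
    assert TRAJECTORY_PRESETS["low-controllability"]["w0"] == 0.8
    assert TRAJECTORY_PRESETS["high-stress-weight"]["k"] == 1.1
    assert TRAJECTORY_PRESETS["high-stress-sensitivity"]["c"] == 20.0
    cfg = trajectory_config(Config(), "low-decay")
    assert cfg.m == 2.0 and cfg.k == 0.7 and cfg.n_trials == 400
    with pytest.raises(KeyError):
        trajectory_config(Config(), "nonexistent")


def test_tracked_cue_columns_present_and_bounded():
    cfg = trajectory_config(Config(n_trials=50, reversal_trial=25), "low-decay")
    cfg = cfg.replace(n_trials=50, reversal_trial=25)
    df = run_session(cfg, seed=0, track_cue=3)
    for col in ("track_pi_pav", "track_belief_go", "track_belief_nogo"):
        assert df[col].between(0.0, 1.0).all()


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    k=st.floats(0.0, 1.3),
    m=st.floats(0.5, 2.5),
    c=st.floats(1.0, 20.0),
    w0=st.floats(0.0, 1.0),
    seed=st.integers(0, 10_000),
)
def test_fuzzed_sessions_preserve_all_invariants(k, m, c, w0, seed):
    """Normalization, bounds and structural constraints hold on every trial
    across the parameter space (per-trial checks raise on violation)."""
    cfg = Config(k=k, m=m, c=c, w0=w0, n_trials=60, reversal_trial=30)
    df = run_session(cfg, seed=seed, validate=True)
    assert np.isfinite(df[["sape", "lambda", "eta", "c_eff"]].to_numpy()).all()
    assert (df["sape"] >= 0).all()
    assert df["lambda"].between(cfg.lambda_min, cfg.lambda_max).all()
    assert (df["eta"] >= 1.0).all()
    belief_cols = [col for col in df.columns if col.startswith("belief_")]
    assert df[belief_cols].to_numpy().min() > 0.0
    assert df[belief_cols].to_numpy().max() < 1.0
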