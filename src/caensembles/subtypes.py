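"""Subensemble classification of Poking-ON and Reward-ON neurons.

Poking-ON neurons split by trial-type response profile:
  Attention-like   significant ON response in correct trials only;
  Trigger-like     ON in both correct and incorrect trials, calcium events
                   predominantly before poke onset;
  Visual-stim      ON in both, events strictly after onset (stimulus driven).
Reward-ON neurons split into:
  Reward-pursuing  ON in both correct and incorrect trials (choice locked);
  Rewarded         ON only when the outcome was a water reward.

"ON response in a trial type" is operationalized as a permutation-significant
positive mean windowed z-score at alpha = 0.05: the observed mean over that
trial type's windows is compared with means recomputed after exchanging trial
windows with same-length baseline windows (frames outside every annotated
behavior epoch).  A threshold-on-mean-z rule is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    BEHAVIOR_POKING,
    BEHAVIOR_REWARD,
    OUTCOMES,
    SessionBundle,
    seconds_to_frames,
)
from .preprocess import align_to_onsets, mean_window_response, zscore_traces

__all__ = [
    "SubtypeConfig",
    "trialtype_significance",
    "baseline_window_means",
    "trial_type_responses",
    "subtype_poking",
    "subtype_reward",
    "subtype_population",
    "previous_outcome_modulation",
    "port_preference",
]

UNTESTABLE = "untestable"


@dataclass(frozen=True)
class SubtypeConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    min_trials: int = 3
    rule: str = "permutation"  # or "threshold": mean z > z_threshold
    z_threshold: float = 0.5
    seed: int = 0


def trialtype_significance(
    trial_means: np.ndarray,
    baseline_means: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_trials: int = 3,
    rng: np.random.Generator | int = 0,
):
    """Is the mean windowed response of one trial type above chance?

    Permutation null: draw ``len(trial_means)`` values from the pooled trial
    and baseline window means and recompute the mean.  Returns True / False,
    or the string "untestable" when fewer than ``min_trials`` trials exist
    (never a silent False).
    """
    trial_means = np.asarray(trial_means, dtype=float)
    baseline_means = np.asarray(baseline_means, dtype=float)
    if trial_means.size < min_trials:
        return UNTESTABLE
    if alpha >= 1.0:
        return True
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = trial_means.mean()
    pooled = np.concatenate([trial_means, baseline_means])
    m = trial_means.size
    idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)[:, :m]
    null = pooled[idx].mean(axis=1)
    return bool(observed > np.quantile(null, 1.0 - alpha))


def baseline_window_means(
    ztrace: np.ndarray,
    behaviors: dict[str, np.ndarray],
    window_frames: int,
) -> np.ndarray:
    """Mean z of non-overlapping windows carved from frames outside every
    annotated behavior epoch (the baseline definition used throughout)."""
    occupied = np.zeros(len(ztrace), dtype=bool)
    for vec in behaviors.values():
        occupied |= np.asarray(vec).astype(bool)
    free = ~occupied
    means = []
    run_start = None
    for i, ok in enumerate(np.concatenate([free, [False]])):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            for s in range(run_start, i - window_frames + 1, window_frames):
                means.append(ztrace[s : s + window_frames].mean())
            run_start = None
    return np.asarray(means)


def _aligned_means(
    bundle: SessionBundle,
    ztraces: np.ndarray,
    behavior: str,
    config_windows: dict,
) -> tuple[dict[str, np.ndarray], int]:
    """Per-outcome (neurons x trials) mean windowed z, aligned per behavior.

    Poking responses align to poke onset; reward responses align to the
    choice/lick frame (water delivery on correct trials, unrewarded licks on
    incorrect and licking-only trials)."""
    window = config_windows[behavior]
    out: dict[str, np.ndarray] = {}
    for outcome, sub in bundle.trials.groupby("outcome"):
        if behavior == BEHAVIOR_POKING:
            onsets = sub["poke_onset_frame"].to_numpy()
        else:
            onsets = np.where(
                sub["reward_frame"].to_numpy() >= 0,
                sub["reward_frame"].to_numpy(),
                sub["choice_frame"].to_numpy(),
            )
        onsets = onsets[onsets >= 0]
        if onsets.size == 0:
            continue
        peri = align_to_onsets(ztraces, onsets, window, bundle.frame_rate)
        out[outcome] = mean_window_response(peri, window)
    w0, w1 = window
    return out, seconds_to_frames(w1 - w0, bundle.frame_rate) + 1


def trial_type_responses(
    bundle: SessionBundle,
    behavior: str,
    config: SubtypeConfig | None = None,
    ztraces: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-neuron mean windowed z and significance flag for every trial type.

    Returns a long DataFrame: neuron_id, trial_type, mean_z, significant
    (True/False/"untestable").
    """
    config = config or SubtypeConfig()
    if ztraces is None:
        ztraces = zscore_traces(bundle.traces)
    cfg = bundle.extras.get("config")
    windows = {
        BEHAVIOR_POKING: cfg.poking_window if cfg is not None else (-0.5, 1.5),
        BEHAVIOR_REWARD: cfg.reward_window if cfg is not None else (-0.5, 3.5),
    }
    means, window_frames = _aligned_means(bundle, ztraces, behavior, windows)
    rows = []
    for n_idx in range(bundle.n_neurons):
        baseline = baseline_window_means(ztraces[n_idx], bundle.behaviors, window_frames)
        for outcome, mat in means.items():
            rng = np.random.default_rng([config.seed, OUTCOMES.index(outcome), n_idx])
            trial_means = mat[n_idx]
            if config.rule == "threshold":
                sig = (
                    UNTESTABLE
                    if trial_means.size < config.min_trials
                    else bool(trial_means.mean() > config.z_threshold)
                )
            else:
                sig = trialtype_significance(
                    trial_means,
                    baseline,
                    n_perm=config.n_perm,
                    alpha=config.alpha,
                    min_trials=config.min_trials,
                    rng=rng,
                )
            rows.append((n_idx, outcome, float(trial_means.mean()), sig))
    return pd.DataFrame(rows, columns=["neuron_id", "trial_type", "mean_z", "significant"])


def _flag(responses: pd.DataFrame, neuron_id: int, trial_type: str):
    sel = responses[
        (responses["neuron_id"] == neuron_id) & (responses["trial_type"] == trial_type)
    ]
    if sel.empty:
        return UNTESTABLE
    val = sel["significant"].iloc[0]
    return val if isinstance(val, str) else bool(val)


def subtype_poking(
    responses: pd.DataFrame, neuron_id: int, event_times_rel: np.ndarray
) -> str:
    """Subtype one Poking-ON neuron from its trial-type flags and the timing
    of its calcium events relative to poke onset (seconds)."""
    corr = _flag(responses, neuron_id, "correct")
    inc = _flag(responses, neuron_id, "incorrect")
    if corr is True and inc is False:
        return "Attention-like"
    if corr is True and inc is True:
        times = np.asarray(event_times_rel, dtype=float)
        if times.size == 0:
            return "Unclassified"
        return "Trigger-like" if np.median(times) <= 0 else "Visual-stim"
    return "Unclassified"


def subtype_reward(responses: pd.DataFrame, neuron_id: int) -> str:
    """Subtype one Reward-ON neuron: choice-locked (both outcomes) vs
    reward-delivery-only responders."""
    corr = _flag(responses, neuron_id, "correct")
    inc = _flag(responses, neuron_id, "incorrect")
    lick = _flag(responses, neuron_id, "licking_only")
    if corr is True and inc is True:
        return "Reward-pursuing"
    if corr is True and inc is False and lick is not True:
        return "Rewarded"
    return "Unclassified"


def subtype_population(
    bundle: SessionBundle,
    labels: pd.DataFrame,
    config: SubtypeConfig | None = None,
    event_trains: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assign a subtype to every ON neuron of both behaviors.

    ``event_trains`` maps neuron_id -> detected event frames (computed with
    :func:`caensembles.preprocess.detect_events` when omitted).
    """
    from .preprocess import detect_events

    config = config or SubtypeConfig()
    ztraces = zscore_traces(bundle.traces)
    out_rows = []
    for behavior in (BEHAVIOR_POKING, BEHAVIOR_REWARD):
        on_ids = labels[
            (labels["behavior"] == behavior) & (labels["label"] == "ON")
        ]["neuron_id"].to_numpy()
        if on_ids.size == 0:
            continue
        responses = trial_type_responses(bundle, behavior, config, ztraces)
        pokes = bundle.trials.loc[
            bundle.trials["poke_onset_frame"] >= 0, "poke_onset_frame"
        ].to_numpy()
        for nid in on_ids:
            if behavior == BEHAVIOR_POKING:
                if event_trains is not None and nid in event_trains:
                    events = np.asarray(event_trains[nid])
                else:
                    events = detect_events(bundle.traces[nid], bundle.frame_rate)
                rel = []
                half = 2.0  # s window for attributing an event to a poke
                half_f = seconds_to_frames(half, bundle.frame_rate)
                for p in pokes:
                    near = events[(events >= p - half_f) & (events <= p + half_f)]
                    rel.extend((near - p) / bundle.frame_rate)
                subtype = subtype_poking(responses, nid, np.asarray(rel))
            else:
                subtype = subtype_reward(responses, nid)
            resp = responses[responses["neuron_id"] == nid]
            mz = dict(zip(resp["trial_type"], resp["mean_z"]))
            out_rows.append(
                (
                    nid,
                    behavior,
                    subtype,
                    mz.get("correct", np.nan),
                    mz.get("incorrect", np.nan),
                    mz.get("omission", mz.get("licking_only", np.nan)),
                )
            )
    return pd.DataFrame(
        out_rows,
        columns=[
            "neuron_id",
            "behavior",
            "subtype",
            "mean_z_correct",
            "mean_z_incorrect",
            "mean_z_omission_or_licking",
        ],
    )


@dataclass(frozen=True)
class OutcomeModulation:
    mean_after_correct: float
    mean_after_incorrect: float
    difference: float
    p_value: float
    n_after_correct: int
    n_after_incorrect: int


def previous_outcome_modulation(
    per_trial_response: np.ndarray,
    outcomes,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
    trial_slice: slice | None = None,
) -> OutcomeModulation | str:
    """Compare responses after correct vs after incorrect previous trials.

    ``per_trial_response`` is one value per trial (e.g. an ensemble's mean
    windowed z); the first trial has no previous outcome and is excluded, as
    are trials whose previous outcome is neither correct nor incorrect.
    ``trial_slice`` restricts the comparison to part of the session for
    split-half analyses.  Returns "untestable" when either group has < 3
    trials, else group means with a two-sided permutation p-value.
    """
    resp = np.asarray(per_trial_response, dtype=float)
    outcomes = list(outcomes)
    if len(resp) != len(outcomes):
        raise ValueError("response and outcome lists differ in length")
    prev = np.array(["" ] + outcomes[:-1])
    idx = np.arange(len(resp))
    keep = (idx > 0) & np.isin(prev, ("correct", "incorrect"))
    if trial_slice is not None:
        in_slice = np.zeros(len(resp), dtype=bool)
        in_slice[trial_slice] = True
        keep &= in_slice
    groups = prev[keep]
    vals = resp[keep]
    after_c = vals[groups == "correct"]
    after_i = vals[groups == "incorrect"]
    if after_c.size < 3 or after_i.size < 3:
        return UNTESTABLE
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = after_c.mean() - after_i.mean()
    n_c = after_c.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        if abs(perm[:n_c].mean() - perm[n_c:].mean()) >= abs(observed) - 1e-15:
            count += 1
    return OutcomeModulation(
        mean_after_correct=float(after_c.mean()),
        mean_after_incorrect=float(after_i.mean()),
        difference=float(observed),
        p_value=(count + 1.0) / (n_perm + 1.0),
        n_after_correct=int(n_c),
        n_after_incorrect=int(after_i.size),
    )


def port_preference(
    per_trial_response: np.ndarray,
    reward_sides,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> str:
    """Left/right/none port preference of one Rewarded neuron.

    Inputs are per-correct-trial responses and the rewarded side of each of
    those trials; a two-sided permutation test on side labels assigns a
    preference at ``alpha``, otherwise "none".
    """
    resp = np.asarray(per_trial_response, dtype=float)
    sides = np.asarray(list(reward_sides))
    if len(resp) != len(sides):
        raise ValueError("response and side lists differ in length")
    left = resp[sides == "left"]
    right = resp[sides == "right"]
    if left.size < 3 or right.size < 3:
        return UNTESTABLE
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = left.mean() - right.mean()
    n_l = left.size
    vals = np.concatenate([left, right])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        if abs(perm[:n_l].mean() - perm[n_l:].mean()) >= abs(observed) - 1e-15:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    if p >= alpha:
        return "none"
    return "left" if observed > 0 else "right"
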