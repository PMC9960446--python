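"""Synthetic sessions with planted behaviorally tuned neurons.

Emulates a head-mounted miniScope recording during a self-initiated
two-alternative visual discrimination task: a mouse pokes a center port to
trigger a trial, chooses a side spout, and on correct choices receives a
water reward.  DF/F traces are built as sparse event trains convolved with
a GCaMP6f-like double-exponential kernel plus Gaussian noise, shifted to be
nonnegative.  Each neuron carries a planted tuning class so downstream
classifiers can be scored against ground truth.

Tuning classes
--------------
Trigger-like      poking-aligned, pre-onset, fires on correct/incorrect and
                  (attenuated) omission trials; modulated by previous outcome.
Attention-like    poking-aligned, post-onset, correct trials only.
Visual-stim       poking-aligned, strictly post-onset, outcome independent.
Reward-pursuing   choice-locked, transient, correct and incorrect trials
                  (attenuated on licking-only events).
Rewarded          reward-delivery-locked, sustained, correct trials only;
                  optional left/right port bias.
Poking-OFF / Reward-OFF
                  tonic background activity suppressed during the matching
                  behavior epochs.
Other             pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    BEHAVIOR_POKING,
    BEHAVIOR_REWARD,
    CLASS_TO_ENSEMBLE,
    OUTCOMES,
    REWARD_SIDES,
    SessionBundle,
    TUNING_CLASSES,
    seconds_to_frames,
)

__all__ = [
    "SessionConfig",
    "NeuronSpec",
    "TransientKernel",
    "TrackedPairConfig",
    "simulate_session",
    "simulate_tracked_pair",
    "default_retention",
]


@dataclass(frozen=True)
class TransientKernel:
    """Unit-peak calcium transient: difference of exponentials."""

    rise_time: float = 0.1  # s
    decay_time: float = 1.0  # s

    def __post_init__(self):
        if self.rise_time < 0 or self.decay_time <= 0:
            raise ValueError("kernel times must be nonnegative (decay > 0)")
        if self.rise_time >= self.decay_time:
            raise ValueError("rise_time must be shorter than decay_time")

    def evaluate(self, frame_rate: float, duration: float | None = None) -> np.ndarray:
        """Sampled kernel, normalized to unit peak; truncated at ``duration`` s
        (default 6 decay constants)."""
        if duration is None:
            duration = 6.0 * self.decay_time
        t = np.arange(0.0, duration, 1.0 / frame_rate)
        k = np.exp(-t / self.decay_time) - np.exp(-t / max(self.rise_time, 1e-6))
        peak = k.max()
        if peak <= 0:
            raise ValueError("degenerate kernel")
        return k / peak


@dataclass(frozen=True)
class SessionConfig:
    """Task and recording parameters for one simulated session.

    Defaults emulate the study conditions: 10-Hz acquisition, ~100 trials per
    day, a −0.5→1.5 s poking window around stimulus onset and a −0.5→3.5 s
    window around water delivery, a 10-s timeout after incorrect choices and
    a 20-s no-response limit for omissions.
    """

    n_trials: int = 100
    frame_rate: float = 10.0
    inter_trial_gap: tuple[float, float] = (2.0, 5.0)  # s
    p_correct: float = 0.70
    p_incorrect: float = 0.15
    p_omission: float = 0.10
    p_licking_only: float = 0.05
    reward_window: tuple[float, float] = (-0.5, 3.5)  # s relative to delivery
    poking_window: tuple[float, float] = (-0.5, 1.5)  # s relative to poke
    reaction_time: tuple[float, float] = (1.5, 3.0)  # s, poke -> side choice
    timeout: float = 10.0  # s after incorrect choice
    omission_timeout: float = 20.0  # s without a choice
    noise_sd: float = 1.0  # DF/F units; planted amplitudes are ~z units
    kernel: TransientKernel = field(default_factory=TransientKernel)
    roi_field_px: float = 400.0
    roi_cluster_std: float | None = None  # cluster tuned neurons if set
    edge_buffer: float = 5.0  # s of quiet recording before/after trials
    seed: int = 0

    def __post_init__(self):
        probs = (self.p_correct, self.p_incorrect, self.p_omission, self.p_licking_only)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("outcome probabilities must lie in [0, 1]")
        if sum(probs) > 1 + 1e-9:
            raise ValueError("outcome probabilities must sum to at most 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be at least 1 (got n_trials=%d)" % self.n_trials)
        for name in ("reward_window", "poking_window", "inter_trial_gap", "reaction_time"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy start < end, got ({lo}, {hi})")

    @property
    def outcome_probs(self) -> np.ndarray:
        p = np.array(
            [self.p_correct, self.p_incorrect, self.p_omission, self.p_licking_only],
            dtype=float,
        )
        return p / p.sum()


# amplitude applied on top of response_amplitude for attenuated trial types
_OMISSION_GAIN = 0.6  # Trigger-like response on omission trials is mild
_LICKING_GAIN = 0.5  # Reward-pursuing response on licking-only events is mild

# alignment of each class's response: poke onset, side choice, or reward delivery
_ALIGNMENT = {
    "Trigger-like": "poke",
    "Attention-like": "poke",
    "Visual-stim": "poke",
    "Reward-pursuing": "choice",
    "Rewarded": "reward",
}

_CLASS_DEFAULTS = {
    # class: (latency s, sustain s, outcome gating); latencies are spike times,
    # so the transient *peak* (the marked event) lags by the kernel rise (~0.26 s)
    "Trigger-like": (-0.5, 0.0, ("correct", "incorrect", "omission")),
    "Attention-like": (0.2, 0.0, ("correct",)),
    "Visual-stim": (0.4, 0.0, ("correct", "incorrect")),
    "Reward-pursuing": (0.1, 0.0, ("correct", "incorrect", "licking_only")),
    "Rewarded": (0.2, 2.0, ("correct",)),
    "Poking-OFF": (0.0, 0.0, ()),
    "Reward-OFF": (0.0, 0.0, ()),
    "Other": (0.0, 0.0, ()),
}


@dataclass(frozen=True)
class NeuronSpec:
    """Planted tuning of one simulated neuron."""

    tuning_class: str = "Other"
    response_amplitude: float = 5.0  # peak DF/F in noise-SD (~z) units
    response_latency: float | None = None  # s relative to aligned onset
    sustain: float | None = None  # s of sustained response (0 = transient)
    outcome_gating: tuple[str, ...] | None = None
    prev_outcome_gain: float = 1.0  # gain after a correct previous trial
    port_bias: float = 1.0  # left-port amplitude gain (right = 1)
    tonic_rate: float = 1.0  # Hz, background events for OFF classes

    def __post_init__(self):
        if self.tuning_class not in TUNING_CLASSES:
            raise ValueError(
                f"unknown tuning_class {self.tuning_class!r}; valid: {list(TUNING_CLASSES)}"
            )
        if self.response_amplitude < 0:
            raise ValueError("response_amplitude must be >= 0")
        lat, sus, gating = _CLASS_DEFAULTS[self.tuning_class]
        if self.response_latency is None:
            object.__setattr__(self, "response_latency", lat)
        if self.sustain is None:
            object.__setattr__(self, "sustain", sus)
        if self.sustain < 0:
            raise ValueError("sustain must be >= 0")
        if self.outcome_gating is None:
            object.__setattr__(self, "outcome_gating", gating)
        bad = set(self.outcome_gating) - set(OUTCOMES)
        if bad:
            raise ValueError(f"outcome_gating contains unknown outcomes {sorted(bad)}")
        if self.tuning_class == "Attention-like" and set(self.outcome_gating) != {"correct"}:
            raise ValueError("Attention-like neurons gate on correct trials only")


def _draw_sides(rng: np.random.Generator, n: int) -> list[str]:
    """Pseudorandom reward sides, at most two consecutive repeats."""
    sides: list[str] = []
    for _ in range(n):
        if len(sides) >= 2 and sides[-1] == sides[-2]:
            sides.append("left" if sides[-1] == "right" else "right")
        else:
            sides.append(REWARD_SIDES[rng.integers(2)])
    return sides


def _build_trials(config: SessionConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, int]:
    """Lay trials out on the session timeline; returns (trial table, n_frames)."""
    fr = config.frame_rate
    cur = seconds_to_frames(config.edge_buffer, fr)
    outcomes = [OUTCOMES[i] for i in rng.choice(4, size=config.n_trials, p=config.outcome_probs)]
    sides = _draw_sides(rng, config.n_trials)
    rows = []
    for i, (outcome, side) in enumerate(zip(outcomes, sides)):
        gap = seconds_to_frames(rng.uniform(*config.inter_trial_gap), fr)
        if outcome == "licking_only":
            lick = cur + seconds_to_frames(0.5, fr)
            rows.append((i, -1, lick, outcome, side, -1))
            cur = lick + seconds_to_frames(2.0, fr)
        else:
            poke = cur
            if outcome == "omission":
                rows.append((i, poke, -1, outcome, side, -1))
                cur = poke + seconds_to_frames(config.omission_timeout, fr)
            else:
                rt = rng.uniform(*config.reaction_time)
                choice = poke + seconds_to_frames(rt, fr)
                if outcome == "correct":
                    rows.append((i, poke, choice, outcome, side, choice))
                    cur = choice + seconds_to_frames(config.reward_window[1] + 0.5, fr)
                else:
                    rows.append((i, poke, choice, outcome, side, -1))
                    cur = choice + seconds_to_frames(config.timeout, fr)
        cur += gap
    n_frames = cur + seconds_to_frames(config.edge_buffer, fr)
    trials = pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "poke_onset_frame",
            "choice_frame",
            "outcome",
            "reward_side",
            "reward_frame",
        ],
    )
    return trials, n_frames


def behavior_vectors_from_trials(
    trials: pd.DataFrame, n_frames: int, config: SessionConfig
) -> dict[str, np.ndarray]:
    """Frame-wise 0/1 annotation vectors implied by the trial table.

    Poking epochs span the poking window around every poke onset; reward
    epochs span the reward window around water delivery on correct trials.
    """
    fr = config.frame_rate
    vectors = {
        BEHAVIOR_POKING: np.zeros(n_frames, dtype=np.int8),
        BEHAVIOR_REWARD: np.zeros(n_frames, dtype=np.int8),
    }
    p0, p1 = (seconds_to_frames(t, fr) for t in config.poking_window)
    r0, r1 = (seconds_to_frames(t, fr) for t in config.reward_window)
    for _, row in trials.iterrows():
        if row.poke_onset_frame >= 0:
            a, b = row.poke_onset_frame + p0, row.poke_onset_frame + p1
            vectors[BEHAVIOR_POKING][max(a, 0) : min(b, n_frames - 1) + 1] = 1
        if row.reward_frame >= 0:
            a, b = row.reward_frame + r0, row.reward_frame + r1
            vectors[BEHAVIOR_REWARD][max(a, 0) : min(b, n_frames - 1) + 1] = 1
    return vectors


def _response_events(
    spec: NeuronSpec,
    trials: pd.DataFrame,
    config: SessionConfig,
    rng: np.random.Generator,
) -> list[tuple[int, float]]:
    """(frame, amplitude) events for one tuned neuron."""
    fr = config.frame_rate
    events: list[tuple[int, float]] = []
    align = _ALIGNMENT[spec.tuning_class]
    prev_outcome = None
    for _, row in trials.iterrows():
        outcome = row.outcome
        gated = outcome in spec.outcome_gating
        if gated:
            if align == "poke":
                onset = row.poke_onset_frame
            elif align == "choice":
                onset = row.choice_frame
            else:
                onset = row.reward_frame if row.reward_frame >= 0 else -1
            if onset >= 0:
                amp = spec.response_amplitude * rng.uniform(0.8, 1.2)
                if outcome == "omission":
                    amp *= _OMISSION_GAIN
                if outcome == "licking_only":
                    amp *= _LICKING_GAIN
                if prev_outcome == "correct":
                    amp *= spec.prev_outcome_gain
                if align == "reward" and row.reward_side == "left":
                    amp *= spec.port_bias
                t0 = onset + seconds_to_frames(spec.response_latency, fr) + int(rng.integers(-1, 2))
                if spec.sustain > 0:
                    step = max(1, seconds_to_frames(0.3, fr))
                    for f in range(t0, t0 + seconds_to_frames(spec.sustain, fr) + 1, step):
                        events.append((f, amp * rng.uniform(0.7, 1.0)))
                else:
                    events.append((t0, amp))
        prev_outcome = outcome
    return events


def _tonic_off_events(
    spec: NeuronSpec,
    suppress: np.ndarray,
    n_frames: int,
    config: SessionConfig,
    rng: np.random.Generator,
) -> list[tuple[int, float]]:
    """Tonic background events, deleted inside the suppressed behavior epochs."""
    fr = config.frame_rate
    n_events = rng.poisson(spec.tonic_rate * n_frames / fr)
    frames = rng.integers(0, n_frames, size=n_events)
    # suppress a fringe after each epoch too, so the decay tail does not leak in
    fringe = seconds_to_frames(config.kernel.decay_time, fr)
    blocked = np.convolve(suppress.astype(float), np.ones(fringe + 1), mode="full")[:n_frames] > 0
    keep = frames[~blocked[frames]]
    return [(int(f), spec.response_amplitude * rng.uniform(0.8, 1.2)) for f in keep]


def _render_trace(
    events: list[tuple[int, float]],
    n_frames: int,
    config: SessionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    spikes = np.zeros(n_frames)
    for frame, amp in events:
        if 0 <= frame < n_frames:
            spikes[frame] += amp
    kernel = config.kernel.evaluate(config.frame_rate)
    signal = np.convolve(spikes, kernel)[:n_frames]
    trace = signal + rng.normal(0.0, config.noise_sd, n_frames)
    return trace - trace.min()  # DF/F is nonnegative by construction


def _scatter_rois(
    specs: list[NeuronSpec], config: SessionConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(specs)
    xy = rng.uniform(0.0, config.roi_field_px, size=(n, 2))
    if config.roi_cluster_std is not None:
        center = rng.uniform(
            0.25 * config.roi_field_px, 0.75 * config.roi_field_px, size=2
        )
        for i, spec in enumerate(specs):
            if spec.tuning_class != "Other":
                xy[i] = center + rng.normal(0.0, config.roi_cluster_std, size=2)
    xy = np.clip(xy, 0.0, config.roi_field_px)
    return pd.DataFrame(
        {"neuron_id": np.arange(n), "x_px": xy[:, 0], "y_px": xy[:, 1]}
    )


def simulate_session(
    config: SessionConfig, neuron_specs: list[NeuronSpec]
) -> tuple[SessionBundle, pd.DataFrame]:
    """Simulate one session.

    Returns
    -------
    bundle : SessionBundle
        Traces (nonnegative DF/F), trial table, behavior vectors, ROI map.
    ground_truth : DataFrame
        Columns neuron_id, tuning_class, behavior, polarity — the planted label
        of every neuron.
    """
    if not neuron_specs:
        raise ValueError("at least one NeuronSpec is required (neuron_specs is empty)")
    rng = np.random.default_rng(config.seed)
    trials, n_frames = _build_trials(config, rng)
    if n_frames <= 0:
        raise ValueError("session has zero frames")
    behaviors = behavior_vectors_from_trials(trials, n_frames, config)

    traces = np.empty((len(neuron_specs), n_frames))
    for i, spec in enumerate(neuron_specs):
        if spec.tuning_class in ("Poking-OFF", "Reward-OFF"):
            vec = behaviors[
                BEHAVIOR_POKING if spec.tuning_class == "Poking-OFF" else BEHAVIOR_REWARD
            ]
            events = _tonic_off_events(spec, vec.astype(bool), n_frames, config, rng)
        elif spec.tuning_class == "Other":
            events = []
        else:
            events = _response_events(spec, trials, config, rng)
        traces[i] = _render_trace(events, n_frames, config, rng)

    rois = _scatter_rois(neuron_specs, config, rng)
    ground_truth = pd.DataFrame(
        {
            "neuron_id": np.arange(len(neuron_specs)),
            "tuning_class": [s.tuning_class for s in neuron_specs],
            "behavior": [CLASS_TO_ENSEMBLE[s.tuning_class][0] for s in neuron_specs],
            "polarity": [CLASS_TO_ENSEMBLE[s.tuning_class][1] for s in neuron_specs],
        }
    )
    bundle = SessionBundle(
        traces=traces,
        trials=trials,
        behaviors=behaviors,
        rois=rois,
        frame_rate=config.frame_rate,
        extras={"ground_truth": ground_truth, "config": config},
    )
    return bundle.validate(), ground_truth


def default_retention(stay: float = 0.6, to_other: float = 0.3) -> dict[str, dict[str, float]]:
    """Retention matrix where tuned classes mostly stay or fall back to Other,
    never switching directly between poking- and reward-tuned classes."""
    rest = 1.0 - stay - to_other
    retention: dict[str, dict[str, float]] = {}
    within = {
        "Trigger-like": ("Attention-like", "Visual-stim"),
        "Attention-like": ("Trigger-like", "Visual-stim"),
        "Visual-stim": ("Trigger-like", "Attention-like"),
        "Reward-pursuing": ("Rewarded",),
        "Rewarded": ("Reward-pursuing",),
        "Poking-OFF": (),
        "Reward-OFF": (),
    }
    for cls, siblings in within.items():
        row = {c: 0.0 for c in TUNING_CLASSES}
        row[cls] = stay
        row["Other"] = to_other + (rest if not siblings else 0.0)
        for s in siblings:
            row[s] = rest / len(siblings)
        retention[cls] = row
    other_row = {c: 0.0 for c in TUNING_CLASSES}
    other_row["Other"] = 0.85
    other_row["Rewarded"] = 0.06
    other_row["Trigger-like"] = 0.03
    other_row["Attention-like"] = 0.03
    other_row["Reward-pursuing"] = 0.03
    retention["Other"] = other_row
    return retention


@dataclass(frozen=True)
class TrackedPairConfig:
    """Two-stage recording with partial neuron overlap.

    ``overlap_fraction`` defaults to the ~67% of neurons the cell-registration
    step typically matches across stages; ``retention`` gives, per stage-1
    tuning class, the probability distribution over stage-2 classes.
    """

    overlap_fraction: float = 0.67
    retention: dict[str, dict[str, float]] = field(default_factory=default_retention)
    n_new_neurons: int = 50
    stage2_seed_offset: int = 104729  # decorrelates the stage-2 session stream
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        for cls, row in self.retention.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"retention row for {cls!r} sums to {total}, expected 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"retention row for {cls!r} has negative probability")


def simulate_tracked_pair(
    config: TrackedPairConfig,
    stage1_truth: pd.DataFrame,
    session_config: SessionConfig,
    amplitude: float = 5.0,
) -> tuple[SessionBundle, pd.DataFrame, pd.DataFrame]:
    """Simulate the second recording stage of a tracked population.

    Parameters
    ----------
    stage1_truth : ground-truth table of the stage-1 session.
    session_config : task parameters for the stage-2 session (its ``seed`` is
        offset so the two stages have independent noise).

    Returns
    -------
    (stage2 bundle, stage2 ground truth, id map) where the id map has columns
    stage1_id, stage2_id and is one-to-one on its domain.
    """
    rng = np.random.default_rng(config.seed)
    n1 = len(stage1_truth)
    if n1 == 0:
        raise ValueError("stage-1 ground truth is empty")
    n_tracked = int(round(config.overlap_fraction * n1))
    tracked_ids = np.sort(rng.choice(n1, size=n_tracked, replace=False))

    classes = list(TUNING_CLASSES)
    stage2_specs: list[NeuronSpec] = []
    stage1_ids: list[int] = []
    class1 = stage1_truth.set_index("neuron_id")["tuning_class"]
    for sid in tracked_ids:
        row = config.retention[class1.loc[sid]]
        probs = np.array([row.get(c, 0.0) for c in classes])
        new_class = classes[rng.choice(len(classes), p=probs)]
        stage2_specs.append(NeuronSpec(tuning_class=new_class, response_amplitude=amplitude))
        stage1_ids.append(int(sid))
    other_row = config.retention.get("Other", {"Other": 1.0})
    probs = np.array([other_row.get(c, 0.0) for c in classes])
    for _ in range(config.n_new_neurons):
        new_class = classes[rng.choice(len(classes), p=probs)]
        stage2_specs.append(NeuronSpec(tuning_class=new_class, response_amplitude=amplitude))

    # shuffle stage-2 ordering so tracked neurons are not trivially the prefix
    order = rng.permutation(len(stage2_specs))
    stage2_specs = [stage2_specs[i] for i in order]
    position = {int(old): int(new) for new, old in enumerate(order)}
    idmap = pd.DataFrame(
        {
            "stage1_id": stage1_ids,
            "stage2_id": [position[i] for i in range(len(stage1_ids))],
        }
    )

    cfg2 = replace(session_config, seed=session_config.seed + config.stage2_seed_offset)
    bundle2, truth2 = simulate_session(cfg2, stage2_specs)
    bundle2.stage = "NSF_day5"
    return bundle2, truth2, idmap
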