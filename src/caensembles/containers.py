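"""Shared containers and vocabulary for session data.

Frame convention: frames are 0-based; trial-table columns hold onset frames
(inclusive).  Seconds are converted to frames by ``round(t * frame_rate)``
and windows are closed at both ends, onset frame included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEHAVIOR_POKING = "poking"
BEHAVIOR_REWARD = "reward"

OUTCOMES = ("correct", "incorrect", "omission", "licking_only")
REWARD_SIDES = ("left", "right")

#: columns every trial table must carry; -1 marks a frame that does not exist
#: for that trial (e.g. reward_frame on incorrect trials).
TRIAL_COLUMNS = (
    "trial_id",
    "poke_onset_frame",
    "choice_frame",
    "outcome",
    "reward_side",
    "reward_frame",
)

#: planted tuning class -> (behavior it is tuned to, ON/OFF polarity).
#: "Other" neurons carry no planted tuning.
CLASS_TO_ENSEMBLE = {
    "Trigger-like": (BEHAVIOR_POKING, "ON"),
    "Attention-like": (BEHAVIOR_POKING, "ON"),
    "Visual-stim": (BEHAVIOR_POKING, "ON"),
    "Reward-pursuing": (BEHAVIOR_REWARD, "ON"),
    "Rewarded": (BEHAVIOR_REWARD, "ON"),
    "Poking-OFF": (BEHAVIOR_POKING, "OFF"),
    "Reward-OFF": (BEHAVIOR_REWARD, "OFF"),
    "Other": (None, None),
}

TUNING_CLASSES = tuple(CLASS_TO_ENSEMBLE)


def seconds_to_frames(t: float, frame_rate: float) -> int:
    """Convert a time offset in seconds to a frame offset (round-half-even)."""
    return int(round(t * frame_rate))


@dataclass
class SessionBundle:
    """One recording session: traces, trials, behavior vectors, ROI map.

    Attributes
    ----------
    traces : (n_neurons, n_frames) array of nonnegative DF/F values.
    trials : trial table with :data:`TRIAL_COLUMNS`.
    behaviors : mapping from behavior name to a frame-wise 0/1 vector.
    rois : DataFrame with columns neuron_id, x_px, y_px.
    """

    traces: np.ndarray
    trials: pd.DataFrame
    behaviors: dict[str, np.ndarray]
    rois: pd.DataFrame
    frame_rate: float = 10.0
    pixel_size_um: float = 2.75
    session_id: str = "session"
    stage: str = "lowSF"
    extras: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[1])

    def validate(self) -> "SessionBundle":
        """Eagerly check cross-file invariants; raise ValueError with the offending location."""
        if self.traces.ndim != 2 or self.traces.size == 0:
            raise ValueError("traces must be a non-empty 2-D matrix (neurons x frames)")
        if not np.all(np.isfinite(self.traces)):
            bad = np.argwhere(~np.isfinite(self.traces))[0]
            raise ValueError(f"non-finite trace value at neuron {bad[0]}, frame {bad[1]}")
        n_frames = self.n_frames
        for name, vec in self.behaviors.items():
            vec = np.asarray(vec)
            if vec.shape != (n_frames,):
                raise ValueError(
                    f"behavior vector '{name}' has {vec.shape[0]} frames, traces have {n_frames}"
                )
            if not np.isin(vec, (0, 1)).all():
                raise ValueError(f"behavior vector '{name}' is not binary")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        bad_outcomes = set(self.trials["outcome"]) - set(OUTCOMES)
        if bad_outcomes:
            raise ValueError(
                f"unknown outcome tokens {sorted(bad_outcomes)}; valid tokens are {list(OUTCOMES)}"
            )
        for col in ("poke_onset_frame", "choice_frame", "reward_frame"):
            frames = self.trials[col].to_numpy()
            out = (frames >= n_frames) | ((frames < 0) & (frames != -1))
            if out.any():
                t = self.trials["trial_id"].to_numpy()[out][0]
                raise ValueError(f"trial {t}: {col} outside session bounds [0, {n_frames})")
        if len(self.rois) != self.n_neurons:
            raise ValueError(
                f"ROI map has {len(self.rois)} entries for {self.n_neurons} neurons"
            )
        return self
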