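"""Behaviorally tuned ON/OFF neuron identification.

The tuning statistic is the normalized inner product between a frame-wise
binary behavior vector B and a neuron's nonnegative calcium trace C,

    s(B, C) = 2 B.C / (|B|^2 + |C|^2),

bounded in [0, 1] on nonnegative inputs, equal to 1 iff B == C (AM-GM
equality) and 0 iff the vectors do not overlap.  Each neuron is compared
against its own chance distribution, obtained by shuffling the behavior
epochs (durations preserved, placed at random non-overlapping positions)
5000 times.  A neuron is ON if its observed similarity strictly exceeds the
99.17% quantile of its null, OFF if it is strictly below the 0.83% quantile,
and Other in between; ties go to Other.

Traces are min-max scaled to [0, 1] per neuron before the statistic so B and
C live on a common amplitude scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SessionBundle

__all__ = [
    "ClassifierConfig",
    "SimilarityResult",
    "similarity",
    "minmax_scale",
    "behavior_epochs",
    "shuffle_behavior",
    "null_distribution",
    "classify_neuron",
    "classify_population",
    "ensemble_members",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Permutation-null parameters for ON/OFF classification."""

    n_permutations: int = 5000
    q_low: float = 0.83  # percentile
    q_high: float = 99.17  # percentile
    null_method: str = "epoch"  # "epoch" shuffle or "circular" frame shift
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.q_low < self.q_high < 100:
            raise ValueError("quantiles must satisfy 0 < q_low < q_high < 100")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if self.null_method not in ("epoch", "circular"):
            raise ValueError(f"unknown null_method {self.null_method!r}")


@dataclass(frozen=True)
class SimilarityResult:
    observed: float
    null_quantile_low: float
    null_quantile_high: float
    label: str  # ON / OFF / Other


def similarity(b: np.ndarray, c: np.ndarray) -> float:
    """Calcium-behavior similarity 2 b.c / (|b|^2 + |c|^2).

    Both inputs must be nonnegative and of equal length; rejects the 0/0
    case where both vectors are identically zero.
    """
    b = np.asarray(b, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    if b.shape != c.shape:
        raise ValueError(f"length mismatch: behavior {b.shape[0]} vs trace {c.shape[0]}")
    if b.min(initial=0.0) < 0 or c.min(initial=0.0) < 0:
        raise ValueError("similarity is defined for nonnegative vectors")
    denom = b @ b + c @ c
    if denom == 0:
        raise ValueError("both vectors are all-zero (similarity undefined, 0/0)")
    return float(2.0 * (b @ c) / denom)


def minmax_scale(c: np.ndarray) -> np.ndarray:
    """Scale a trace to [0, 1] (constant traces map to zeros)."""
    c = np.asarray(c, dtype=float).ravel()
    lo, hi = c.min(), c.max()
    if hi == lo:
        return np.zeros_like(c)
    return (c - lo) / (hi - lo)


def behavior_epochs(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and durations of the maximal runs of 1s in a binary vector."""
    b = np.asarray(b).astype(np.int8).ravel()
    if not np.isin(b, (0, 1)).all():
        raise ValueError("behavior vector must be binary")
    edges = np.diff(np.concatenate(([0], b, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return starts, ends - starts


def _random_epoch_starts(
    durations: np.ndarray, n_frames: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_draws, k) start frames for epochs of the given durations, placed in
    random order at random non-overlapping positions (>= 1 frame apart so the
    epoch count is preserved)."""
    k = len(durations)
    slack = n_frames - int(durations.sum()) - (k - 1)
    if slack < 0:
        raise ValueError(
            f"epochs cannot fit: {durations.sum()} ON frames + {k - 1} gaps > {n_frames} frames"
        )
    if k == 0:
        empty = np.zeros((n_draws, 0), dtype=int)
        return empty, empty
    order = rng.random((n_draws, k)).argsort(axis=1)
    d = np.asarray(durations, dtype=int)[order]
    # cumulative left-gap totals: sorted draws over 0..slack
    p = np.sort(rng.integers(0, slack + 1, size=(n_draws, k)), axis=1)
    offsets = np.cumsum(d, axis=1) - d + np.arange(k)  # previous epochs + unit gaps
    return p + offsets, d


def shuffle_behavior(b: np.ndarray, rng: np.random.Generator | int = 0) -> np.ndarray:
    """One epoch-preserving shuffle of a binary behavior vector.

    The output has the same number of epochs with the same durations as the
    input, placed at random non-overlapping positions; the total ON-frame
    count is conserved.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    b = np.asarray(b).astype(np.int8).ravel()
    starts, durations = behavior_epochs(b)
    out = np.zeros_like(b)
    if len(starts) == 0:
        return out
    new_starts, d = _random_epoch_starts(durations, b.size, 1, rng)
    for s, dur in zip(new_starts[0], d[0]):
        out[s : s + dur] = 1
    return out


def _null_similarities(
    b: np.ndarray, c_scaled: np.ndarray, config: ClassifierConfig, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized null: for binary B, B.C is the sum of C over ON frames, so
    each shuffled similarity needs only k cumulative-sum lookups."""
    starts, durations = behavior_epochs(b)
    n = b.size
    denom = float(durations.sum()) + float(c_scaled @ c_scaled)
    if denom == 0:
        raise ValueError("both vectors are all-zero (similarity undefined, 0/0)")
    csum = np.concatenate(([0.0], np.cumsum(c_scaled)))
    if config.null_method == "circular":
        # sum of C over circularly shifted epochs, all shifts at once via FFT
        corr = np.fft.irfft(
            np.fft.rfft(c_scaled) * np.conj(np.fft.rfft(b.astype(float))), n
        )
        shifts = rng.integers(0, n, size=config.n_permutations)
        sums = corr[shifts]
    else:
        new_starts, d = _random_epoch_starts(durations, n, config.n_permutations, rng)
        sums = (csum[new_starts + d] - csum[new_starts]).sum(axis=1)
    return 2.0 * sums / denom


def null_distribution(
    b: np.ndarray, c: np.ndarray, config: ClassifierConfig
) -> np.ndarray:
    """Chance similarity distribution for one neuron (length n_permutations)."""
    b = np.asarray(b).astype(np.int8).ravel()
    c_scaled = minmax_scale(c)
    if b.shape != c_scaled.shape:
        raise ValueError(f"length mismatch: behavior {b.shape[0]} vs trace {c_scaled.shape[0]}")
    rng = np.random.default_rng(config.seed)
    return _null_similarities(b, c_scaled, config, rng)


def classify_neuron(
    b: np.ndarray, c: np.ndarray, config: ClassifierConfig | None = None
) -> SimilarityResult:
    """Label one neuron ON/OFF/Other for one behavior against its own null."""
    config = config or ClassifierConfig()
    b = np.asarray(b).astype(np.int8).ravel()
    c_scaled = minmax_scale(c)
    observed = similarity(b, c_scaled)
    rng = np.random.default_rng(config.seed)
    null = _null_similarities(b, c_scaled, config, rng)
    q_low, q_high = np.percentile(null, [config.q_low, config.q_high])
    if observed > q_high:
        label = "ON"
    elif observed < q_low:
        label = "OFF"
    else:
        label = "Other"
    return SimilarityResult(
        observed=observed,
        null_quantile_low=float(q_low),
        null_quantile_high=float(q_high),
        label=label,
    )


def classify_population(
    bundle: SessionBundle,
    behaviors: list[str] | None = None,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """ON/OFF/Other label for every neuron and every annotated behavior.

    Returns a DataFrame with columns neuron_id, behavior, observed_similarity,
    q_low_value, q_high_value, label.  Each (neuron, behavior) pair uses an
    independent permutation substream derived from the config seed, so the
    result is reproducible and order-independent.
    """
    config = config or ClassifierConfig()
    if behaviors is None:
        behaviors = list(bundle.behaviors)
    unknown = set(behaviors) - set(bundle.behaviors)
    if unknown:
        raise ValueError(f"behaviors {sorted(unknown)} are not annotated in this session")
    rows = []
    for b_idx, behavior in enumerate(behaviors):
        b = np.asarray(bundle.behaviors[behavior]).astype(np.int8)
        for n_idx in range(bundle.n_neurons):
            # independent, order-invariant substream per (behavior, neuron)
            rng = np.random.default_rng([config.seed, b_idx, n_idx])
            c_scaled = minmax_scale(bundle.traces[n_idx])
            observed = similarity(b, c_scaled)
            null = _null_similarities(b, c_scaled, config, rng)
            q_low, q_high = np.percentile(null, [config.q_low, config.q_high])
            if observed > q_high:
                label = "ON"
            elif observed < q_low:
                label = "OFF"
            else:
                label = "Other"
            rows.append((n_idx, behavior, observed, float(q_low), float(q_high), label))
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "behavior",
            "observed_similarity",
            "q_low_value",
            "q_high_value",
            "label",
        ],
    )


def ensemble_members(labels: pd.DataFrame, behavior: str, polarity: str = "ON") -> np.ndarray:
    """Neuron ids forming one ensemble (the ON or OFF set for one behavior)."""
    sel = (labels["behavior"] == behavior) & (labels["label"] == polarity)
    return labels.loc[sel, "neuron_id"].to_numpy()
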