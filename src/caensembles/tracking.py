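"""Cross-stage ensemble bookkeeping over registered (tracked) neurons.

The id map pairing stage-1 with stage-2 neurons is an input (produced by
image-based cell registration upstream, or by the synthetic generator); this
module computes overlap fractions, per-ensemble proportions among tracked
neurons, class-transformation matrices, and within-stage split-half label
stability.  Overlap uses the stage-1 population as denominator.  A neuron ON
for both behaviors is counted in both ensembles, so proportions need not sum
to one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import SessionBundle
from .ensembles import ClassifierConfig, classify_population

__all__ = [
    "validate_idmap",
    "overlap_fraction",
    "transformation_matrix",
    "ensemble_proportions",
    "composite_labels",
    "split_half_stability",
]

#: coarse per-neuron classes used for transformation matrices
COARSE_CLASSES = ("Poking-ON", "Reward-ON", "OFF", "Other")


def validate_idmap(idmap: pd.DataFrame) -> pd.DataFrame:
    for col in ("stage1_id", "stage2_id"):
        if col not in idmap.columns:
            raise ValueError(f"id map missing column {col!r}")
        if idmap[col].duplicated().any():
            dup = idmap[col][idmap[col].duplicated()].iloc[0]
            raise ValueError(f"id map is not one-to-one: {col}={dup} appears twice")
    return idmap


def overlap_fraction(idmap: pd.DataFrame, n_stage1: int) -> float:
    """Percentage of stage-1 neurons present at stage 2: 100 |map| / n_stage1."""
    if n_stage1 <= 0:
        raise ValueError("stage-1 population is empty")
    validate_idmap(idmap)
    if len(idmap) > n_stage1:
        raise ValueError(f"id map has {len(idmap)} pairs but only {n_stage1} stage-1 neurons")
    return 100.0 * len(idmap) / n_stage1


def composite_labels(labels: pd.DataFrame) -> pd.Series:
    """Collapse per-behavior ON/OFF/Other labels into one coarse class per
    neuron: Poking-ON, Reward-ON (ON for both behaviors counts toward each
    matrix margin via Poking-ON priority), OFF, or Other."""
    wide = labels.pivot(index="neuron_id", columns="behavior", values="label")
    def coarse(row) -> str:
        if (row == "ON").any():
            on_behaviors = row.index[row == "ON"]
            return "Poking-ON" if "poking" in on_behaviors else "Reward-ON"
        if (row == "OFF").any():
            return "OFF"
        return "Other"
    return wide.apply(coarse, axis=1)


def transformation_matrix(
    labels1: pd.Series, labels2: pd.Series, idmap: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts (and row-normalized proportions) of class transitions among
    tracked neurons: rows are stage-1 classes, columns stage-2 classes."""
    validate_idmap(idmap)
    c1, c2 = [], []
    for _, row in idmap.iterrows():
        for labels, nid, stage in ((labels1, row.stage1_id, 1), (labels2, row.stage2_id, 2)):
            if nid not in labels.index:
                raise ValueError(f"neuron {nid} (stage {stage}) has no class label")
        c1.append(labels1.loc[row.stage1_id])
        c2.append(labels2.loc[row.stage2_id])
    classes = sorted(set(c1) | set(c2))
    counts = pd.crosstab(
        pd.Categorical(c1, categories=classes),
        pd.Categorical(c2, categories=classes),
        dropna=False,
    )
    counts.index.name, counts.columns.name = "stage1", "stage2"
    row_sums = counts.sum(axis=1).replace(0, 1)
    proportions = counts.div(row_sums, axis=0)
    return counts, proportions


def ensemble_proportions(labels: pd.DataFrame, subset: np.ndarray) -> pd.DataFrame:
    """Fraction of ``subset`` neurons belonging to each (behavior, polarity)
    ensemble.  Fractions for distinct behaviors may overlap."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("subset of neurons is empty")
    known = set(labels["neuron_id"])
    missing = [int(n) for n in subset if n not in known]
    if missing:
        raise ValueError(f"subset neurons {missing[:5]} have no labels")
    rows = []
    for (behavior, polarity), grp in labels.groupby(["behavior", "label"]):
        if polarity not in ("ON", "OFF"):
            continue
        members = np.intersect1d(grp["neuron_id"].to_numpy(), subset)
        rows.append((behavior, polarity, len(members), len(members) / subset.size))
    return pd.DataFrame(rows, columns=["behavior", "polarity", "n_members", "fraction"])


def _slice_bundle(bundle: SessionBundle, f0: int, f1: int) -> SessionBundle:
    """Restrict a session to the frame range [f0, f1); trials outside are dropped."""
    trials = bundle.trials.copy()
    anchor = trials[["poke_onset_frame", "choice_frame"]].max(axis=1)
    keep = (anchor >= f0) & (anchor < f1)
    trials = trials.loc[keep].copy()
    for col in ("poke_onset_frame", "choice_frame", "reward_frame"):
        trials[col] = np.where(trials[col] >= 0, trials[col] - f0, -1)
    return SessionBundle(
        traces=bundle.traces[:, f0:f1],
        trials=trials,
        behaviors={k: np.asarray(v)[f0:f1] for k, v in bundle.behaviors.items()},
        rois=bundle.rois,
        frame_rate=bundle.frame_rate,
        pixel_size_um=bundle.pixel_size_um,
        session_id=bundle.session_id,
        stage=bundle.stage,
        extras=dict(bundle.extras),
    )


def split_half_stability(
    bundle: SessionBundle,
    config: ClassifierConfig | None = None,
    min_trials: int = 3,
) -> dict:
    """Re-identify ON/OFF neurons independently on the two halves of a session
    and report label consistency.

    Returns a dict with the per-(neuron, behavior) label table, the fraction
    assigned the same label in both halves, and the fraction that is either
    stable or switches only between an ensemble and Other (the lenient
    criterion under which stable populations score near 1).
    """
    config = config or ClassifierConfig()
    mid = bundle.n_frames // 2
    halves = []
    for f0, f1 in ((0, mid), (mid, bundle.n_frames)):
        half = _slice_bundle(bundle, f0, f1)
        if len(half.trials) < min_trials:
            raise ValueError(
                f"half [{f0}, {f1}) has only {len(half.trials)} trials (need >= {min_trials})"
            )
        halves.append(classify_population(half, config=config))
    merged = halves[0].merge(
        halves[1], on=["neuron_id", "behavior"], suffixes=("_h1", "_h2")
    )
    same = merged["label_h1"] == merged["label_h2"]
    via_other = same | (merged["label_h1"] == "Other") | (merged["label_h2"] == "Other")
    return {
        "labels": merged[["neuron_id", "behavior", "label_h1", "label_h2"]],
        "fraction_same": float(same.mean()),
        "fraction_same_or_via_other": float(via_other.mean()),
    }
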