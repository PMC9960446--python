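"""Readers and writers for the TSV/HDF5 session interchange formats.

Canonical layout of a session directory:

    traces.tsv     row = neuron, header = frame index (or traces.h5, dataset "dff")
    trials.tsv     trial_id, poke_onset_frame, choice_frame, outcome, reward_side, reward_frame
    behaviors.tsv  one binary column per annotated behavior
    rois.tsv       neuron_id, x_px, y_px
    meta.yaml      frame_rate, pixel_size_um, session_id, stage
    ground_truth.tsv (optional)  neuron_id, tuning_class

Frames are 0-based; -1 marks a frame that does not exist for a trial.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import SessionBundle

__all__ = ["write_session", "read_session", "write_labels", "read_labels"]


def write_session(
    bundle: SessionBundle, directory: str | Path, traces_format: str = "tsv"
) -> Path:
    """Write a session bundle to a directory (TSV canonical, HDF5 optional for traces)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if traces_format == "h5":
        with h5py.File(directory / "traces.h5", "w") as f:
            f.create_dataset("dff", data=bundle.traces)
    elif traces_format == "tsv":
        pd.DataFrame(
            bundle.traces, columns=[str(i) for i in range(bundle.n_frames)]
        ).to_csv(directory / "traces.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown traces format {traces_format!r}")
    bundle.trials.to_csv(directory / "trials.tsv", sep="\t", index=False)
    pd.DataFrame({k: np.asarray(v, dtype=int) for k, v in bundle.behaviors.items()}).to_csv(
        directory / "behaviors.tsv", sep="\t", index=False
    )
    bundle.rois.to_csv(directory / "rois.tsv", sep="\t", index=False)
    meta = {
        "schema_version": 1,
        "frame_rate": float(bundle.frame_rate),
        "pixel_size_um": float(bundle.pixel_size_um),
        "session_id": bundle.session_id,
        "stage": bundle.stage,
    }
    (directory / "meta.yaml").write_text(yaml.safe_dump(meta))
    truth = bundle.extras.get("ground_truth")
    if truth is not None:
        truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    return directory


def read_session(directory: str | Path) -> SessionBundle:
    """Read and eagerly validate a session directory written by :func:`write_session`."""
    directory = Path(directory)
    h5_path = directory / "traces.h5"
    tsv_path = directory / "traces.tsv"
    if h5_path.exists():
        with h5py.File(h5_path, "r") as f:
            traces = np.asarray(f["dff"])
    elif tsv_path.exists():
        traces = pd.read_csv(tsv_path, sep="\t").to_numpy(dtype=float)
    else:
        raise FileNotFoundError(f"no traces.tsv or traces.h5 in {directory}")
    trials = pd.read_csv(directory / "trials.tsv", sep="\t")
    behaviors_df = pd.read_csv(directory / "behaviors.tsv", sep="\t")
    behaviors = {c: behaviors_df[c].to_numpy(dtype=np.int8) for c in behaviors_df.columns}
    rois = pd.read_csv(directory / "rois.tsv", sep="\t")
    meta = yaml.safe_load((directory / "meta.yaml").read_text())
    extras = {}
    truth_path = directory / "ground_truth.tsv"
    if truth_path.exists():
        extras["ground_truth"] = pd.read_csv(truth_path, sep="\t")
    bundle = SessionBundle(
        traces=traces,
        trials=trials,
        behaviors=behaviors,
        rois=rois,
        frame_rate=float(meta["frame_rate"]),
        pixel_size_um=float(meta.get("pixel_size_um", 2.75)),
        session_id=str(meta.get("session_id", directory.name)),
        stage=str(meta.get("stage", "lowSF")),
        extras=extras,
    )
    return bundle.validate()


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels.to_csv(path, sep="\t", index=False)
    return path


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
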