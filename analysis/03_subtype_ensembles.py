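#!/usr/bin/env python
"""Subdivide the ON ensembles and run the outcome-history analyses.

Assigns Trigger-like / Attention-like / Visual-stim subtypes to Poking-ON
neurons and Reward-pursuing / Rewarded subtypes to Reward-ON neurons, then
asks (a) whether each subensemble responds more strongly after correct than
after incorrect previous trials (whole session and split halves) and
(b) whether individual Rewarded neurons prefer the left or right port.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from caensembles.containers import BEHAVIOR_REWARD
from caensembles.io import read_session, read_labels, write_labels
from caensembles.preprocess import align_to_onsets, mean_window_response, zscore_traces
from caensembles.subtypes import (
    SubtypeConfig,
    previous_outcome_modulation,
    port_preference,
    subtype_population,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--sessions", type=Path, default=Path("results/sessions"))
    parser.add_argument("--labels", type=Path, default=Path("results/labels_stage1.tsv"))
    parser.add_argument("--stage", default="stage1")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    bundle = read_session(args.sessions / args.stage)
    labels = read_labels(args.labels)
    subtypes = subtype_population(bundle, labels, SubtypeConfig(seed=args.seed))
    write_labels(subtypes, args.out / f"subtypes_{args.stage}.tsv")
    print("subtype counts:")
    print(subtypes.groupby(["behavior", "subtype"]).size().to_string())

    # per-trial poking-window responses for the outcome-history comparison
    ztraces = zscore_traces(bundle.traces)
    trials = bundle.trials.reset_index(drop=True)
    cfg = bundle.extras.get("config")
    window = cfg.poking_window if cfg is not None else (-0.5, 1.5)
    pokes = trials.poke_onset_frame.to_numpy()
    rows = []
    for behavior, group in subtypes.groupby("behavior"):
        onset_col = "poke_onset_frame" if behavior != BEHAVIOR_REWARD else "choice_frame"
        onsets = trials[onset_col].to_numpy()
        usable = onsets >= 0
        peri = align_to_onsets(ztraces, onsets[usable], window, bundle.frame_rate)
        resp = mean_window_response(peri, window)
        for subtype, sub in group.groupby("subtype"):
            if subtype == "Unclassified":
                continue
            ens = resp[sub.neuron_id.to_numpy()].mean(axis=0)
            per_trial = np.full(len(trials), np.nan)
            per_trial[np.flatnonzero(usable)[: ens.size]] = ens
            outcome_list = list(trials.outcome)
            filled = np.nan_to_num(per_trial)
            res = previous_outcome_modulation(filled, outcome_list, seed=args.seed)
            if isinstance(res, str):
                rows.append((subtype, np.nan, np.nan, np.nan, res))
            else:
                rows.append(
                    (
                        subtype,
                        res.mean_after_correct,
                        res.mean_after_incorrect,
                        res.p_value,
                        "significant" if res.p_value < 0.05 else "n.s.",
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=["subtype", "after_correct", "after_incorrect", "p", "verdict"],
    )
    write_labels(table, args.out / f"previous_outcome_{args.stage}.tsv")
    print("\nprevious-outcome modulation (mean windowed z):")
    print(table.round(3).to_string(index=False))

    # port preference of Rewarded neurons on correct trials
    correct = trials[trials.outcome == "correct"]
    peri = align_to_onsets(
        ztraces,
        correct.reward_frame.to_numpy(),
        cfg.reward_window if cfg is not None else (-0.5, 3.5),
        bundle.frame_rate,
    )
    resp = mean_window_response(peri, cfg.reward_window if cfg is not None else (-0.5, 3.5))
    kept_sides = correct.reward_side.to_numpy()[: resp.shape[1]]
    rewarded = subtypes[subtypes.subtype.eq("Rewarded")].neuron_id.to_numpy()
    prefs = [
        port_preference(resp[nid], kept_sides, seed=args.seed) for nid in rewarded
    ]
    counts = pd.Series(prefs).value_counts()
    print("\nport preference of Rewarded neurons:")
    print(counts.to_string() if len(counts) else "  (no Rewarded neurons)")


if __name__ == "__main__":
    main()
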