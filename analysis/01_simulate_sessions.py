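#!/usr/bin/env python
"""Simulate the two-stage study dataset every later analysis consumes.

Stage 1 emulates the low-spatial-frequency task-execution recording; stage 2
emulates the near-threshold (NSF) training recording with ~67% of neurons
tracked across stages and class turnover drawn from a retention matrix that
keeps most tuned neurons in class, lets some fall back to untuned, and never
switches poking-tuned neurons directly to reward-tuned classes.

Writes results/sessions/stage1 and stage2 plus the id map.
"""

import argparse
from pathlib import Path

from caensembles.io import write_session
from caensembles.pipeline import specs_from_counts
from caensembles.synthetic import (
    SessionConfig,
    TrackedPairConfig,
    simulate_session,
    simulate_tracked_pair,
)

STAGE1_COUNTS = {
    "Trigger-like": 10,
    "Attention-like": 8,
    "Visual-stim": 2,
    "Reward-pursuing": 8,
    "Rewarded": 12,
    "Poking-OFF": 8,
    "Reward-OFF": 8,
    "Other": 94,
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/sessions"))
    args = parser.parse_args()

    config = SessionConfig(n_trials=100, seed=args.seed)
    bundle1, truth1 = simulate_session(config, specs_from_counts(STAGE1_COUNTS))
    bundle1.session_id, bundle1.stage = "stage1", "lowSF"
    write_session(bundle1, args.out / "stage1")

    pair = TrackedPairConfig(overlap_fraction=0.67, n_new_neurons=25, seed=args.seed + 1)
    bundle2, truth2, idmap = simulate_tracked_pair(pair, truth1, config)
    bundle2.session_id = "stage2"
    write_session(bundle2, args.out / "stage2")
    idmap.to_csv(args.out / "idmap.tsv", sep="\t", index=False)

    print(f"stage 1: {bundle1.n_neurons} neurons, {bundle1.n_frames} frames, "
          f"{len(bundle1.trials)} trials")
    print(f"stage 2: {bundle2.n_neurons} neurons, {bundle2.n_frames} frames")
    print(f"tracked: {len(idmap)}/{bundle1.n_neurons} "
          f"({100 * len(idmap) / bundle1.n_neurons:.1f}%) -> {args.out}")


if __name__ == "__main__":
    main()
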