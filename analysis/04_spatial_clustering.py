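#!/usr/bin/env python
"""Are the identified ensembles spatially clustered or scattered?

Computes global Moran's I (inverse-squared-distance weights) on the ROI
centroid map for each ensemble's membership indicator, with a 999-label-
permutation p-value and the analytic randomization z.  Under scattered
organization (the expected outcome on these synthetic maps, whose ROI
positions are drawn independently of tuning) p > 0.05 throughout.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from caensembles.containers import BEHAVIOR_POKING, BEHAVIOR_REWARD
from caensembles.ensembles import ensemble_members
from caensembles.io import read_labels, read_session, write_labels
from caensembles.spatial import morans_test


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--sessions", type=Path, default=Path("results/sessions"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = []
    for stage in ("stage1", "stage2"):
        bundle = read_session(args.sessions / stage)
        labels = read_labels(args.out / f"labels_{stage}.tsv")
        coords = bundle.rois[["x_px", "y_px"]].to_numpy()
        for behavior in (BEHAVIOR_POKING, BEHAVIOR_REWARD):
            for polarity in ("ON", "OFF"):
                members = ensemble_members(labels, behavior, polarity)
                if members.size in (0, bundle.n_neurons):
                    continue
                x = np.zeros(bundle.n_neurons)
                x[members] = 1.0
                res = morans_test(x, coords, n_perm=999, seed=args.seed)
                rows.append(
                    (stage, behavior, polarity, res.n_members, res.i,
                     res.p_perm, res.z_analytic)
                )
    report = pd.DataFrame(
        rows,
        columns=["stage", "behavior", "ensemble", "N_members", "I", "p_perm", "z_analytic"],
    )
    write_labels(report, args.out / "moran_report.tsv")
    print(report.round(4).to_string(index=False))
    n_clustered = int((report.p_perm < 0.05).sum())
    print(f"\n{n_clustered}/{len(report)} ensembles reach p < 0.05 "
          f"(scattered organization expected on these maps)")


if __name__ == "__main__":
    main()
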