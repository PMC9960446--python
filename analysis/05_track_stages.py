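#!/usr/bin/env python
"""Cross-stage ensemble dynamics over the tracked neurons.

Reports the tracked overlap percentage, each ensemble's share of the tracked
population at both stages, the class-transformation matrix between stages,
and the within-stage split-half stability of the labels.
"""

import argparse
from pathlib import Path

import pandas as pd

from caensembles.ensembles import ClassifierConfig
from caensembles.io import read_labels, read_session
from caensembles.tracking import (
    composite_labels,
    ensemble_proportions,
    overlap_fraction,
    split_half_stability,
    transformation_matrix,
    validate_idmap,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--sessions", type=Path, default=Path("results/sessions"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n-permutations", type=int, default=1000)
    args = parser.parse_args()

    idmap = validate_idmap(pd.read_csv(args.sessions / "idmap.tsv", sep="\t"))
    bundle1 = read_session(args.sessions / "stage1")
    labels1 = read_labels(args.out / "labels_stage1.tsv")
    labels2 = read_labels(args.out / "labels_stage2.tsv")

    pct = overlap_fraction(idmap, bundle1.n_neurons)
    print(f"tracked neurons: {len(idmap)}/{bundle1.n_neurons} ({pct:.1f}%)")

    print("\nensemble share of the tracked population "
          "(a dual-ON neuron counts in both, so shares need not sum to 1):")
    for stage, labels, ids in (
        ("stage1", labels1, idmap.stage1_id.to_numpy()),
        ("stage2", labels2, idmap.stage2_id.to_numpy()),
    ):
        props = ensemble_proportions(labels, ids)
        for r in props.itertuples():
            print(f"  {stage} {r.behavior:7s} {r.polarity:3s}: "
                  f"{r.n_members:3d} ({r.fraction:.1%})")

    coarse1, coarse2 = composite_labels(labels1), composite_labels(labels2)
    counts, props = transformation_matrix(coarse1, coarse2, idmap)
    counts.to_csv(args.out / "transformation_counts.tsv", sep="\t")
    props.round(4).to_csv(args.out / "transformation_proportions.tsv", sep="\t")
    print("\nclass transformation (stage1 rows -> stage2 columns):")
    print(counts.to_string())
    via_other = counts.copy()
    stable = sum(
        counts.loc[c, c2]
        for c in counts.index
        for c2 in counts.columns
        if c == c2 or "Other" in (c, c2)
    )
    print(f"stable or switching via Other: {stable}/{counts.values.sum()} "
          f"({stable / counts.values.sum():.1%})")

    res = split_half_stability(
        bundle1, ClassifierConfig(n_permutations=args.n_permutations, seed=args.seed)
    )
    print(f"\nsplit-half stability (stage1): same label {res['fraction_same']:.1%}, "
          f"same or via Other {res['fraction_same_or_via_other']:.1%}")


if __name__ == "__main__":
    main()
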