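"""Frame-wise behavior decoding from population z-scored traces.

A linear classifier trained by stochastic gradient descent (hinge loss)
predicts, for each imaging frame, whether the behavior occurred.  Tenfold
cross-validation: frames are randomly divided into 10 equal subsets, nine
train the model and the held-out subset is scored; the mean per-fold
balanced accuracy (mean of the two class recalls; 0.5 = chance, 1 = perfect)
is reported.

Five dataset configurations mirror the shuffle-control design:
ALL (every neuron), ON+OFF, ON+rOFF, rON+OFF and rON+rOFF, where an "r"
prefix means each of those neurons' traces is independently frame-shuffled,
destroying its temporal relation to behavior while preserving its value
distribution.  A size-balanced variant subsamples the ON ensemble to the OFF
ensemble's size over repeated draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold

from .containers import SessionBundle
from .ensembles import ensemble_members
from .preprocess import zscore_traces

__all__ = [
    "CONFIGURATIONS",
    "DecodeConfig",
    "DecodeResult",
    "build_design",
    "tenfold_balanced_accuracy",
    "decode_all_configurations",
]

CONFIGURATIONS = ("ALL", "ON+OFF", "ON+rOFF", "rON+OFF", "rON+rOFF")


@dataclass(frozen=True)
class DecodeConfig:
    configuration: str = "ALL"
    n_folds: int = 10
    seed: int = 0
    balance_sizes: bool = False
    n_balance_repeats: int = 10
    split: str = "random"  # frame-wise random folds, or "blocks" (contiguous)

    def __post_init__(self):
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(
                f"unknown configuration {self.configuration!r}; valid: {list(CONFIGURATIONS)}"
            )
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.split not in ("random", "blocks"):
            raise ValueError(f"unknown split {self.split!r}")


@dataclass(frozen=True)
class DecodeResult:
    behavior: str
    configuration: str
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float


def _shuffle_columns(design: np.ndarray, cols: np.ndarray, rng: np.random.Generator) -> None:
    for c in cols:
        design[:, c] = design[rng.permutation(design.shape[0]), c]


def build_design(
    ztraces: np.ndarray,
    on_ids: np.ndarray,
    off_ids: np.ndarray,
    configuration: str,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Frames x neurons design matrix for one configuration.

    Shuffled ("r") neurons are frame-permuted independently per neuron;
    unshuffled columns are identical to the input traces.
    """
    if configuration not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration {configuration!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ztraces = np.asarray(ztraces, dtype=float)
    if configuration == "ALL":
        return ztraces.T.copy()
    on_ids = np.asarray(on_ids, dtype=int)
    off_ids = np.asarray(off_ids, dtype=int)
    if on_ids.size == 0 and off_ids.size == 0:
        raise ValueError(f"configuration {configuration!r} needs non-empty ON or OFF sets")
    design = ztraces[np.concatenate([on_ids, off_ids])].T.copy()
    on_cols = np.arange(on_ids.size)
    off_cols = np.arange(on_ids.size, on_ids.size + off_ids.size)
    if configuration in ("rON+OFF", "rON+rOFF"):
        _shuffle_columns(design, on_cols, rng)
    if configuration in ("ON+rOFF", "rON+rOFF"):
        _shuffle_columns(design, off_cols, rng)
    return design


def tenfold_balanced_accuracy(
    design: np.ndarray,
    target: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    split: str = "random",
    behavior: str = "",
    configuration: str = "",
) -> DecodeResult:
    """Cross-validated balanced accuracy of the linear SGD decoder."""
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] == 1 and design.shape[1] > 1:
        design = design.T
    target = np.asarray(target).astype(int).ravel()
    if design.shape[0] != target.size:
        raise ValueError(
            f"design has {design.shape[0]} frames, target has {target.size}"
        )
    if len(np.unique(target)) < 2:
        raise ValueError("target contains a single class; decoding undefined")
    if split == "random":
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        kf = KFold(n_splits=n_folds, shuffle=False)
    accuracies = []
    for fold, (train, test) in enumerate(kf.split(design)):
        if len(np.unique(target[train])) < 2:
            raise ValueError(f"fold {fold}: training frames contain a single class")
        clf = SGDClassifier(loss="hinge", random_state=seed + fold, tol=1e-3)
        clf.fit(design[train], target[train])
        pred = clf.predict(design[test])
        if len(np.unique(target[test])) < 2:
            # degenerate held-out fold: score plain accuracy of the present class
            accuracies.append(float((pred == target[test]).mean()))
        else:
            accuracies.append(float(balanced_accuracy_score(target[test], pred)))
    return DecodeResult(
        behavior=behavior,
        configuration=configuration,
        fold_accuracies=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
    )


def decode_all_configurations(
    bundle: SessionBundle,
    labels: pd.DataFrame,
    behaviors: list[str] | None = None,
    config: DecodeConfig | None = None,
    configurations=CONFIGURATIONS,
) -> pd.DataFrame:
    """Decode every behavior under every dataset configuration.

    With ``config.balance_sizes`` the ON ensemble is subsampled to the OFF
    ensemble's size ``n_balance_repeats`` times and the mean accuracy over
    draws is reported (identical to the unbalanced run when |ON| <= |OFF|).
    """
    config = config or DecodeConfig()
    if behaviors is None:
        behaviors = list(bundle.behaviors)
    ztraces = zscore_traces(bundle.traces)
    rows = []
    for behavior in behaviors:
        target = np.asarray(bundle.behaviors[behavior]).astype(int)
        on_ids = ensemble_members(labels, behavior, "ON")
        off_ids = ensemble_members(labels, behavior, "OFF")
        for configuration in configurations:
            rng = np.random.default_rng([config.seed, 7, CONFIGURATIONS.index(configuration)])
            if config.balance_sizes and configuration != "ALL" and on_ids.size > off_ids.size > 0:
                means, folds = [], None
                for _ in range(config.n_balance_repeats):
                    sub_on = rng.choice(on_ids, size=off_ids.size, replace=False)
                    design = build_design(ztraces, sub_on, off_ids, configuration, rng)
                    res = tenfold_balanced_accuracy(
                        design, target, config.n_folds, config.seed, config.split,
                        behavior, configuration,
                    )
                    means.append(res.mean_accuracy)
                    folds = res.fold_accuracies
                rows.append((behavior, configuration, folds, float(np.mean(means))))
            else:
                design = build_design(ztraces, on_ids, off_ids, configuration, rng)
                res = tenfold_balanced_accuracy(
                    design, target, config.n_folds, config.seed, config.split,
                    behavior, configuration,
                )
                rows.append((behavior, configuration, res.fold_accuracies, res.mean_accuracy))
    return pd.DataFrame(
        rows, columns=["behavior", "configuration", "fold_accuracies", "mean_accuracy"]
    )
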