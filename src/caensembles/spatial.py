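"""Global Moran's I for the spatial scatter of ensemble membership.

Membership is a 0/1 indicator per neuron over ROI centroids; spatial weights
are inverse squared pairwise distances with zero diagonal,

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.

I typically ranges from -1 (dissimilar neighbors) through 0 (random scatter)
to +1 (clustered similars); under random labeling E[I] = -1/(N-1).
Significance is assessed by a label-permutation test (default) and by the
analytic z-score under the randomization assumption.  I is invariant to
translation, rotation and uniform rescaling of the coordinates, so pixel
units and micrometers give the same value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["morans_i", "morans_test", "MoranResult"]


def _weights(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 neurons with 2-D coordinates")
    d = squareform(pdist(coords))
    off = ~np.eye(len(coords), dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValueError(f"coincident ROI centroids (neurons {i} and {j}): weights diverge")
    with np.errstate(divide="ignore"):
        w = 1.0 / d**2
    np.fill_diagonal(w, 0.0)
    return w


def _check_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if np.all(x == x[0]):
        raise ValueError("membership indicator is constant: Moran's I undefined (zero variance)")
    return x


def morans_i(x: np.ndarray, coords: np.ndarray) -> float:
    """Global Moran's I of indicator ``x`` over ROI centroids ``coords``."""
    x = _check_x(x)
    w = _weights(coords)
    if len(x) != len(w):
        raise ValueError(f"{len(x)} labels for {len(w)} coordinates")
    n = len(x)
    xc = x - x.mean()
    return float(n / w.sum() * (xc @ w @ xc) / (xc @ xc))


@dataclass(frozen=True)
class MoranResult:
    i: float
    expected: float  # -1/(N-1) under random labeling
    p_perm: float  # two-sided permutation p-value
    z_analytic: float  # randomization-assumption z-score
    n: int
    n_members: int


def morans_test(
    x: np.ndarray,
    coords: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> MoranResult:
    """Moran's I with permutation and analytic significance.

    The permutation p is the two-sided rank of the observed I among I values
    recomputed on random relabelings (the distance weights stay fixed, so only
    the cross-product term changes).  The analytic z uses the standard
    randomization moments with E[I] = -1/(N-1).
    """
    x = _check_x(x)
    w = _weights(coords)
    n = len(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xc = x - x.mean()
    den = xc @ xc
    w_sum = w.sum()
    observed = float(n / w_sum * (xc @ w @ xc) / den)
    expected = -1.0 / (n - 1)

    perm_i = np.empty(n_perm)
    for p in range(n_perm):
        xp = xc[rng.permutation(n)]  # variance term is permutation-invariant
        perm_i[p] = n / w_sum * (xp @ w @ xp) / den
    exceed = np.abs(perm_i - expected) >= np.abs(observed - expected) - 1e-15
    p_perm = (1.0 + int(exceed.sum())) / (n_perm + 1.0)

    # randomization variance (Cliff & Ord moments)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    b2 = n * (xc**4).sum() / den**2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * w_sum**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * w_sum**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * w_sum**2) - expected**2
    z = (observed - expected) / np.sqrt(var) if var > 0 else np.nan

    return MoranResult(
        i=observed,
        expected=expected,
        p_perm=float(p_perm),
        z_analytic=float(z),
        n=n,
        n_members=int((x == x.max()).sum()) if set(np.unique(x)) <= {0.0, 1.0} else -1,
    )
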