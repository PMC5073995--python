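"""First-stage blind voxel selection: normality screening and Information Gain.

Information Gain of a voxel is the reduction in class entropy achieved by
the best supervised discretization of its values:

    IG(v) = H(class) - sum_bins (n_bin / N) * H(class | bin)

with bins found by recursive binary splitting of the sorted values, each
split accepted only if it passes the Fayyad-Irani minimum-description-length
(MDL) stopping criterion.  If no split is accepted the voxel carries no
usable class information and IG(v) = 0; voxel selection keeps exactly the
voxels with IG(v) > 0.  The MDL stop is what makes the filter sparse: on
noise features the best cut's gain almost never pays for the cost of
encoding the partition, so the vast majority of voxels receive IG = 0.

IG depends only on the ordering of the values (cut points fall between
distinct values), so it is invariant under strictly monotone transforms.
Logarithms are base 2 (bits) and 0*log(0) := 0.

The Lilliefors normality screen is descriptive only: it reports which
fraction of voxels look Gaussian within each class (the motivation for
preferring a non-parametric filter) and never gates the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.diagnostic import lilliefors

from .volume_io import SubjectMatrix

__all__ = ["IgResult", "information_gain", "ig_filter", "normality_screen"]


@dataclass
class IgResult:
    """Per-voxel information gain (bits) and the surviving column indices."""

    ig_bits: np.ndarray
    selected: np.ndarray
    class_priors: tuple[float, float]


def _vent(o: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Element-wise binary entropy (bits) of class counts; 0*log0 = 0."""
    tot = np.maximum(o + z, 1)
    p1 = o / tot
    p2 = z / tot
    t1 = np.where(p1 > 0, -p1 * np.log2(np.where(p1 > 0, p1, 1.0)), 0.0)
    t2 = np.where(p2 > 0, -p2 * np.log2(np.where(p2 > 0, p2, 1.0)), 0.0)
    return t1 + t2


def _entropy2(n1: float, n2: float) -> float:
    """Binary entropy in bits of class counts (n1, n2); 0*log0 = 0."""
    n = n1 + n2
    if n == 0 or n1 == 0 or n2 == 0:
        return 0.0
    p1 = n1 / n
    p2 = n2 / n
    return float(-p1 * np.log2(p1) - p2 * np.log2(p2))


def _segment_ig(y: np.ndarray, cuts: np.ndarray, lo: int, hi: int) -> float:
    """Total information gain of accepted MDL splits on y[lo:hi] (y sorted by value).

    ``cuts`` are the admissible cut positions for the whole feature
    (indices i such that a split may fall between i-1 and i, i.e. between
    distinct values).  Returns H(segment) - weighted entropy of final bins,
    restricted to the segment, scaled by the segment's share is handled by
    the caller; here the value returned is the drop in entropy for the
    segment itself (already a weighted, additive quantity across the
    recursion when multiplied by segment size).
    """
    # cumulative class-1 counts over the sorted labels, for O(1) range counts
    csum = np.concatenate([[0], np.cumsum(y)])

    def ent_range(a: int, b: int) -> float:
        ones = csum[b] - csum[a]
        return _entropy2(ones, (b - a) - ones)

    def recurse(a: int, b: int) -> float:
        """Entropy drop (bits, weighted by in-segment fraction) for y[a:b]."""
        n = b - a
        if n < 2:
            return 0.0
        cand = cuts[(cuts > a) & (cuts < b)]
        if cand.size == 0:
            return 0.0
        ent_s = ent_range(a, b)
        if ent_s == 0.0:
            return 0.0
        n_left = cand - a
        ones_left = csum[cand] - csum[a]
        ones_all = csum[b] - csum[a]
        zeros_left = n_left - ones_left
        ones_right = ones_all - ones_left
        zeros_right = (n - n_left) - ones_right

        ent_l = _vent(ones_left, zeros_left)
        ent_r = _vent(ones_right, zeros_right)
        gain = ent_s - (n_left / n) * ent_l - ((n - n_left) / n) * ent_r
        best = int(np.argmax(gain))  # leftmost cut on ties
        best_gain = float(gain[best])

        # Fayyad-Irani MDL acceptance
        k = 2 if 0 < ones_all < n else 1
        k1 = 2 if 0 < ones_left[best] < n_left[best] else 1
        k2 = 2 if 0 < ones_right[best] < (n - n_left[best]) else 1
        delta = np.log2(3.0**k - 2.0) - (
            k * ent_s - k1 * float(ent_l[best]) - k2 * float(ent_r[best])
        )
        if best_gain <= (np.log2(n - 1.0) + delta) / n:
            return 0.0
        c = int(cand[best])
        # weighted, additive decomposition of the final-bin entropy drop
        return (
            best_gain
            + (c - a) / n * recurse(a, c)
            + (b - c) / n * recurse(c, b)
        )

    return recurse(lo, hi)


def information_gain(values: np.ndarray, labels: np.ndarray) -> float:
    """Information gain (bits) of one feature for a two-class labeling.

    Bins come from recursive binary splits on the sorted values with the
    MDL stopping rule; tied values always share a bin.  Returns a value in
    [0, H(class)]; 0 when no split is accepted.  Both classes must be
    present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    y = (labels == classes[1]).astype(np.int64)
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = y[order]
    cuts = np.flatnonzero(v[1:] != v[:-1]) + 1  # splits only between distinct values
    return _segment_ig(y, cuts, 0, len(v))


def ig_filter(m: SubjectMatrix) -> IgResult:
    """Information gain per column; survivors are the columns with IG > 0."""
    labels = np.asarray(m.labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    y = (labels == classes[1]).astype(np.int64)
    p2 = y.mean()
    priors = (float(1 - p2), float(p2))

    n_vox = m.n_voxels
    n = m.n_subjects
    ig = np.zeros(n_vox, dtype=float)

    # Vectorized first-level screen: for every column at once, find the best
    # admissible cut and apply the MDL acceptance test.  Columns that reject
    # the first split (the vast majority on noise) have IG = 0 by
    # construction; only accepted columns need the full recursion.
    order = np.argsort(m.values, axis=0, kind="stable")
    v_sorted = np.take_along_axis(m.values, order, axis=0)
    y_sorted = y[order]
    csum = np.vstack([np.zeros(n_vox, dtype=np.int64), np.cumsum(y_sorted, axis=0)])
    ones_all = csum[n].astype(float)
    ent_s = _vent(ones_all, n - ones_all)

    n_left = np.arange(1, n, dtype=float)[:, None]
    ones_left = csum[1:n].astype(float)
    zeros_left = n_left - ones_left
    ones_right = ones_all[None, :] - ones_left
    zeros_right = (n - n_left) - ones_right
    ent_l = _vent(ones_left, zeros_left)
    ent_r = _vent(ones_right, zeros_right)
    gain = ent_s[None, :] - (n_left / n) * ent_l - ((n - n_left) / n) * ent_r
    admissible = v_sorted[1:] != v_sorted[:-1]
    gain = np.where(admissible, gain, -1.0)

    best = np.argmax(gain, axis=0)
    cols = np.arange(n_vox)
    best_gain = gain[best, cols]
    k = np.where((ones_all > 0) & (ones_all < n), 2, 1)
    bl_ones, bl_n = ones_left[best, cols], n_left[best, 0]
    k1 = np.where((bl_ones > 0) & (bl_ones < bl_n), 2, 1)
    br_ones, br_n = ones_right[best, cols], n - n_left[best, 0]
    k2 = np.where((br_ones > 0) & (br_ones < br_n), 2, 1)
    delta = np.log2(3.0**k - 2.0) - (
        k * ent_s - k1 * ent_l[best, cols] - k2 * ent_r[best, cols]
    )
    accepted = (
        admissible.any(axis=0)
        & (ent_s > 0)
        & (best_gain > (np.log2(n - 1.0) + delta) / n)
    )

    for j in np.flatnonzero(accepted):
        vj = v_sorted[:, j]
        yj = y_sorted[:, j]
        cuts = np.flatnonzero(vj[1:] != vj[:-1]) + 1
        ig[j] = _segment_ig(yj, cuts, 0, n)
    selected = np.flatnonzero(ig > 0)
    return IgResult(ig, selected, priors)


def normality_screen(
    m: SubjectMatrix, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Lilliefors normality test per voxel, within each class.

    A voxel is flagged normal iff the test is *not* rejected at ``alpha``
    in both classes; zero-variance voxels count as rejections.  Returns the
    fraction of normal voxels and the per-voxel boolean flags.  Descriptive
    only — the result never gates the pipeline.
    """
    labels = np.asarray(m.labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    for c in classes:
        if (labels == c).sum() < 5:
            raise ValueError(f"need >= 5 subjects per class, class {c!r} is smaller")

    normal = np.ones(m.n_voxels, dtype=bool)
    for c in classes:
        rows = m.values[labels == c]
        for j in range(m.n_voxels):
            if not normal[j]:
                continue
            x = rows[:, j]
            if np.ptp(x) == 0:
                normal[j] = False
                continue
            _, p = lilliefors(x, dist="norm", pvalmethod="approx")
            if p <= alpha:
                normal[j] = False
    return float(normal.mean()), normal
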