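"""Tri-level expression thresholding by 1-D weighted k-medians.

Expressed genes of a sample (values above the background threshold) are
partitioned into three contiguous expression classes - low (LEG), moderate
(MEG) and high (HEG) - by a one-dimensional weighted k-medians: points are
(x, y) pairs where x is an expression value and y the number of genes at
that value, distances are absolute differences of log-compressed values
log2(x + n), and each cluster centroid is the weighted median (an actual
data value, the "middle gene").  The low threshold of a sample is the
midpoint between the largest LEG value and the smallest MEG value on the
original RPKM scale; the high threshold is the MEG/HEG analogue.  Unified
thresholds are medians of per-sample thresholds.

An exact dynamic program over contiguous partitions
(:func:`dp_optimal_objective`) provides an independent optimum for the same
weighted L1 objective; it shares no code with the iterative algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionMatrix, InvalidInputError

_MAX_ITER = 500


def transform(x, n: float = 1.0):
    """Monotone log compression log2(x + n) applied before distance
    computation; *n* is the transform factor (default 1)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise InvalidInputError("transform requires strictly positive expression values")
    return np.log2(arr + n)


@dataclass
class ClusterState:
    """Converged 1-D weighted k-medians partition.

    ``x`` and ``weights`` are the aggregated points sorted by x; ``labels``
    assigns each point to cluster 0..K-1 in ascending centroid order
    (0 = LEG, 1 = MEG, 2 = HEG for K = 3).  ``centroids`` are original-scale
    expression values.  ``objective`` is the weighted sum of absolute
    deviations in the working (transformed) space.
    """

    x: np.ndarray
    weights: np.ndarray
    labels: np.ndarray
    centroids: np.ndarray
    objective: float
    n_iter: int
    k: int
    transform_n: float
    distance_space: str

    def cluster_values(self, label: int) -> np.ndarray:
        return self.x[self.labels == label]

    def cluster_weight(self, label: int) -> int:
        return int(self.weights[self.labels == label].sum())


def _aggregate_points(x, weights=None):
    arr = np.asarray(x, dtype=float)
    if weights is None:
        w = np.ones(arr.size, dtype=np.int64)
    else:
        w = np.asarray(weights, dtype=np.int64)
        if w.shape != arr.shape:
            raise InvalidInputError("x and weights must have the same length")
        if np.any(w < 1):
            raise InvalidInputError("point weights must be positive integers")
    if np.any(arr <= 0):
        raise InvalidInputError("expression points must be positive")
    ux, inv = np.unique(arr, return_inverse=True)
    uw = np.bincount(inv, weights=w).astype(np.int64)
    return ux, uw


def _weighted_median_index(weights: np.ndarray) -> int:
    """Index of the lower-middle element under cumulative weight."""
    cw = np.cumsum(weights)
    need = (cw[-1] + 1) // 2
    return int(np.searchsorted(cw, need))


def _assign(t: np.ndarray, cent_t: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment in 1-D; equidistant points go to the
    lower cluster.  Clusters are therefore contiguous intervals in x."""
    order = np.argsort(cent_t, kind="stable")
    cs = cent_t[order]
    boundaries = (cs[:-1] + cs[1:]) / 2.0
    idx = np.searchsorted(boundaries, t, side="left")
    return order[idx] if not np.array_equal(order, np.arange(order.size)) else idx


def _objective(t, w, labels, cent_t, k):
    total = 0.0
    for c in range(k):
        m = labels == c
        if m.any():
            total += float(np.sum(w[m] * np.abs(t[m] - cent_t[c])))
    return total


def weighted_kmedians_1d(
    x,
    weights=None,
    k: int = 3,
    n: float = 1.0,
    distance_space: str = "transformed",
    seed: int | None = None,
    max_restarts: int = 0,
) -> ClusterState:
    """Cluster weighted 1-D expression points into *k* contiguous classes.

    Iterates nearest-centroid assignment and weighted-median centroid update
    until the assignment is a fixed point.  The default initialisation is
    deterministic (weighted quantiles at (2j+1)/(2k)); ``max_restarts`` adds
    seeded random initialisations, keeping the lowest-objective solution.
    Empty clusters are reseeded at the point farthest from its nearest
    surviving centroid.
    """
    ux, uw = _aggregate_points(x, weights)
    if ux.size < k:
        raise InvalidInputError(f"need at least {k} distinct values, got {ux.size}")
    if distance_space not in ("transformed", "raw"):
        raise InvalidInputError("distance_space must be 'transformed' or 'raw'")
    t = transform(ux, n) if distance_space == "transformed" else ux.astype(float)

    inits = [_quantile_init(ux, uw, k)]
    if max_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(max_restarts):
            inits.append(np.sort(rng.choice(ux.size, size=k, replace=False)))

    best = None
    for init_idx in inits:
        state = _run_once(ux, uw, t, init_idx, k)
        if best is None or state[2] < best[2] - 1e-12:
            best = state
    labels, cent_idx, obj, n_iter = best
    # relabel clusters 0..k-1 by ascending centroid
    order = np.argsort(t[cent_idx], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centroids = ux[cent_idx][order]
    return ClusterState(
        x=ux, weights=uw, labels=labels, centroids=centroids,
        objective=obj, n_iter=n_iter, k=k, transform_n=n,
        distance_space=distance_space,
    )


def _quantile_init(ux, uw, k) -> np.ndarray:
    """Indices of the weighted (2j+1)/(2k) quantile points, forced distinct."""
    cw = np.cumsum(uw)
    total = cw[-1]
    idx = []
    for j in range(k):
        need = max(1, int(np.ceil((2 * j + 1) / (2 * k) * total)))
        i = int(np.searchsorted(cw, need))
        idx.append(min(i, ux.size - 1))
    # force distinct, preserving order
    for j in range(1, k):
        if idx[j] <= idx[j - 1]:
            idx[j] = idx[j - 1] + 1
    if idx[-1] >= ux.size:
        idx = list(range(ux.size - k, ux.size))
    return np.asarray(idx, dtype=int)


def _run_once(ux, uw, t, cent_idx, k):
    cent_idx = np.array(cent_idx, dtype=int)
    labels = None
    for it in range(1, _MAX_ITER + 1):
        new_labels = _assign(t, t[cent_idx])
        # empty-cluster repair: reseed at the farthest point
        for c in range(k):
            if not (new_labels == c).any():
                dists = np.min(np.abs(t[:, None] - t[cent_idx][None, :]), axis=1)
                far = int(np.argmax(dists))
                cent_idx[c] = far
                new_labels = _assign(t, t[cent_idx])
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = np.flatnonzero(labels == c)
            mi = _weighted_median_index(uw[members])
            cent_idx[c] = members[mi]
    obj = _objective(t, uw, labels, t[cent_idx], k)
    return labels, cent_idx, obj, it


def extract_thresholds(state: ClusterState) -> tuple[float, float]:
    """Low/high cutoffs on the original scale: midpoints between adjacent
    cluster extremes (max of LEG with min of MEG; max of MEG with min of HEG)."""
    if state.k != 3:
        raise InvalidInputError("threshold extraction requires K = 3")
    parts = [state.cluster_values(c) for c in range(3)]
    if any(p.size == 0 for p in parts):
        raise InvalidInputError("empty cluster: cannot extract thresholds")
    low = (parts[0].max() + parts[1].min()) / 2.0
    high = (parts[1].max() + parts[2].min()) / 2.0
    return float(low), float(high)


def unify_thresholds(per_sample: list[tuple[float, float]]) -> tuple[float, float]:
    """Componentwise medians of per-sample (low, high) pairs."""
    if not per_sample:
        raise InvalidInputError("need at least one per-sample threshold pair")
    arr = np.asarray(per_sample, dtype=float)
    return float(np.median(arr[:, 0])), float(np.median(arr[:, 1]))


# ------------------------------------------------------------- exact oracle


def dp_optimal_objective(x, weights=None, k: int = 3, n: float = 1.0,
                         distance_space: str = "transformed") -> float:
    """Exact minimum weighted-L1 objective over all contiguous k-partitions.

    Dynamic program in O(k n^2): segment cost is deviation from the segment's
    weighted median, computed from prefix sums.  Serves as an independent
    optimum for :func:`weighted_kmedians_1d`.
    """
    ux, uw = _aggregate_points(x, weights)
    if ux.size < k:
        raise InvalidInputError(f"need at least {k} distinct values, got {ux.size}")
    t = transform(ux, n) if distance_space == "transformed" else ux.astype(float)
    m = ux.size
    pw = np.concatenate([[0.0], np.cumsum(uw)])
    pwt = np.concatenate([[0.0], np.cumsum(uw * t)])

    def seg_cost(i: int, j: int) -> float:
        # inclusive [i, j]
        med = i + _weighted_median_index(uw[i : j + 1])
        tm = t[med]
        left_w = pw[med + 1] - pw[i]
        left_wt = pwt[med + 1] - pwt[i]
        right_w = pw[j + 1] - pw[med + 1]
        right_wt = pwt[j + 1] - pwt[med + 1]
        return (tm * left_w - left_wt) + (right_wt - tm * right_w)

    cost = np.full((m, m), np.inf)
    for i in range(m):
        for j in range(i, m):
            cost[i, j] = seg_cost(i, j)
    dp = np.full((k + 1, m + 1), np.inf)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, m + 1):
            best = np.inf
            for i in range(c - 1, j):
                v = dp[c - 1, i] + cost[i, j - 1]
                if v < best:
                    best = v
            dp[c, j] = best
    return float(dp[k, m])


# -------------------------------------------------------------- per sample


def trilevel_sample(values, background: float, k: int = 3, n: float = 1.0,
                    distance_space: str = "transformed", seed: int | None = None,
                    max_restarts: int = 0) -> dict:
    """Cluster the expressed values of one sample and report the Table-style
    row: class gene counts, low/high thresholds and expressed total."""
    arr = np.asarray(values, dtype=float)
    expressed = arr[arr > background]
    state = weighted_kmedians_1d(expressed, k=k, n=n, distance_space=distance_space,
                                 seed=seed, max_restarts=max_restarts)
    low, high = extract_thresholds(state)
    return {
        "low_count": state.cluster_weight(0),
        "low_threshold": low,
        "moderate_count": state.cluster_weight(1),
        "high_count": state.cluster_weight(2),
        "high_threshold": high,
        "total": int(expressed.size),
        "state": state,
    }


def trilevel_table(matrix: ExpressionMatrix, background: float, *, k: int = 3,
                   n: float = 1.0, distance_space: str = "transformed",
                   seed: int | None = None, max_restarts: int = 0,
                   unify_group: str = "normal"):
    """Per-sample tri-level rows plus unified thresholds.

    Unified (low, high) are medians over the samples of ``unify_group``
    (the normal group by default, which acts as the control standard).
    Returns (DataFrame indexed by sample, (unified_low, unified_high)).
    """
    import pandas as pd

    rows = {}
    for sid in matrix.sample_ids:
        rec = trilevel_sample(matrix.values[sid].to_numpy(), background, k=k, n=n,
                              distance_space=distance_space, seed=seed,
                              max_restarts=max_restarts)
        rec.pop("state")
        rows[sid] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    if unify_group == "all":
        pick = list(table.index)
    else:
        pick = matrix.group_columns(unify_group)
    pairs = [(table.loc[s, "low_threshold"], table.loc[s, "high_threshold"]) for s in pick]
    return table, unify_thresholds(pairs)
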