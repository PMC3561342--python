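"""Background ("expressed / not expressed") threshold estimation.

A positive set (exonic gene expression values) is compared with a negative
set (expression density of intergenic regions).  For every candidate cutoff
t the false positive rate is the fraction of intergenic values called
expressed (value > t) and the false negative rate is the fraction of gene
values called silent (value <= t).  The background threshold coordinates the
two error rates: it is the candidate minimising |FPR - FNR| (ties broken
toward the smaller threshold).  Per-sample thresholds are unified across
samples as their median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionMatrix, InvalidInputError


@dataclass
class BackgroundModel:
    """FPR/FNR curves over candidate thresholds plus the selected cutoff."""

    positive_values: np.ndarray
    negative_values: np.ndarray
    candidates: np.ndarray       # sorted unique observed values plus 0
    fpr_at: np.ndarray           # aligned with candidates
    fnr_at: np.ndarray
    fp_at: np.ndarray            # integer counts aligned with candidates
    fn_at: np.ndarray
    threshold: float
    fp_count: int
    tn_count: int
    fn_count: int
    tp_count: int

    @property
    def fpr(self) -> float:
        return self.fp_count / (self.fp_count + self.tn_count)

    @property
    def fnr(self) -> float:
        return self.fn_count / (self.fn_count + self.tp_count)


def fpr_fnr_curve(positive_values, negative_values) -> BackgroundModel:
    """Compute FPR and FNR at every candidate threshold.

    Candidates are the sorted unique union of observed values and 0.  At a
    candidate t: FP = #{negative > t}, TN = #{negative <= t},
    FN = #{positive <= t}, TP = #{positive > t}.
    """
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("positive and negative sets must both be non-empty")
    if (pos < 0).any() or (neg < 0).any():
        raise InvalidInputError("expression values must be non-negative")
    candidates = np.unique(np.concatenate([pos, neg, [0.0]]))
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # counts <= t via searchsorted on the right edge
    neg_le = np.searchsorted(neg_sorted, candidates, side="right")
    pos_le = np.searchsorted(pos_sorted, candidates, side="right")
    fp = neg.size - neg_le
    tn = neg_le
    fn = pos_le
    tp = pos.size - pos_le
    fpr = fp / neg.size
    fnr = fn / pos.size
    idx = _select_index(fp, fn, neg.size, pos.size)
    return BackgroundModel(
        positive_values=pos,
        negative_values=neg,
        candidates=candidates,
        fpr_at=fpr,
        fnr_at=fnr,
        fp_at=fp,
        fn_at=fn,
        threshold=float(candidates[idx]),
        fp_count=int(fp[idx]),
        tn_count=int(tn[idx]),
        fn_count=int(fn[idx]),
        tp_count=int(tp[idx]),
    )


def _select_index(fp: np.ndarray, fn: np.ndarray, n_neg: int, n_pos: int) -> int:
    # |FPR - FNR| compared exactly via integer cross-multiplication:
    # |fp/n_neg - fn/n_pos| ~ |fp * n_pos - fn * n_neg|.  Exact rational ties
    # (which float division can break arbitrarily) then resolve to the first,
    # i.e. smallest, candidate as documented.
    gap = np.abs(fp.astype(np.int64) * n_pos - fn.astype(np.int64) * n_neg)
    return int(np.argmin(gap))


def select_background_threshold(model: BackgroundModel) -> float:
    """Candidate minimising |FPR - FNR|; smaller threshold wins ties."""
    idx = _select_index(model.fp_at, model.fn_at,
                        model.negative_values.size, model.positive_values.size)
    return float(model.candidates[idx])


def unified_background(per_sample_thresholds) -> float:
    """Median of the per-sample thresholds (even count: mean of middle two)."""
    arr = np.asarray(list(per_sample_thresholds), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("need at least one per-sample threshold")
    return float(np.median(arr))


def per_sample_backgrounds(matrix: ExpressionMatrix, negative_values) -> dict[str, float]:
    """Background threshold for every sample of a matrix.

    The positive set for a sample is its column of gene expression values
    restricted to values > 0 (genes with no reads carry no evidence); the
    negative set is shared across samples.
    """
    out: dict[str, float] = {}
    for sid in matrix.sample_ids:
        col = matrix.values[sid].to_numpy()
        pos = col[col > 0]
        if pos.size == 0:
            raise InvalidInputError(f"sample {sid!r} has no positive expression values")
        model = fpr_fnr_curve(pos, negative_values)
        out[sid] = model.threshold
    return out
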