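"""Rank-based expression variation: tri-level ranks, CV and status classes.

Raw expression values inflate variance estimates for highly expressed genes,
so variation is measured on tri-level ranks instead: every expressed value
is mapped to 1 (low), 2 (moderate) or 3 (high) via the unified thresholds,
and a gene's coefficient of variation CV = sigma / mu is computed over its
per-sample ranks with the population (divide-by-N) standard deviation.
Genes are classified as constant (CV <= q1), moderate variable
(q1 < CV <= q3) or variable (CV > q3) where q1/q3 are the first and third
quartiles of the normal-group HK CV distribution (0.14 and 0.26 in the
reference human dataset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, InvalidInputError

CONSTANT = "constant"
MODERATE_VARIABLE = "moderate_variable"
VARIABLE = "variable"
STATUSES = (CONSTANT, MODERATE_VARIABLE, VARIABLE)

DEFAULT_Q1 = 0.14
DEFAULT_Q3 = 0.26


def assign_ranks(values: pd.DataFrame, unified_low: float, unified_high: float,
                 background: float) -> pd.DataFrame:
    """Map expression to ranks 1/2/3; cells at or below background are masked
    (NaN).  Bins are (background, low] -> 1, (low, high] -> 2, (high, inf) -> 3.
    """
    if not background < unified_low < unified_high:
        raise InvalidInputError(
            f"need background < low < high, got {background}, {unified_low}, {unified_high}"
        )
    arr = values.to_numpy(dtype=float)
    ranks = np.full(arr.shape, np.nan)
    ranks[(arr > background) & (arr <= unified_low)] = 1.0
    ranks[(arr > unified_low) & (arr <= unified_high)] = 2.0
    ranks[arr > unified_high] = 3.0
    return pd.DataFrame(ranks, index=values.index, columns=values.columns)


@dataclass
class CVRecord:
    gene: str
    n: int
    mu: float
    sigma: float
    cv: float | None  # None when undefined (fewer than 2 ranks)


def cv(ranks, gene: str = "") -> CVRecord:
    """Coefficient of variation of a gene's rank vector.

    mu is the arithmetic mean; sigma is the population standard deviation
    (square root of the mean squared deviation).  Masked entries (NaN) are
    dropped; fewer than 2 surviving ranks yields an undefined CV.
    """
    arr = np.asarray(ranks, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return CVRecord(gene, int(arr.size), float("nan"), float("nan"), None)
    mu = float(arr.mean())
    sigma = float(np.sqrt(np.mean((arr - mu) ** 2)))
    return CVRecord(gene, int(arr.size), mu, sigma, sigma / mu)


def cv_table(rank_matrix: pd.DataFrame, require_complete: bool = True) -> pd.Series:
    """Per-gene CV over the columns of *rank_matrix*.

    With ``require_complete`` (default) genes with any masked sample are
    excluded - HK genes of the group under study are never masked by
    construction, so this only drops genes outside that set.
    """
    arr = rank_matrix.to_numpy(dtype=float)
    if require_complete:
        keep = ~np.isnan(arr).any(axis=1)
    else:
        keep = (~np.isnan(arr)).sum(axis=1) >= 2
    out = {}
    for gene, row in zip(rank_matrix.index[keep], arr[keep]):
        rec = cv(row, gene)
        if rec.cv is not None:
            out[gene] = rec.cv
    return pd.Series(out, name="cv", dtype=float)


def cv_thresholds(cv_values) -> tuple[float, float]:
    """First and third quartiles (linear interpolation between order
    statistics) of the control CV distribution."""
    arr = np.asarray(list(cv_values), dtype=float)
    if arr.size < 4:
        raise InvalidInputError("need at least 4 CV values to set quartile thresholds")
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation (type 7)
    return float(q1), float(q3)


def classify_status(cv_value: float, q1: float = DEFAULT_Q1, q3: float = DEFAULT_Q3) -> str:
    """Constant ([0, q1]), moderate variable ((q1, q3]) or variable ((q3, inf)).

    CV = 0 counts as constant so every gene receives a status.
    """
    if cv_value < 0:
        raise InvalidInputError("CV must be non-negative")
    if cv_value <= q1:
        return CONSTANT
    if cv_value <= q3:
        return MODERATE_VARIABLE
    return VARIABLE


def status_table(cv_values: pd.Series, q1: float = DEFAULT_Q1, q3: float = DEFAULT_Q3) -> pd.Series:
    return cv_values.apply(classify_status, args=(q1, q3)).rename("status")


def transition_matrix(status_normal: pd.Series, status_cancer: pd.Series) -> pd.DataFrame:
    """3x3 table of status transitions between conditions for a shared gene
    set; rows index the normal-condition status, columns the cancer one."""
    if set(status_normal.index) != set(status_cancer.index):
        raise InvalidInputError("status maps must cover the same gene set")
    counts = pd.DataFrame(0, index=list(STATUSES), columns=list(STATUSES), dtype=int)
    for gene in status_normal.index:
        counts.loc[status_normal[gene], status_cancer[gene]] += 1
    return counts
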