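"""MDAD statistics: group-extreme differences and signed-rank testing.

For each gene the maximum and positive minimum expression are taken within
the normal group and within the cancer group.  Two log2-scale statistics
summarise the discrepancy between conditions (an MA-plot-style pair over
group extremes):

* ``MD`` (M distance)  = log2(max_n / min_n) - log2(max_c / min_c):
  the difference of expression span widths; MD < 0 means the gene's
  expression distribution is wider in cancer.
* ``AD`` (A distance)  = 1/2 [log2 max_n + log2 min_n]
  - 1/2 [log2 max_c + log2 min_c]: the difference of log-scale mid-levels;
  AD < 0 means the gene's relative average level is higher in cancer.

``maxR = max_n / max_c`` and ``minR = min_n / min_c`` compare raw extremes;
a ratio of 0 marks a gene switched on only in cancer, ratios in (0, 1]
mean the cancer extreme is at least as high.

Whether MD/AD of a gene population centres on zero is assessed with a
paired Wilcoxon signed-rank test against a zero-median null: exact by
enumeration of the sign-flip distribution for small n, otherwise a normal
approximation with tie-corrected variance and continuity correction; the
reported Z carries the sign of the observed shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ExpressionMatrix, InvalidInputError, round_half_up

EXACT_N_MAX = 20


@dataclass
class GroupExtremes:
    gene: str
    max_n: float  # 0 when no positive normal value
    min_n: float  # positive minimum; 0 when absent
    max_c: float
    min_c: float

    @property
    def only_on_in_cancer(self) -> bool:
        return self.max_n == 0 and self.max_c > 0

    @property
    def only_on_in_normal(self) -> bool:
        return self.max_c == 0 and self.max_n > 0

    @property
    def defined(self) -> bool:
        """All four extremes positive - MD/AD computable."""
        return min(self.max_n, self.min_n, self.max_c, self.min_c) > 0


def group_extremes(matrix: ExpressionMatrix) -> list[GroupExtremes]:
    """Per-gene max and positive min within each group.

    The minimum is taken over strictly positive entries only; a gene with no
    positive entry in a group gets 0 extremes there (flagged via the
    ``only_on_in_*`` properties).
    """
    nv = matrix.group_values("normal").to_numpy()
    cv_ = matrix.group_values("cancer").to_numpy()
    out = []
    for gene, nrow, crow in zip(matrix.gene_ids, nv, cv_):
        out.append(GroupExtremes(gene, *_extremes(nrow), *_extremes(crow)))
    return out


def _extremes(row: np.ndarray) -> tuple[float, float]:
    pos = row[row > 0]
    if pos.size == 0:
        return 0.0, 0.0
    return float(pos.max()), float(pos.min())


def mdad(extremes: GroupExtremes) -> tuple[float, float]:
    """(MD, AD) for one gene; requires all four extremes positive."""
    if not extremes.defined:
        raise InvalidInputError(
            f"{extremes.gene}: MD/AD undefined with a non-positive group extreme"
        )
    md = math.log2(extremes.max_n / extremes.min_n) - math.log2(extremes.max_c / extremes.min_c)
    ad = 0.5 * (math.log2(extremes.max_n) + math.log2(extremes.min_n)) - 0.5 * (
        math.log2(extremes.max_c) + math.log2(extremes.min_c)
    )
    return md, ad


def ratios(extremes: GroupExtremes) -> tuple[float, float]:
    """(maxR, minR) = normal extreme / cancer extreme.

    0 when the gene is off in normal; inf when off in cancer; undefined
    (error) when off in both.
    """
    if extremes.max_n == 0 and extremes.max_c == 0:
        raise InvalidInputError(f"{extremes.gene}: both group extremes are zero")
    maxr = math.inf if extremes.max_c == 0 else extremes.max_n / extremes.max_c
    minr = math.inf if extremes.min_c == 0 else extremes.min_n / extremes.min_c
    return maxr, minr


def mdad_table(matrix: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Per-gene MD, AD, maxR, minR plus on/off flags.

    Genes with an undefined extreme keep their ratios (0 / inf semantics)
    but carry NaN MD/AD and are excluded from the signed-rank tests.
    """
    wanted = set(genes) if genes is not None else None
    rows = []
    for ext in group_extremes(matrix):
        if wanted is not None and ext.gene not in wanted:
            continue
        if ext.max_n == 0 and ext.max_c == 0:
            continue  # silent everywhere: nothing to compare
        md = ad = float("nan")
        if ext.defined:
            md, ad = mdad(ext)
        maxr, minr = ratios(ext)
        rows.append(
            {
                "gene_id": ext.gene, "max_n": ext.max_n, "min_n": ext.min_n,
                "max_c": ext.max_c, "min_c": ext.min_c, "MD": md, "AD": ad,
                "maxR": maxr, "minR": minr,
                "only_on_in_cancer": ext.only_on_in_cancer,
                "only_on_in_normal": ext.only_on_in_normal,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["max_n", "min_n", "max_c", "min_c", "MD", "AD", "maxR", "minR",
                 "only_on_in_cancer", "only_on_in_normal"]
    )


# ------------------------------------------------------------ signed rank


@dataclass
class WilcoxonResult:
    n_used: int
    w_plus: float
    z: float
    p_value: float
    method: str  # "exact" or "normal"
    reject: bool
    alpha: float = 0.05


def wilcoxon_signed_rank(values, mu0: float = 0.0, alpha: float = 0.05) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of median(values) = mu0, two-sided.

    Exact zero differences are dropped; ties share average ranks.  For
    n_used <= 20 the p-value is exact (dynamic program over the 2^n
    equiprobable sign assignments of the observed |ranks|); otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used.  Z always carries the sign of
    (W+ - n(n+1)/4), positive when values sit above mu0.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise InvalidInputError("signed-rank test undefined: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    # tie-corrected variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_plus - mean
    if var > 0:
        cc = min(0.5, abs(diff))  # continuity correction toward the mean
        z = (diff - math.copysign(cc, diff)) / math.sqrt(var) if diff != 0 else 0.0
    else:
        z = 0.0
    if n <= EXACT_N_MAX:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    p = min(1.0, p)
    return WilcoxonResult(n_used=n, w_plus=w_plus, z=float(z), p_value=p,
                          method=method, reject=p < alpha, alpha=alpha)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ under random sign flips of the observed
    ranks.  Ranks are scaled by 2 so tied (half-integer) ranks become
    integers; the subset-sum distribution is built by convolution, which is
    equivalent to enumerating all 2^n sign assignments."""
    scaled = np.rint(ranks * 2).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus * 2))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ------------------------------------------------------------- summaries


def mdad_test_summary(table: pd.DataFrame, statuses: pd.Series | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Signed-rank test of MD and AD over all genes and per variation-status
    subtype.  Output columns mirror a per-class test report: gene count,
    reject flag (1 = null rejected), p-value and signed Z."""
    defined = table.dropna(subset=["MD", "AD"])
    groups: list[tuple[str, pd.DataFrame]] = [("all", defined)]
    if statuses is not None:
        for status in ("constant", "moderate_variable", "variable"):
            sel = [g for g in defined.index if statuses.get(g) == status]
            groups.append((status, defined.loc[sel]))
    rows = []
    for name, sub in groups:
        for stat in ("MD", "AD"):
            if len(sub) == 0:
                rows.append({"type": f"{stat}_{name}", "gene_count": 0, "reject": "",
                             "p_value": "", "z": ""})
                continue
            res = wilcoxon_signed_rank(sub[stat].to_numpy(), alpha=alpha)
            rows.append({"type": f"{stat}_{name}", "gene_count": len(sub),
                         "reject": int(res.reject), "p_value": res.p_value, "z": res.z})
    return pd.DataFrame(rows).set_index("type")


def accumulated_ratio_table(table: pd.DataFrame, statuses: pd.Series | None = None,
                            cutoff: float = 1.0) -> pd.DataFrame:
    """Percent of genes with minR <= cutoff and maxR <= cutoff, overall and
    per variation status (two-decimal percentages)."""
    groups: list[tuple[str, pd.DataFrame]] = [("all", table)]
    if statuses is not None:
        for status in ("constant", "moderate_variable", "variable"):
            sel = [g for g in table.index if statuses.get(g) == status]
            groups.append((status, table.loc[sel]))
    rows = []
    for name, sub in groups:
        n = len(sub)
        if n == 0:
            rows.append({"type": name, "gene_count": 0,
                         "minR_le_cutoff_pct": "", "maxR_le_cutoff_pct": ""})
            continue
        minr_pct = 100.0 * (sub["minR"] <= cutoff).sum() / n
        maxr_pct = 100.0 * (sub["maxR"] <= cutoff).sum() / n
        rows.append({"type": name, "gene_count": n,
                     "minR_le_cutoff_pct": round_half_up(minr_pct, 2),
                     "maxR_le_cutoff_pct": round_half_up(maxr_pct, 2)})
    return pd.DataFrame(rows).set_index("type")
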