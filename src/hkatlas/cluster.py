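"""Sample-profile clustering: Spearman similarity + average-linkage tree.

Expression-profile similarity between samples is the Spearman rank
correlation of their gene expression vectors; samples are clustered
hierarchically on the distance 1 - rho.  Cutting the tree into two clusters
reads out how cleanly the normal and cancer conditions separate (purity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import ExpressionMatrix, InvalidInputError


def spearman_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Samples x samples Spearman correlation (average ranks on ties).

    A sample with a constant profile has undefined correlations (NaN).
    """
    if len(matrix.sample_ids) < 2 or len(matrix.gene_ids) < 2:
        raise InvalidInputError("need at least 2 samples and 2 genes")
    vals = matrix.values.to_numpy()
    constant = [s for s, col in zip(matrix.sample_ids, vals.T)
                if np.all(col == col[0])]
    if constant:
        raise InvalidInputError(
            f"constant expression profile (correlation undefined) for samples: {constant}"
        )
    rho = sps.spearmanr(vals, axis=0).statistic
    rho = np.atleast_2d(rho)
    df = pd.DataFrame(rho, index=matrix.sample_ids, columns=matrix.sample_ids)
    # force exact 1.0 diagonal (spearmanr already guarantees it numerically)
    np.fill_diagonal(df.values, 1.0)
    return df


@dataclass
class Dendrogram:
    """Average-linkage tree over samples on distance 1 - rho.

    ``linkage`` is a scipy linkage matrix over ``sample_ids`` (sorted
    lexicographically before clustering, the documented tie-break).
    """

    sample_ids: list[str]
    linkage: np.ndarray

    @property
    def leaf_order(self) -> list[str]:
        leaves = hierarchy.leaves_list(self.linkage)
        return [self.sample_ids[i] for i in leaves]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.sample_ids)
        return str(tree).strip()


def hierarchical_cluster(corr: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerate samples on distance 1 - rho with the given linkage
    (average by default; complete/single also supported)."""
    if linkage not in ("average", "complete", "single"):
        raise InvalidInputError(f"unsupported linkage {linkage!r}")
    bad = [s for s in corr.index if corr[s].isna().any()]
    if bad:
        raise InvalidInputError(f"undefined correlations for samples: {bad}")
    ids = sorted(corr.index)  # lexicographic order fixes scipy's tie-breaks
    dist = 1.0 - corr.loc[ids, ids].to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return Dendrogram(sample_ids=ids, linkage=z)


def cut_k(dendrogram: Dendrogram, k: int, labels: dict[str, str] | None = None):
    """Cut the tree into *k* clusters; with *labels* also report purity
    (fraction of samples agreeing with their cluster's majority label)."""
    n = len(dendrogram.sample_ids)
    if not 1 <= k <= n:
        raise InvalidInputError(f"k must be in [1, {n}], got {k}")
    assignment = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    partition = {sid: int(c) for sid, c in zip(dendrogram.sample_ids, assignment)}
    purity = None
    if labels is not None:
        agree = 0
        for c in set(partition.values()):
            members = [s for s, ci in partition.items() if ci == c]
            tags = [labels[s] for s in members]
            agree += max(tags.count(t) for t in set(tags))
        purity = agree / n
    return partition, purity


def cluster_samples(matrix: ExpressionMatrix, linkage: str = "average",
                    expressed_only: bool = False, background: float = 0.0):
    """Convenience wrapper: correlation matrix -> tree -> 2-way purity.

    With ``expressed_only`` genes silent (<= background) in every sample are
    dropped before correlating.
    """
    if expressed_only:
        keep = (matrix.values > background).any(axis=1)
        sub = ExpressionMatrix(matrix.values.loc[keep], matrix.samples)
    else:
        sub = matrix
    corr = spearman_matrix(sub)
    tree = hierarchical_cluster(corr, linkage=linkage)
    labels = {s.sample_id: s.group for s in matrix.samples}
    partition, purity = cut_k(tree, 2, labels)
    return tree, partition, purity
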