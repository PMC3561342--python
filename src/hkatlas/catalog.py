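"""Housekeeping-gene catalog: expression breadth and the five HK types.

A housekeeping (HK) gene of a group is a gene expressed above the background
threshold in every sample of that group.  Comparing the normal-group and
cancer-group HK sets yields four mutually exclusive base classes

* ``shared``            - HK in both groups,
* ``normal_unique``     - HK only in the normal group,
* ``cancer_associated`` - HK only in the cancer group,
* ``non_HK``            - HK in neither,

and two derived sets: normal HK = shared + normal_unique and cancer
HK = shared + cancer_associated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import ExpressionMatrix, InvalidInputError

SHARED = "shared"
NORMAL_UNIQUE = "normal_unique"
CANCER_ASSOCIATED = "cancer_associated"
NON_HK = "non_HK"
BASE_CLASSES = (SHARED, NORMAL_UNIQUE, CANCER_ASSOCIATED, NON_HK)


@dataclass
class HKCatalog:
    """Per-gene base class plus the derived normal/cancer HK sets."""

    base_class: dict[str, str]  # gene -> one of BASE_CLASSES

    @property
    def shared(self) -> set[str]:
        return {g for g, c in self.base_class.items() if c == SHARED}

    @property
    def normal_unique(self) -> set[str]:
        return {g for g, c in self.base_class.items() if c == NORMAL_UNIQUE}

    @property
    def cancer_associated(self) -> set[str]:
        return {g for g, c in self.base_class.items() if c == CANCER_ASSOCIATED}

    @property
    def non_hk(self) -> set[str]:
        return {g for g, c in self.base_class.items() if c == NON_HK}

    @property
    def normal_hk(self) -> set[str]:
        return self.shared | self.normal_unique

    @property
    def cancer_hk(self) -> set[str]:
        return self.shared | self.cancer_associated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.base_class), "hk_class": list(self.base_class.values())}
        ).set_index("gene_id")


def expression_breadth(matrix: ExpressionMatrix, threshold: float, group: str) -> pd.Series:
    """Number of *group* samples in which each gene exceeds *threshold*."""
    if threshold < 0:
        raise InvalidInputError("threshold must be >= 0")
    sub = matrix.group_values(group)
    return (sub > threshold).sum(axis=1)


def define_hk(matrix: ExpressionMatrix, threshold: float, group: str,
              min_breadth_fraction: float = 1.0) -> set[str]:
    """Genes expressed above *threshold* in every sample of *group*.

    ``min_breadth_fraction`` relaxes strict ubiquity (default 1.0 = all
    samples of the group).
    """
    if not 0 < min_breadth_fraction <= 1:
        raise InvalidInputError("min_breadth_fraction must be in (0, 1]")
    n = len(matrix.group_columns(group))
    need = math.ceil(min_breadth_fraction * n)
    breadth = expression_breadth(matrix, threshold, group)
    return set(breadth.index[breadth >= need])


def classify_five_types(normal_hk: set[str], cancer_hk: set[str], all_genes: set[str]) -> HKCatalog:
    """Partition *all_genes* into the four base classes by set algebra."""
    if not normal_hk <= all_genes or not cancer_hk <= all_genes:
        raise InvalidInputError("HK sets must be subsets of all_genes")
    base: dict[str, str] = {}
    for g in all_genes:
        in_n = g in normal_hk
        in_c = g in cancer_hk
        if in_n and in_c:
            base[g] = SHARED
        elif in_n:
            base[g] = NORMAL_UNIQUE
        elif in_c:
            base[g] = CANCER_ASSOCIATED
        else:
            base[g] = NON_HK
    return HKCatalog(base)


def _percent_half_up(count: int, total: int) -> int:
    """Integer percent, rounding halves up (so 46.5 -> 47)."""
    return int(math.floor(100.0 * count / total + 0.5))


def catalog_accounting(catalog: HKCatalog, total_loci: int) -> pd.DataFrame:
    """Counts and integer percent of *total_loci* for every class and the
    derived normal/cancer HK sets."""
    n_classified = len(catalog.base_class)
    if total_loci < n_classified:
        raise InvalidInputError(
            f"total_loci ({total_loci}) smaller than classified genes ({n_classified})"
        )
    rows = {
        "shared": len(catalog.shared),
        "normal_unique": len(catalog.normal_unique),
        "cancer_associated": len(catalog.cancer_associated),
        "non_HK": len(catalog.non_hk),
        "normal_HK": len(catalog.normal_hk),
        "cancer_HK": len(catalog.cancer_hk),
    }
    return pd.DataFrame(
        {
            "count": list(rows.values()),
            "percent_of_loci": [_percent_half_up(c, total_loci) for c in rows.values()],
        },
        index=list(rows),
    )


def build_catalog(matrix: ExpressionMatrix, threshold: float,
                  min_breadth_fraction: float = 1.0) -> HKCatalog:
    """End-to-end: breadth in both groups -> HK sets -> five-type catalog."""
    normal_hk = define_hk(matrix, threshold, "normal", min_breadth_fraction)
    cancer_hk = define_hk(matrix, threshold, "cancer", min_breadth_fraction)
    return classify_five_types(normal_hk, cancer_hk, set(matrix.gene_ids))
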