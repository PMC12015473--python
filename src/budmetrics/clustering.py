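"""Hierarchical clustering of accessions on bud size traits.

Accessions are clustered on their four trait means with Euclidean distances
(optionally z-score standardized per trait so no single trait dominates the
metric) under Ward linkage by default.  The tree can be cut either at a
height or into exactly k groups; groups are labeled with Roman numerals by
descending size, the convention of germplasm-panel reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .imaging import ValidationError

LINKAGES = ("ward", "complete", "average", "single")


def _roman(n: int) -> str:
    vals = [1000, 900, 500, 400, 100, 90, 50, 40, 10, 9, 5, 4, 1]
    syms = ["M", "CM", "D", "CD", "C", "XC", "L", "XL", "X", "IX", "V", "IV", "I"]
    out = ""
    for v, s in zip(vals, syms):
        while n >= v:
            out += s
            n -= v
    return out


@dataclass
class ClusterResult:
    """Agglomeration history over a fixed accession ordering."""

    merge: np.ndarray  # scipy linkage matrix (n-1, 4): left, right, height, size
    accessions: pd.Index
    trait_means: pd.DataFrame
    linkage: str
    standardized: bool

    @property
    def heights(self) -> np.ndarray:
        return self.merge[:, 2]


def cluster_accessions(
    trait_means: pd.DataFrame,
    linkage: str = "ward",
    standardize: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of accessions on their trait means.

    ``trait_means`` is an accession x trait matrix (accessions in the index).
    SciPy's agglomeration is deterministic for fixed input order; exact
    distance ties resolve to the lowest pair index.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    if len(trait_means) < 2:
        raise ValidationError("need >= 2 accessions")
    if trait_means.isna().any().any():
        bad = trait_means.index[trait_means.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing trait values for accessions: {bad}")
    X = trait_means.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    return ClusterResult(
        merge=Z,
        accessions=trait_means.index,
        trait_means=trait_means,
        linkage=linkage,
        standardized=standardize,
    )


def cut_tree(
    result: ClusterResult, height: float | None = None, k: int | None = None
) -> pd.Series:
    """Cut the tree at a height or into exactly k groups.

    Exactly one of ``height`` and ``k`` must be given.  Groups are labeled
    I, II, ... by descending size, ties broken by first-accession order.
    """
    if (height is None) == (k is None):
        raise ValidationError("give exactly one of height= or k=")
    n = len(result.accessions)
    if height is not None:
        if height <= 0:
            raise ValidationError("height must be > 0")
        raw = hierarchy.fcluster(result.merge, t=height, criterion="distance")
    else:
        if not 1 <= k <= n:
            raise ValidationError(f"k must be in [1, {n}]")
        raw = hierarchy.fcluster(result.merge, t=k, criterion="maxclust")
    assignment = pd.Series(raw, index=result.accessions, name="group")
    # Canonical labels: descending size, then first appearance.
    order = sorted(
        assignment.unique(),
        key=lambda g: (-(assignment == g).sum(), int(np.argmax(assignment.to_numpy() == g))),
    )
    mapping = {g: _roman(i + 1) for i, g in enumerate(order)}
    return assignment.map(mapping)


def summarize_groups(
    assignment: pd.Series,
    trait_means: pd.DataFrame,
    regions: pd.Series | None = None,
    top_n_regions: int = 15,
) -> dict[str, pd.DataFrame]:
    """Per-group counts and trait means, plus a region x group table.

    The region table is restricted to the ``top_n_regions`` regions by total
    accession count.  Accessions without a region are counted as "unknown".
    """
    if not assignment.index.equals(trait_means.index):
        missing = trait_means.index.difference(assignment.index).tolist()
        if missing:
            raise ValidationError(f"assignment missing accessions: {missing}")
        assignment = assignment.reindex(trait_means.index)
    df = trait_means.copy()
    df["group"] = assignment
    by = df.groupby("group", observed=True)
    summary = by.mean()
    summary.insert(0, "n_accessions", by.size())
    summary = summary.sort_values("n_accessions", ascending=False)

    out = {"groups": summary}
    if regions is not None:
        reg = regions.reindex(assignment.index).fillna("unknown")
        table = pd.crosstab(reg, assignment)
        totals = table.sum(axis=1).sort_values(ascending=False)
        table = table.loc[totals.index[:top_n_regions]]
        table.index.name = "region"
        out["regions"] = table
    return out
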