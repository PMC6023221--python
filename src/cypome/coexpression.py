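"""Co-expression clustering of category-averaged profiles.

Profiles are clustered by complete-linkage agglomeration on the distance
d = 1 - r, where r is Pearson's correlation across the condition
categories.  Cutting the dendrogram at height 1 - cut_r (default cut_r =
0.656) yields clusters in which *every* within-cluster pair of profiles
correlates at r >= cut_r — for complete linkage the cophenetic height of
a cluster is its maximum pairwise distance, so the cut is a hard
guarantee, not a heuristic.

Constant (zero-variance) profiles have no defined correlation; they are
assigned r = 0 (d = 1) against everything rather than dropped, keeping
the expressed set intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionClusterResult",
    "correlation_distance",
    "cluster_profiles",
    "row_normalize",
]


@dataclass(slots=True)
class ExpressionClusterResult:
    labels: dict[str, str]  # annotation id -> cluster label (letters)
    cut_r: float
    linkage: np.ndarray  # scipy linkage matrix (merge heights = distances)
    ids: tuple[str, ...]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def sizes(self) -> pd.Series:
        return pd.Series(list(self.labels.values())).value_counts().sort_index()


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance 1 - Pearson r between profile rows.

    d is in [0, 2] with d(i, i) = 0.  Zero-variance rows get r = 0
    against every other row.  Raises if any row has fewer than two finite
    values (a correlation needs at least two paired observations).
    """
    values = profiles.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("profiles need at least two categories")
    finite = np.isfinite(values)
    if (finite.sum(axis=1) < 2).any():
        bad = profiles.index[finite.sum(axis=1) < 2][0]
        raise ValueError(f"profile {bad!r} has fewer than two finite values")
    sd = values.std(axis=1)
    constant = sd == 0
    corr = np.zeros((len(values), len(values)))
    ok = ~constant
    if ok.sum() >= 1:
        sub = np.corrcoef(values[ok])
        sub = np.atleast_2d(sub)
        corr[np.ix_(ok, ok)] = sub
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, 2.0, out=dist)
    return pd.DataFrame(dist, index=profiles.index, columns=profiles.index)


def cluster_profiles(
    distances: pd.DataFrame, cut_r: float = 0.656
) -> ExpressionClusterResult:
    """Complete-linkage clustering of a 1 - r distance matrix, cut at
    height 1 - cut_r.

    Labels are letters (A, B, ... then AA, AB, ...) assigned in
    dendrogram leaf order, so identical inputs give identical labels.
    """
    if len(distances) < 2:
        raise ValueError("need at least two profiles to cluster")
    ids = tuple(str(i) for i in distances.index)
    dist = distances.to_numpy(dtype=float)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    flat = hierarchy.fcluster(linkage, t=1.0 - cut_r, criterion="distance")
    leaf_order = hierarchy.leaves_list(linkage)
    # letter labels in order of first appearance along the dendrogram leaves
    letter_of: dict[int, str] = {}
    for leaf in leaf_order:
        cl = int(flat[leaf])
        if cl not in letter_of:
            letter_of[cl] = _letter(len(letter_of))
    labels = {ids[i]: letter_of[int(flat[i])] for i in range(len(ids))}
    return ExpressionClusterResult(labels=labels, cut_r=cut_r, linkage=linkage, ids=ids)


def _letter(index: int) -> str:
    out = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = ascii_uppercase[rem] + out
    return out


def row_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Heatmap normalization (x - row minimum) / row maximum.

    The denominator is the row maximum (not the range), exactly as used
    for the published heatmaps.  Rows whose maximum is not positive are
    rejected — they cannot occur for expressed sequences.
    """
    values = matrix.to_numpy(dtype=float)
    row_min = values.min(axis=1, keepdims=True)
    row_max = values.max(axis=1, keepdims=True)
    if (row_max <= 0).any():
        bad = matrix.index[(row_max <= 0).ravel()][0]
        raise ValueError(f"row {bad!r} has no positive value")
    return pd.DataFrame(
        (values - row_min) / row_max, index=matrix.index, columns=matrix.columns
    )
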