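"""Resampling null models and contingency enrichment.

Two resampling tests quantify how unusual the observed organization of
the family is:

* :func:`clustering_bootstrap` — are family members more often part of a
  physical cluster than a random same-sized set of genome features?  Each
  iteration draws ``n_features`` features without replacement from the
  merged annotation, flags them as the family (keeping their true genomic
  coordinates) and re-runs cluster detection.
* :func:`coexpression_bootstrap` — do members of a physical cluster share
  expression profiles more often than expected?  The observed statistic is
  the fraction of expressed, physically clustered features whose
  expression-cluster label matches at least one other expressed member of
  the same physical cluster; the null permutes the labels uniformly among
  all expressed family features.

Empirical p-values are the plug-in estimate ``#(null >= observed) /
n_iter``; an optional ``(count + 1) / (n_iter + 1)`` correction is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .annotation import GenomeAnnotation
from .clusters import ClusterParams, ClusteringResult, clustered_mask, genome_arrays

__all__ = [
    "BootstrapResult",
    "clustering_bootstrap",
    "coexpression_bootstrap",
    "shared_label_fraction",
    "chi2_enrichment",
]


@dataclass(slots=True)
class BootstrapResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_iter: int
    seed: int
    corrected: bool = False

    def summary(self) -> dict:
        qs = np.quantile(self.null_values, [0.0, 0.25, 0.5, 0.75, 1.0])
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "corrected": self.corrected,
            "null_min": float(qs[0]),
            "null_q25": float(qs[1]),
            "null_median": float(qs[2]),
            "null_q75": float(qs[3]),
            "null_max": float(qs[4]),
        }


def _p_value(observed: float, null_values: np.ndarray, corrected: bool) -> float:
    count = int(np.sum(null_values >= observed))
    if corrected:
        return (count + 1) / (null_values.size + 1)
    return count / null_values.size


def clustering_bootstrap(
    ann: GenomeAnnotation,
    n_features: int,
    params: ClusterParams | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    corrected: bool = False,
) -> BootstrapResult:
    """Permutation null for physical-clustering enrichment.

    ``ann`` is the merged annotation (family + background).  The observed
    statistic is the clustered fraction of the real family; each null
    iteration samples ``n_features`` features without replacement from the
    whole feature table, treats them as the family and records the
    clustered fraction under the same linking rule.  One seeded generator
    drives all iterations.
    """
    params = params or ClusterParams()
    arrays = genome_arrays(ann)
    n_total = len(arrays.feature_ids)
    if n_features > n_total:
        raise ValueError(
            f"cannot sample {n_features} features from an annotation of {n_total}"
        )
    if arrays.family_idx.size == 0:
        raise ValueError("annotation contains no family features")
    observed_mask = clustered_mask(arrays, arrays.family_idx, params)
    observed = float(observed_mask.mean())

    rng = np.random.default_rng(seed)
    null_values = np.empty(n_iter, dtype=float)
    for i in range(n_iter):
        idx = rng.choice(n_total, size=n_features, replace=False)
        idx.sort()
        null_values[i] = clustered_mask(arrays, idx, params).mean()
    return BootstrapResult(
        observed=observed,
        null_values=null_values,
        p_value=_p_value(observed, null_values, corrected),
        n_iter=n_iter,
        seed=seed,
        corrected=corrected,
    )


def shared_label_fraction(
    cluster_ids: np.ndarray, labels: np.ndarray
) -> float:
    """Fraction of clustered items sharing their label with another item of
    the same cluster.

    ``cluster_ids`` holds a non-negative physical-cluster index per item,
    or -1 for items outside any cluster; ``labels`` holds integer-encoded
    expression-cluster labels.  The denominator is the number of items with
    ``cluster_ids >= 0``.
    """
    in_cluster = cluster_ids >= 0
    n_in = int(in_cluster.sum())
    if n_in == 0:
        raise ValueError("empty denominator: no expressed features in any cluster")
    n_labels = int(labels.max()) + 1 if labels.size else 0
    key = cluster_ids[in_cluster] * n_labels + labels[in_cluster]
    counts = np.bincount(key)
    return float((counts[key] >= 2).mean())


def coexpression_bootstrap(
    res: ClusteringResult,
    expr_labels: Mapping[str, object],
    n_iter: int = 10_000,
    seed: int = 0,
    corrected: bool = False,
) -> BootstrapResult:
    """Permutation null for co-expression within physical clusters.

    ``expr_labels`` maps expressed family feature ids to their expression
    cluster label; features absent from the mapping are treated as not
    expressed.  The observed statistic is invariant under any bijective
    renaming of the labels.  The null permutes the labels uniformly among
    all expressed family features (clustered and isolated alike), so the
    marginal label frequencies are preserved.
    """
    cluster_of = res.cluster_of()
    ids = sorted(expr_labels)
    if not ids:
        raise ValueError("empty denominator: no expressed features given")
    label_codes = {lab: i for i, lab in enumerate(sorted(set(map(str, expr_labels.values()))))}
    labels = np.array([label_codes[str(expr_labels[i])] for i in ids], dtype=np.int64)
    cluster_ids = np.array([cluster_of.get(i, -1) for i in ids], dtype=np.int64)
    # re-code cluster ids densely for bincount
    uniq = np.unique(cluster_ids[cluster_ids >= 0])
    remap = {int(c): j for j, c in enumerate(uniq)}
    cluster_ids = np.array(
        [remap[int(c)] if c >= 0 else -1 for c in cluster_ids], dtype=np.int64
    )

    observed = shared_label_fraction(cluster_ids, labels)
    rng = np.random.default_rng(seed)
    null_values = np.empty(n_iter, dtype=float)
    for i in range(n_iter):
        null_values[i] = shared_label_fraction(cluster_ids, rng.permutation(labels))
    return BootstrapResult(
        observed=observed,
        null_values=null_values,
        p_value=_p_value(observed, null_values, corrected),
        n_iter=n_iter,
        seed=seed,
        corrected=corrected,
    )


def chi2_enrichment(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, without continuity
    correction.  Returns ``(statistic, dof, p_value)``."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if (arr < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
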