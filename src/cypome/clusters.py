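"""Detection of physical gene-family clusters.

Two consecutive family annotations on the same scaffold are linked when
they are separated by at most ``max_gap_bp`` (default 200 kb, measured
from the end of the first to the start of the second, clamped at zero for
overlapping annotations) and by at most ``max_intervening`` background
genes (default 8; a background gene intervenes when its start lies
strictly inside the open interval between the two).  Physical clusters
are the maximal chains of linked consecutive annotations with at least
``min_cluster_size`` members (default 2); all other family features are
isolated.

The linking rule is evaluated only between *consecutive* family
annotations in genome order, never across an intermediate family member.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, GenomeFeature

__all__ = [
    "ClusterParams",
    "PhysicalCluster",
    "ClusteringResult",
    "detect_clusters",
    "cluster_statistics",
    "clusters_to_frame",
    "write_cluster_bed",
    "GenomeArrays",
    "genome_arrays",
    "clustered_mask",
]


@dataclass(frozen=True, slots=True)
class ClusterParams:
    max_gap_bp: int = 200_000
    max_intervening: int = 8
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        for name in ("max_gap_bp", "max_intervening", "min_cluster_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True, slots=True)
class PhysicalCluster:
    cluster_id: int
    scaffold: str
    members: tuple[str, ...]  # feature ids in positional order
    span: tuple[int, int]  # start of first member, end of last member
    families: Counter = field(default_factory=Counter)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_families(self) -> int:
        return len(self.families)


@dataclass(slots=True)
class ClusteringResult:
    clusters: list[PhysicalCluster]
    isolated: set[str]
    params: ClusterParams

    @property
    def clustered_ids(self) -> set[str]:
        return {m for c in self.clusters for m in c.members}

    @property
    def n_clustered(self) -> int:
        return sum(c.size for c in self.clusters)

    @property
    def n_family(self) -> int:
        return self.n_clustered + len(self.isolated)

    @property
    def fraction_clustered(self) -> float:
        n = self.n_family
        return self.n_clustered / n if n else 0.0

    def cluster_of(self) -> dict[str, int]:
        """Map feature id -> cluster id (clustered members only)."""
        return {m: c.cluster_id for c in self.clusters for m in c.members}


# ---------------------------------------------------------------------------
# array core shared by detect_clusters and the resampling null
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class GenomeArrays:
    """Sorted coordinate arrays of a merged annotation.

    ``starts``/``ends`` follow the annotation's iteration order, which is
    contiguous per scaffold; ``slices`` maps each scaffold code to its
    half-open index range on those arrays.
    """

    starts: np.ndarray
    ends: np.ndarray
    codes: np.ndarray  # scaffold code per feature
    slices: list[tuple[int, int]]  # per code: (lo, hi) into starts/ends
    feature_ids: list[str]
    family_idx: np.ndarray  # global indices of real family features


def genome_arrays(ann: GenomeAnnotation) -> GenomeArrays:
    feats = ann.features
    rank = {s: i for i, s in enumerate(ann.scaffold_order)}
    starts = np.fromiter((f.start for f in feats), dtype=np.int64, count=len(feats))
    ends = np.fromiter((f.end for f in feats), dtype=np.int64, count=len(feats))
    codes = np.fromiter((rank[f.scaffold] for f in feats), dtype=np.int64, count=len(feats))
    if np.any(np.diff(codes) < 0) or np.any(
        (np.diff(codes) == 0) & (np.diff(starts) < 0)
    ):
        raise ValueError("annotation is not sorted by (scaffold, start)")
    slices: list[tuple[int, int]] = []
    bounds = np.searchsorted(codes, np.arange(len(ann.scaffold_order) + 1))
    for i in range(len(ann.scaffold_order)):
        slices.append((int(bounds[i]), int(bounds[i + 1])))
    family_idx = np.flatnonzero(
        np.fromiter((f.is_family for f in feats), dtype=bool, count=len(feats))
    )
    return GenomeArrays(
        starts=starts,
        ends=ends,
        codes=codes,
        slices=slices,
        feature_ids=[f.feature_id for f in feats],
        family_idx=family_idx,
    )


def _segments(
    arrays: GenomeArrays, idx_sorted: np.ndarray, params: ClusterParams
) -> list[np.ndarray]:
    """Maximal linked chains (>= min size) of the 'family' features given by
    ``idx_sorted``, a sorted array of global feature indices.

    All features of the annotation that are not in ``idx_sorted`` count as
    background for the intervening-gene rule.
    """
    k = idx_sorted.size
    if k == 0:
        return []
    codes = arrays.codes[idx_sorted]
    starts = arrays.starts[idx_sorted]
    ends = arrays.ends[idx_sorted]

    linked = np.zeros(max(k - 1, 0), dtype=bool)
    if k > 1:
        same = codes[1:] == codes[:-1]
        gaps = starts[1:] - ends[:-1]
        gap_ok = gaps <= params.max_gap_bp
        # intervening background genes per consecutive same-scaffold pair
        run_breaks = np.flatnonzero(codes[1:] != codes[:-1]) + 1
        run_starts = np.concatenate(([0], run_breaks))
        run_ends = np.concatenate((run_breaks, [k]))
        intervening = np.zeros(k - 1, dtype=np.int64)
        for lo_run, hi_run in zip(run_starts, run_ends):
            if hi_run - lo_run < 2:
                continue
            code = codes[lo_run]
            slo, shi = arrays.slices[code]
            scaffold_starts = arrays.starts[slo:shi]
            left = np.searchsorted(scaffold_starts, ends[lo_run : hi_run - 1], side="right")
            right = np.searchsorted(scaffold_starts, starts[lo_run + 1 : hi_run], side="left")
            count = right - left
            # subtract the sampled features themselves when two of them tie
            # on start inside the open interval (cannot happen for strictly
            # consecutive sampled features, but clamp defensively)
            np.maximum(count, 0, out=count)
            intervening[lo_run : hi_run - 1] = count
        linked = same & gap_ok & (intervening <= params.max_intervening)

    segments: list[np.ndarray] = []
    i = 0
    while i < k:
        j = i
        while j < k - 1 and linked[j]:
            j += 1
        if j - i + 1 >= params.min_cluster_size:
            segments.append(idx_sorted[i : j + 1])
        i = j + 1
    return segments


def clustered_mask(
    arrays: GenomeArrays, idx_sorted: np.ndarray, params: ClusterParams
) -> np.ndarray:
    """Boolean mask over ``idx_sorted``: True where the feature belongs to a
    physical cluster when ``idx_sorted`` plays the role of the family."""
    mask = np.zeros(idx_sorted.size, dtype=bool)
    pos = {int(g): i for i, g in enumerate(idx_sorted)}
    for seg in _segments(arrays, idx_sorted, params):
        for g in seg:
            mask[pos[int(g)]] = True
    return mask


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def detect_clusters(
    ann: GenomeAnnotation, params: ClusterParams | None = None
) -> ClusteringResult:
    """Detect maximal physical clusters of family features in a merged
    annotation (family + background genes interleaved in genome order).

    Clusters are numbered sequentially along the genome (scaffold order,
    then position).  Raises ``ValueError`` if the annotation is not sorted.
    """
    params = params or ClusterParams()
    arrays = genome_arrays(ann)
    segs = _segments(arrays, arrays.family_idx, params)
    clusters: list[PhysicalCluster] = []
    clustered: set[str] = set()
    feats = ann.features
    for num, seg in enumerate(segs, start=1):
        members = [feats[int(g)] for g in seg]
        fams = Counter(m.family for m in members if m.family is not None)
        clusters.append(
            PhysicalCluster(
                cluster_id=num,
                scaffold=members[0].scaffold,
                members=tuple(m.feature_id for m in members),
                span=(members[0].start, members[-1].end),
                families=fams,
            )
        )
        clustered.update(m.feature_id for m in members)
    isolated = {f.feature_id for f in feats if f.is_family} - clustered
    return ClusteringResult(clusters=clusters, isolated=isolated, params=params)


def cluster_statistics(res: ClusteringResult) -> dict:
    """Size distribution and composition summary of a clustering result."""
    sizes = [c.size for c in res.clusters]
    single_family = [c for c in res.clusters if c.n_families <= 1]
    per_scaffold: dict[str, dict[str, int]] = {}
    for c in res.clusters:
        per_scaffold.setdefault(c.scaffold, {"clustered": 0, "isolated": 0})
        per_scaffold[c.scaffold]["clustered"] += c.size
    return {
        "n_clusters": len(res.clusters),
        "sizes": sorted(sizes),
        "mean_size": float(np.mean(sizes)) if sizes else 0.0,
        "median_size": float(np.median(sizes)) if sizes else 0.0,
        "max_size": max(sizes) if sizes else 0,
        "n_clustered": res.n_clustered,
        "n_isolated": len(res.isolated),
        "fraction_clustered": res.fraction_clustered,
        "fraction_single_family": (
            len(single_family) / len(res.clusters) if res.clusters else 0.0
        ),
        "per_scaffold": per_scaffold,
    }


def clusters_to_frame(res: ClusteringResult) -> pd.DataFrame:
    """Cluster report table: one row per cluster (label, scaffold, span,
    size, members, family composition)."""
    rows = []
    for c in res.clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "scaffold": c.scaffold,
                "start": c.span[0],
                "end": c.span[1],
                "size": c.size,
                "n_families": c.n_families,
                "families": ",".join(f"{f}:{n}" for f, n in sorted(c.families.items())),
                "members": ",".join(c.members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "scaffold",
            "start",
            "end",
            "size",
            "n_families",
            "families",
            "members",
        ],
    )


def write_cluster_bed(res: ClusteringResult, path: str | Path) -> None:
    """Cluster spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in res.clusters:
            fh.write(f"{c.scaffold}\t{c.span[0] - 1}\t{c.span[1]}\tcluster_{c.cluster_id}\t{c.size}\t.\n")
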