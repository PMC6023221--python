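"""Paralog proximity: are a clustered gene's nearest paralogs in its own
physical cluster?

For every complete gene the paralogs are ranked by similarity (score
desc, identity desc, subject id asc) after applying the family-similarity
filter (identity >= 40 % over >= 70 % of the query).  The summary
statistic is, for k = 1, 2, 3, ..., the fraction of eligible clustered
genes whose k-th ranked paralog lies in the same physical cluster.
Eligible genes are clustered complete genes whose cluster holds at least
two complete genes; queries lacking a k-th hit stay in the denominator as
misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .clusters import ClusteringResult
from .similarity import PRESETS, filter_hits, _as_frame

__all__ = [
    "ParalogRanking",
    "rank_paralogs",
    "eligible_clustered_genes",
    "same_cluster_fraction",
    "paralog_link_table",
]


@dataclass(frozen=True, slots=True)
class ParalogRanking:
    query_id: str
    ranked_subjects: tuple[str, ...]  # self excluded, best first


def rank_paralogs(hits, queries: Iterable[str]) -> dict[str, ParalogRanking]:
    """Per-query paralog ranking over the complete-gene set.

    ``hits`` is a similarity table (list of hits or DataFrame); queries
    and subjects are restricted to ``queries`` (the complete genes),
    self-hits are dropped, the family-similarity filter is applied, and
    the survivors are ordered by (score desc, identity desc, subject asc).
    Every query receives a ranking, possibly empty.
    """
    queries = set(queries)
    frame, _ = _as_frame(hits)
    frame = frame[
        frame["query_id"].isin(queries) & frame["subject_id"].isin(queries)
    ]
    frame = filter_hits(frame, PRESETS["family_similarity"])
    frame = frame[frame["query_id"] != frame["subject_id"]]
    frame = frame.sort_values(
        ["query_id", "score", "pct_identity", "subject_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    rankings = {
        q: ParalogRanking(q, tuple(sub["subject_id"]))
        for q, sub in frame.groupby("query_id", sort=False)
    }
    for q in queries:
        rankings.setdefault(q, ParalogRanking(q, ()))
    return rankings


def eligible_clustered_genes(
    clustering: ClusteringResult, complete_genes: Iterable[str]
) -> set[str]:
    """Clustered complete genes in clusters holding >= 2 complete genes."""
    complete = set(complete_genes)
    eligible: set[str] = set()
    for c in clustering.clusters:
        members = [m for m in c.members if m in complete]
        if len(members) >= 2:
            eligible.update(members)
    return eligible


def same_cluster_fraction(
    rankings: Mapping[str, ParalogRanking],
    clustering: ClusteringResult,
    k: int,
    eligible: Iterable[str],
) -> float:
    """Fraction of eligible queries whose k-th ranked paralog exists and
    lies in the query's own physical cluster."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    eligible = set(eligible)
    if not eligible:
        return 0.0
    cluster_of = clustering.cluster_of()
    matches = 0
    for q in eligible:
        ranking = rankings.get(q)
        if ranking is None or len(ranking.ranked_subjects) < k:
            continue
        subject = ranking.ranked_subjects[k - 1]
        if cluster_of.get(subject) == cluster_of.get(q) and q in cluster_of:
            matches += 1
    return matches / len(eligible)


def paralog_link_table(
    rankings: Mapping[str, ParalogRanking],
    clustering: ClusteringResult,
    eligible: Iterable[str],
    max_rank: int = 3,
) -> pd.DataFrame:
    """Link table (query, subject, rank, same_cluster) for the first
    ``max_rank`` paralogs of every eligible query — a plottable substitute
    for circular similarity diagrams."""
    cluster_of = clustering.cluster_of()
    rows = []
    for q in sorted(set(eligible)):
        ranking = rankings.get(q)
        if ranking is None:
            continue
        for rank, subject in enumerate(ranking.ranked_subjects[:max_rank], start=1):
            rows.append(
                {
                    "query_id": q,
                    "subject_id": subject,
                    "rank": rank,
                    "query_cluster": cluster_of.get(q),
                    "subject_cluster": cluster_of.get(subject),
                    "same_cluster": cluster_of.get(q) is not None
                    and cluster_of.get(q) == cluster_of.get(subject),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "subject_id",
            "rank",
            "query_cluster",
            "subject_cluster",
            "same_cluster",
        ],
    )
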