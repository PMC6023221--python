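"""FPKM quantification, expressed-set definition, quantile expression
levels and per-category averages.

Expression is summarized as FPKM (fragments per kilobase of exon per
million mapped fragments):

    fpkm[g, e] = count[g, e] / ((exon_length[g] / 1e3) * (library_size[e] / 1e6))

A sequence counts as expressed when its FPKM is positive in at least two
experiments.  Experiments are grouped into six condition categories
(leaves, downy-mildew-infected leaves, powdery-mildew-infected leaves,
flowers, young berries, ripe berries) and a per-category mean FPKM is
computed for every sequence.  Pooled 33 % / 66 % quantiles of all
non-zero per-experiment FPKM values split the category averages into
four levels: none (exactly 0), low (0, q33], average (q33, q66] and high
(> q66).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationCategory

__all__ = [
    "CATEGORIES",
    "CountMatrix",
    "LevelThresholds",
    "compute_fpkm",
    "expressed_set",
    "category_average",
    "pooled_quantile_levels",
    "expression_summary",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_category_map",
    "write_category_map",
]

#: condition categories of the experiment design, in report order
CATEGORIES = (
    "leaves",
    "downy_mildew",
    "powdery_mildew",
    "flowers",
    "young_berries",
    "ripe_berries",
)

LEVELS = ("none", "low", "average", "high")


@dataclass(slots=True)
class CountMatrix:
    """Fragment counts (annotations x experiments) plus the normalization
    constants: per-annotation exon length (bp) and per-experiment library
    size (total counted fragments, genome-wide)."""

    counts: pd.DataFrame
    exon_lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.exon_lengths = self.exon_lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.exon_lengths.isna().any():
            missing = list(self.exon_lengths.index[self.exon_lengths.isna()][:5])
            raise ValueError(f"missing exon lengths for annotations {missing}")
        if self.library_sizes.isna().any():
            missing = list(self.library_sizes.index[self.library_sizes.isna()][:5])
            raise ValueError(f"missing library sizes for experiments {missing}")
        if (self.exon_lengths <= 0).any():
            raise ValueError("exon lengths must be positive")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("fragment counts must be non-negative")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, exon_lengths: pd.Series) -> "CountMatrix":
        """Library sizes taken as the column totals of the count matrix."""
        return cls(counts, exon_lengths, counts.sum(axis=0))


@dataclass(frozen=True, slots=True)
class LevelThresholds:
    q33: float
    q66: float

    def __post_init__(self) -> None:
        if not 0 < self.q33 <= self.q66:
            raise ValueError(f"require 0 < q33 <= q66, got {self.q33}, {self.q66}")


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """FPKM matrix; a cell is zero exactly when its count is zero."""
    kb = cm.exon_lengths.to_numpy(dtype=float) / 1e3
    millions = cm.library_sizes.to_numpy(dtype=float) / 1e6
    values = cm.counts.to_numpy(dtype=float) / np.outer(kb, millions)
    return pd.DataFrame(values, index=cm.counts.index, columns=cm.counts.columns)


def expressed_set(fpkm: pd.DataFrame, min_experiments: int = 2) -> set[str]:
    """Annotations with FPKM > 0 in at least ``min_experiments`` experiments."""
    n_pos = (fpkm > 0).sum(axis=1)
    return set(fpkm.index[n_pos >= min_experiments])


def category_average(
    fpkm: pd.DataFrame,
    cmap: Mapping[str, str],
    categories: Iterable[str] = CATEGORIES,
) -> pd.DataFrame:
    """Arithmetic mean FPKM per condition category (columns ordered as
    ``categories``).  Every category must have at least one experiment."""
    categories = list(categories)
    missing = [e for e in fpkm.columns if e not in cmap]
    if missing:
        raise ValueError(f"experiments without a category: {missing[:5]}")
    unknown = sorted(set(cmap.values()) - set(categories))
    if unknown:
        raise ValueError(f"unknown categories in map: {unknown}")
    out = {}
    for cat in categories:
        exps = [e for e in fpkm.columns if cmap[e] == cat]
        if not exps:
            raise ValueError(f"category {cat!r} has no experiments")
        out[cat] = fpkm[exps].mean(axis=1)
    return pd.DataFrame(out, index=fpkm.index, columns=categories)


def pooled_quantile_levels(
    fpkm: pd.DataFrame,
    category_avgs: pd.DataFrame,
    probs: tuple[float, float] = (0.33, 0.66),
    method: str = "linear",
) -> tuple[LevelThresholds, pd.DataFrame]:
    """Assign one of four expression levels to every category average.

    Thresholds are the ``probs`` quantiles (linear interpolation of order
    statistics by default) of all non-zero per-experiment FPKM values,
    pooled across annotations and experiments; they are then applied to
    the category averages with right-closed intervals:
    0 -> none, (0, q33] -> low, (q33, q66] -> average, > q66 -> high.
    """
    values = fpkm.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("no non-zero FPKM values to compute quantiles from")
    q33, q66 = np.quantile(nonzero, probs, method=method)
    thresholds = LevelThresholds(float(q33), float(q66))
    avg = category_avgs.to_numpy(dtype=float)
    levels = np.select(
        [avg == 0, avg <= thresholds.q33, avg <= thresholds.q66],
        ["none", "low", "average"],
        default="high",
    )
    return thresholds, pd.DataFrame(
        levels, index=category_avgs.index, columns=category_avgs.columns
    )


# classes the expression summary reports: putative pseudogenes are pooled
# with pseudogenes, mirroring how degenerate copies are summarized
DEFAULT_CLASS_OF: Mapping[AnnotationCategory, str] = {
    AnnotationCategory.GENE: "gene",
    AnnotationCategory.PARTIAL: "partial",
    AnnotationCategory.PUTATIVE_PSEUDOGENE: "pseudogene",
    AnnotationCategory.PSEUDOGENE: "pseudogene",
}


def expression_summary(
    fpkm: pd.DataFrame,
    expressed: Iterable[str],
    categories: Mapping[str, AnnotationCategory],
    class_of: Mapping[AnnotationCategory, str] = DEFAULT_CLASS_OF,
) -> pd.DataFrame:
    """Mean and median FPKM per annotation class, over all (expressed
    annotation, experiment) cells."""
    expressed = [a for a in fpkm.index if a in set(expressed)]
    rows = []
    by_class: dict[str, list[str]] = {}
    for a in expressed:
        cat = categories.get(a)
        if cat is None or cat not in class_of:
            continue
        by_class.setdefault(class_of[cat], []).append(a)
    for cls in sorted(by_class):
        cells = fpkm.loc[by_class[cls]].to_numpy(dtype=float).ravel()
        rows.append(
            {
                "class": cls,
                "n_expressed": len(by_class[cls]),
                "mean_fpkm": float(np.mean(cells)),
                "median_fpkm": float(np.median(cells)),
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_expressed", "mean_fpkm", "median_fpkm"])


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")


def read_category_map(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["experiment"], frame["category"]))


def write_category_map(cmap: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"experiment": list(cmap), "category": [cmap[e] for e in cmap]}
    ).to_csv(path, sep="\t", index=False)
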