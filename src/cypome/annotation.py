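"""Genome feature tables and GFF3 I/O.

A :class:`GenomeAnnotation` is a positionally ordered table of gene-level
features.  Features belonging to the gene family under study (cytochrome
P450s in the original use case) carry one of four annotation categories —
complete ``gene``, ``partial`` gene, ``putative_pseudogene`` or
``pseudogene`` — while all other genes of the genome are ``background``.
Physical-cluster detection and the resampling tests downstream rely on the
ordering invariant enforced here: features are iterated scaffold by
scaffold, ascending by start coordinate (ties broken by end, then id).

Coordinates are 1-based and inclusive, exactly as stored in GFF3.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "AnnotationCategory",
    "GenomeFeature",
    "GenomeAnnotation",
    "read_gff3",
    "write_gff3",
    "merge_annotations",
    "category_counts",
]


class AnnotationCategory(str, enum.Enum):
    """Annotation status of a feature.

    ``gene``
        complete gene: start codon, stop codon, canonical intron borders.
    ``partial``
        annotation interrupted by (or containing) an assembly gap.
    ``putative_pseudogene``
        gene-like structure broken by exactly one point mutation, which
        may be a sequencing/assembly artefact.
    ``pseudogene``
        degenerate copy: multiple disabling mutations or a fragment.
    ``background``
        any genome gene that is not a member of the studied family.
    """

    GENE = "gene"
    PARTIAL = "partial"
    PUTATIVE_PSEUDOGENE = "putative_pseudogene"
    PSEUDOGENE = "pseudogene"
    BACKGROUND = "background"


# accepted spellings in GFF3 ``category=`` attributes
_CATEGORY_ALIASES: Mapping[str, AnnotationCategory] = {
    "gene": AnnotationCategory.GENE,
    "partial": AnnotationCategory.PARTIAL,
    "putative_pseudogene": AnnotationCategory.PUTATIVE_PSEUDOGENE,
    "pseudogene?": AnnotationCategory.PUTATIVE_PSEUDOGENE,
    "pseudogene": AnnotationCategory.PSEUDOGENE,
    "background": AnnotationCategory.BACKGROUND,
}

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, slots=True)
class GenomeFeature:
    """One gene-level feature with 1-based inclusive coordinates."""

    feature_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    category: AnnotationCategory = AnnotationCategory.BACKGROUND
    family: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.feature_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.feature_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"{self.feature_id}: invalid strand {self.strand!r}")

    @property
    def is_family(self) -> bool:
        """True for members of the studied family (any non-background category)."""
        return self.category is not AnnotationCategory.BACKGROUND

    def sort_key(self, scaffold_rank: Mapping[str, int]) -> tuple:
        return (scaffold_rank[self.scaffold], self.start, self.end, self.feature_id)


class GenomeAnnotation:
    """Positionally ordered collection of :class:`GenomeFeature`.

    Parameters
    ----------
    features
        Any iterable of features; they are sorted on construction.
    scaffold_order
        Preferred scaffold ordering (e.g. chr1..chr19, then unanchored
        scaffolds).  Scaffolds present in the data but absent from this
        list are appended in lexicographic order.
    """

    def __init__(
        self,
        features: Iterable[GenomeFeature] = (),
        scaffold_order: Iterable[str] | None = None,
    ) -> None:
        feats = list(features)
        seen: dict[str, GenomeFeature] = {}
        for f in feats:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature_id {f.feature_id!r}")
            seen[f.feature_id] = f

        order = list(scaffold_order) if scaffold_order is not None else []
        known = set(order)
        extra = sorted({f.scaffold for f in feats} - known)
        order += extra
        rank = {s: i for i, s in enumerate(order)}
        feats.sort(key=lambda f: f.sort_key(rank))

        self._features: tuple[GenomeFeature, ...] = tuple(feats)
        self._by_id = seen
        self.scaffold_order: tuple[str, ...] = tuple(order)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[GenomeFeature]:
        return iter(self._features)

    def __getitem__(self, feature_id: str) -> GenomeFeature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    @property
    def features(self) -> tuple[GenomeFeature, ...]:
        return self._features

    @property
    def family_features(self) -> tuple[GenomeFeature, ...]:
        return tuple(f for f in self._features if f.is_family)

    @property
    def background_features(self) -> tuple[GenomeFeature, ...]:
        return tuple(f for f in self._features if not f.is_family)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self._features],
                "scaffold": [f.scaffold for f in self._features],
                "start": [f.start for f in self._features],
                "end": [f.end for f in self._features],
                "strand": [f.strand for f in self._features],
                "category": [f.category.value for f in self._features],
                "family": [f.family for f in self._features],
                "name": [f.name for f in self._features],
            }
        )


def read_gff3(
    path: str | Path,
    family_tag: str = "family",
    scaffold_order: Iterable[str] | None = None,
) -> GenomeAnnotation:
    """Read gene-level records of a GFF3 file into a :class:`GenomeAnnotation`.

    Only top-level records (those without a ``Parent`` attribute) are kept,
    one :class:`GenomeFeature` each.  The annotation category is taken from
    the ``category=`` attribute (``pseudogene?`` is accepted as an alias of
    ``putative_pseudogene``); records without it default to ``background``
    unless the family attribute is present, in which case they default to
    complete ``gene``.  The family is read from ``family_tag`` and the
    display name from ``Name``.

    Raises
    ------
    ValueError
        On malformed coordinates or a duplicate id, with the line number.
    """
    feats: list[GenomeFeature] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            try:
                rec = feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils message varies
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record: {exc}") from exc
            if "Parent" in rec.attributes:
                continue
            fid = rec.attributes.get("ID", [rec.id or ""])[0]
            if not fid:
                raise ValueError(f"{path}:{lineno}: record without an ID attribute")
            if fid in ids:
                raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            family = rec.attributes.get(family_tag, [None])[0]
            raw_cat = rec.attributes.get("category", [None])[0]
            if raw_cat is None:
                category = (
                    AnnotationCategory.GENE if family else AnnotationCategory.BACKGROUND
                )
            else:
                try:
                    category = _CATEGORY_ALIASES[raw_cat]
                except KeyError:
                    raise ValueError(
                        f"{path}:{lineno}: unknown category {raw_cat!r}"
                    ) from None
            if rec.end < rec.start:
                raise ValueError(
                    f"{path}:{lineno}: end ({rec.end}) < start ({rec.start})"
                )
            try:
                feats.append(
                    GenomeFeature(
                        feature_id=fid,
                        scaffold=rec.seqid,
                        start=int(rec.start),
                        end=int(rec.end),
                        strand=rec.strand if rec.strand in _STRANDS else ".",
                        category=category,
                        family=family,
                        name=rec.attributes.get("Name", [None])[0],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            ids.add(fid)
    return GenomeAnnotation(feats, scaffold_order=scaffold_order)


def write_gff3(ann: GenomeAnnotation, path: str | Path, family_tag: str = "family") -> None:
    """Write an annotation as GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ann:
            attrs = [f"ID={f.feature_id}", f"category={f.category.value}"]
            if f.family:
                attrs.append(f"{family_tag}={f.family}")
            if f.name:
                attrs.append(f"Name={f.name}")
            fh.write(
                "\t".join(
                    [
                        f.scaffold,
                        "cypome",
                        "gene",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def merge_annotations(
    background: GenomeAnnotation, family: GenomeAnnotation
) -> GenomeAnnotation:
    """Union of a background genome annotation and a family annotation.

    Background features are (re-)flagged ``background``; family features
    keep their category and family string.  Feature id sets must be
    disjoint.  The merged table is re-sorted, which is the ordering used by
    every physical-cluster computation (the intervening-gene rule needs
    background and family genes interleaved in genome order).
    """
    collisions = {f.feature_id for f in background} & {f.feature_id for f in family}
    if collisions:
        some = sorted(collisions)[:5]
        raise ValueError(
            f"feature ids present in both background and family annotations: {some}"
        )
    bg = [
        replace(f, category=AnnotationCategory.BACKGROUND, family=None)
        for f in background
    ]
    order = list(background.scaffold_order)
    order += [s for s in family.scaffold_order if s not in set(order)]
    return GenomeAnnotation(bg + list(family), scaffold_order=order)


def category_counts(ann: GenomeAnnotation, by: str = "category") -> pd.Series:
    """Count features by ``category``, ``scaffold`` or ``family``.

    Returns a Series whose values sum to ``len(ann)``; for ``family``,
    features without a family string are counted under ``None``.
    """
    if by not in {"category", "scaffold", "family"}:
        raise ValueError(f"unsupported grouping {by!r}")
    if by == "category":
        keys = [f.category.value for f in ann]
    elif by == "scaffold":
        keys = [f.scaffold for f in ann]
    else:
        keys = [f.family for f in ann]
    counts = pd.Series(keys, dtype=object).value_counts(dropna=False).sort_index()
    counts.index.name = by
    counts.name = "count"
    return counts
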