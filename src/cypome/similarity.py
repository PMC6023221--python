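"""Similarity hits, threshold filters, naming and pairwise identity.

Family membership of plant P450s is conventionally defined by protein
identity (members of one CYP family share >= 40 % identity).  The study
pipeline applies a small set of fixed identity/coverage filters to BLAST
style hit tables:

``family_similarity``
    identity >= 40 % over >= 70 % of the query length — within/between
    cluster similarity and paralog ranking.
``pseudogene_validation``
    identity >= 50 % over >= 30 % of the query length — keeps candidate
    pseudogenes resembling a complete family gene.
``tblastn_same_species``
    identity >= 70 % and alignment >= 50 residues — parsing TBLASTN hits
    of same-species query sets.
``tblastn_outgroup``
    identity >= 50 % and alignment >= 50 residues — parsing TBLASTN hits
    of an outgroup (e.g. Arabidopsis) query set.

Hit tables may be lists of :class:`SimilarityHit` or pandas DataFrames
with the same column names; operations return the kind they were given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "HIT_COLUMNS",
    "SimilarityHit",
    "FilterPreset",
    "PRESETS",
    "NamingResult",
    "hits_to_frame",
    "frame_to_hits",
    "read_blast_tab",
    "filter_hits",
    "assign_cyp_name",
    "validate_pseudogene",
    "pairwise_identity",
    "next_member_name",
]

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "query_length",
    "subject_length",
    "score",
]


@dataclass(frozen=True, slots=True)
class SimilarityHit:
    """One pairwise alignment record (best HSP per pair).

    ``query_coverage`` is the alignment length over the query length; it
    may exceed 1 when the alignment contains gaps and is deliberately not
    clamped, so imported tables must already be collapsed to the best HSP
    per pair.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    query_length: int
    subject_length: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")

    @property
    def query_coverage(self) -> float:
        if self.query_length <= 0:
            raise ValueError(f"{self.query_id}: query_length must be positive")
        return self.aln_length / self.query_length


@dataclass(frozen=True, slots=True)
class FilterPreset:
    """Identity / coverage / alignment-length cutoffs for hit filtering."""

    name: str
    min_identity: float  # percent
    min_coverage: float  # fraction of query length
    min_aln_length: int  # residues; 0 if unused


PRESETS: Mapping[str, FilterPreset] = {
    "family_similarity": FilterPreset("family_similarity", 40.0, 0.70, 0),
    "pseudogene_validation": FilterPreset("pseudogene_validation", 50.0, 0.30, 0),
    "tblastn_same_species": FilterPreset("tblastn_same_species", 70.0, 0.0, 50),
    "tblastn_outgroup": FilterPreset("tblastn_outgroup", 50.0, 0.0, 50),
}

# thresholds of the naming rule: keep the registry name above 95 % identity,
# otherwise assign the best hit's family down to the 40 % family boundary
NAME_KEEP_IDENTITY = 95.0
FAMILY_MIN_IDENTITY = 40.0


@dataclass(frozen=True, slots=True)
class NamingResult:
    query_id: str
    assigned_name: str | None
    assigned_family: str | None
    status: str  # kept_name | family_assigned | novel


def hits_to_frame(hits: Iterable[SimilarityHit]) -> pd.DataFrame:
    rows = [
        (h.query_id, h.subject_id, h.pct_identity, h.aln_length,
         h.query_length, h.subject_length, h.score)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(frame: pd.DataFrame) -> list[SimilarityHit]:
    return [
        SimilarityHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            pct_identity=float(r.pct_identity),
            aln_length=int(r.aln_length),
            query_length=int(r.query_length),
            subject_length=int(r.subject_length),
            score=float(r.score),
        )
        for r in frame.itertuples(index=False)
    ]


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read a BLAST tabular file (outfmt 6 dialect).

    Expected columns: ``qseqid sseqid pident length qlen slen bitscore``,
    tab-separated, no header.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["qseqid", "sseqid", "pident", "length", "qlen", "slen", "bitscore"],
        comment="#",
    )
    frame.columns = HIT_COLUMNS
    return frame


def _as_frame(hits) -> tuple[pd.DataFrame, bool]:
    if isinstance(hits, pd.DataFrame):
        return hits, True
    return hits_to_frame(hits), False


def filter_hits(hits, preset: FilterPreset | str):
    """Keep hits passing a preset's identity, coverage and length cutoffs.

    All three conditions must hold: ``pct_identity >= min_identity``,
    ``aln_length / query_length >= min_coverage`` and
    ``aln_length >= min_aln_length``.  Input order is preserved.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    frame, was_frame = _as_frame(hits)
    if len(frame) == 0:
        return frame if was_frame else []
    if (frame["query_length"] <= 0).any():
        bad = frame.loc[frame["query_length"] <= 0, "query_id"].iloc[0]
        raise ValueError(f"non-positive query_length for query {bad!r}")
    keep = (
        (frame["pct_identity"] >= preset.min_identity)
        & (frame["aln_length"] / frame["query_length"] >= preset.min_coverage)
        & (frame["aln_length"] >= preset.min_aln_length)
    )
    out = frame.loc[keep]
    return out if was_frame else frame_to_hits(out)


def rank_hits(hits: Sequence[SimilarityHit]) -> list[SimilarityHit]:
    """Deterministic best-hit order: score desc, identity desc, subject asc."""
    return sorted(hits, key=lambda h: (-h.score, -h.pct_identity, h.subject_id))


def assign_cyp_name(
    query_id: str,
    hits: Sequence[SimilarityHit],
    registry: Mapping[str, tuple[str, str]],
) -> NamingResult:
    """Name a new sequence against a registry of already-named members.

    The registry maps subject ids to ``(name, family)``.  If the best hit
    (score desc, identity desc, subject asc) exceeds 95 % identity the
    registry name is kept; at 40–95 % identity the sequence is assigned
    the best hit's family only; below the family boundary (or with no
    hits) it is novel.
    """
    ranked = rank_hits(hits)
    if not ranked:
        return NamingResult(query_id, None, None, "novel")
    best = ranked[0]
    try:
        name, family = registry[best.subject_id]
    except KeyError:
        raise KeyError(f"subject {best.subject_id!r} missing from registry") from None
    if best.pct_identity > NAME_KEEP_IDENTITY:
        return NamingResult(query_id, name, family, "kept_name")
    if best.pct_identity >= FAMILY_MIN_IDENTITY:
        return NamingResult(query_id, None, family, "family_assigned")
    return NamingResult(query_id, None, None, "novel")


def validate_pseudogene(hits) -> bool:
    """True iff any hit against the complete-gene set passes the
    pseudogene-validation cutoffs (identity >= 50 %, coverage >= 30 %)."""
    kept = filter_hits(hits, PRESETS["pseudogene_validation"])
    return len(kept) > 0


_AA = set("ACDEFGHIKLMNPQRSTVWYXBZ")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> SimilarityHit:
    """Global protein alignment identity (BLOSUM62, affine gaps -10/-0.5).

    Percent identity is matches over alignment columns (gap columns
    included).  Deterministic for fixed gap parameters: the first optimal
    alignment of the dynamic program is used.
    """
    for label, seq in ((id_a, seq_a), (id_b, seq_b)):
        if not seq:
            raise ValueError(f"empty sequence for {label!r}")
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValueError(f"{label!r}: non-amino-acid letters {sorted(bad)}")
    aligner = _make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    pct = 100.0 * counts.identities / columns if columns else 0.0
    return SimilarityHit(
        query_id=id_a,
        subject_id=id_b,
        pct_identity=pct,
        aln_length=int(columns),
        query_length=len(seq_a),
        subject_length=len(seq_b),
        score=float(aln.score),
    )


def next_member_name(subfamily: str, existing: Iterable[str]) -> str:
    """Next free member name within a subfamily, e.g. CYP76F -> CYP76F15.

    Official CYP nomenclature is curated externally; this helper only
    proposes a provisional label for novel sequences.
    """
    top = 0
    for name in existing:
        if name.startswith(subfamily):
            suffix = name[len(subfamily):]
            digits = ""
            for ch in suffix:
                if ch.isdigit():
                    digits += ch
                else:
                    break
            if digits:
                top = max(top, int(digits))
    return f"{subfamily}{top + 1}"
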