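"""Synthetic genomes, similarity tables and expression matrices.

The generator emulates the statistical structure the analysis assumes,
with a full ground-truth record, so that every downstream stage can be
verified without external data:

* a background genome of ~30,000 genes spread over multiple scaffolds
  with exponential intergenic spacing;
* a gene family grown from founders by tandem, segmental (2–4 gene
  blocks) and dispersed duplications, with per-event identity decay and
  optional pseudogenization of the copies;
* similarity hits for every family pair, with identity derived from the
  duplication lineage (100 minus the summed decays along the path,
  floored) and alignment coverage drawn uniformly;
* expression archetypes per lineage — one preferred condition category
  expressed at a log-normal magnitude, baseline elsewhere — inherited by
  duplicates with probability ``p_inherit_profile``, plus multiplicative
  noise and Poisson fragment counts.

Identity is modelled as additive decay on lineage paths rather than by
explicit sequence evolution; that is sufficient to exercise the 40/70
and 95 % thresholds.  :func:`simulate_proteins` optionally mutates real
residues for alignment-level tests.

Setting ``noise_cv = 0`` produces the noise-free limit (exact expected
counts, no Poisson sampling), which supports exact assertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationCategory, GenomeAnnotation, GenomeFeature, merge_annotations
from .expression import CATEGORIES, CountMatrix
from .similarity import HIT_COLUMNS

__all__ = ["SimConfig", "TruthRecord", "simulate_genome", "simulate_expression", "simulate_proteins"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Generator parameters.

    Defaults emulate the grapevine study system: a reference annotation
    of ~30,000 genes on 19 chromosomes and a family of ~580 sequences in
    ~48 families, about half of them degenerate copies, profiled over
    six condition categories (~60 experiments).
    """

    seed: int = 0
    # genome
    n_scaffolds: int = 19
    n_background_genes: int = 29_971
    intergenic_mean_bp: float = 12_000.0
    gene_length_range: tuple[int, int] = (1_000, 6_000)
    # family growth
    n_founders: int = 48
    dups_per_founder: float = 10.0
    p_tandem: float = 0.6
    p_segmental: float = 0.2
    max_gap_bp: int = 200_000
    tandem_max_intervening: int = 3
    identity_decay_range: tuple[float, float] = (2.0, 10.0)
    identity_floor: float = 20.0
    cross_family_identity_range: tuple[float, float] = (20.0, 35.0)
    coverage_range: tuple[float, float] = (0.6, 1.0)
    p_pseudogenize: float = 0.5
    # weights for pseudogene / putative_pseudogene / partial among
    # pseudogenized copies
    pseudo_weights: tuple[float, float, float] = (0.90, 0.04, 0.06)
    protein_length_range: tuple[int, int] = (350, 600)
    # expression
    archetype_log_mu: float = 1.5
    archetype_log_sigma: float = 1.0
    baseline_fpkm: float = 0.3
    p_inherit_profile: float = 0.75
    noise_cv: float = 0.3
    n_experiments_per_category: int = 10
    library_size_mean: float = 2.0e7
    exon_length_range: tuple[int, int] = (900, 1_800)
    pseudogene_expression_prob: float = 0.3
    pseudogene_expression_scale: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_tandem", "p_segmental", "p_pseudogenize", "p_inherit_profile",
                     "pseudogene_expression_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_scaffolds", "n_background_genes", "n_founders"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(slots=True)
class TruthRecord:
    """Ground truth emitted alongside a simulated genome."""

    members: list[str]  # family feature ids in creation order
    founder_of: dict[str, str]
    lineage: dict[str, tuple[str, float]]  # child -> (parent, identity decay)
    true_cluster: dict[str, int]  # feature id -> intended physical cluster
    category: dict[str, AnnotationCategory]
    archetype: dict[str, tuple[str, float]]  # feature id -> (category, magnitude)
    exon_length: dict[str, int]
    protein_length: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "members": self.members,
            "founder_of": self.founder_of,
            "lineage": {k: [p, d] for k, (p, d) in self.lineage.items()},
            "true_cluster": self.true_cluster,
            "category": {k: v.value for k, v in self.category.items()},
            "archetype": {k: [c, m] for k, (c, m) in self.archetype.items()},
            "exon_length": self.exon_length,
            "protein_length": self.protein_length,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass(slots=True)
class _Member:
    member_id: str
    family: str
    founder: str
    scaffold: int
    start: int
    end: int
    category: AnnotationCategory
    true_cluster: int


def _place_background(cfg: SimConfig, rng: np.random.Generator):
    """Exponentially spaced background genes; returns per-scaffold start and
    end arrays plus scaffold lengths."""
    per = np.full(cfg.n_scaffolds, cfg.n_background_genes // cfg.n_scaffolds, dtype=int)
    per[: cfg.n_background_genes % cfg.n_scaffolds] += 1
    starts, ends, lengths = [], [], []
    lo, hi = cfg.gene_length_range
    for m in per:
        glen = rng.integers(lo, hi + 1, size=m)
        gaps = rng.exponential(cfg.intergenic_mean_bp, size=m).astype(np.int64) + 1
        cum = np.cumsum(gaps + glen)
        ends.append(cum)
        starts.append(cum - glen + 1)
        lengths.append(int(cum[-1] + cfg.intergenic_mean_bp) if m else 1_000_000)
    return starts, ends, np.array(lengths, dtype=np.int64)


def simulate_genome(
    cfg: SimConfig,
) -> tuple[GenomeAnnotation, pd.DataFrame, TruthRecord]:
    """Simulate a merged genome annotation, a similarity-hit table and the
    ground truth.

    Returns the merged (background + family) :class:`GenomeAnnotation`,
    an all-pairs hit DataFrame and a :class:`TruthRecord`.  Identical
    seeds give identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    bg_starts, bg_ends, scaffold_len = _place_background(cfg, rng)

    members: list[_Member] = []
    lineage: dict[str, tuple[str, float]] = {}
    founder_of: dict[str, str] = {}
    archetype: dict[str, tuple[str, float]] = {}
    next_cluster = 0
    glo, ghi = cfg.gene_length_range

    def draw_archetype() -> tuple[str, float]:
        cat = CATEGORIES[rng.integers(0, len(CATEGORIES))]
        mag = float(rng.lognormal(cfg.archetype_log_mu, cfg.archetype_log_sigma))
        return cat, mag

    def draw_category() -> AnnotationCategory:
        if rng.random() < cfg.p_pseudogenize:
            which = rng.choice(3, p=np.array(cfg.pseudo_weights) / sum(cfg.pseudo_weights))
            return (
                AnnotationCategory.PSEUDOGENE,
                AnnotationCategory.PUTATIVE_PSEUDOGENE,
                AnnotationCategory.PARTIAL,
            )[which]
        return AnnotationCategory.GENE

    def tandem_start(scaffold: int, after_end: int) -> int:
        """Start position downstream of ``after_end`` with a sub-threshold
        gap and at most ``tandem_max_intervening`` background genes."""
        gap = float(rng.uniform(1_000, cfg.max_gap_bp / 2))
        candidate = after_end + int(gap)
        bgs = bg_starts[scaffold]
        i0 = int(np.searchsorted(bgs, after_end, side="right"))
        allowed = int(rng.integers(0, cfg.tandem_max_intervening + 1))
        if i0 + allowed < len(bgs):
            limit = int(bgs[i0 + allowed]) - 1
            candidate = min(candidate, limit)
        return max(candidate, after_end + 1)

    for fi in range(cfg.n_founders):
        family = f"CYPS{fi + 1:02d}"
        founder_id = f"{family}m001"
        counter = 1
        scaffold = int(rng.integers(0, cfg.n_scaffolds))
        start = int(rng.integers(1, max(int(scaffold_len[scaffold]), 2)))
        length = int(rng.integers(glo, ghi + 1))
        founder = _Member(
            member_id=founder_id,
            family=family,
            founder=founder_id,
            scaffold=scaffold,
            start=start,
            end=start + length - 1,
            category=AnnotationCategory.GENE,
            true_cluster=next_cluster,
        )
        next_cluster += 1
        founder_of[founder_id] = founder_id
        archetype[founder_id] = draw_archetype()
        fam_members = [founder]

        n_events = int(rng.poisson(cfg.dups_per_founder))
        for _ in range(n_events):
            ordered = sorted(fam_members, key=lambda m: (m.scaffold, m.start))
            if rng.random() < cfg.p_segmental and len(ordered) >= 2:
                size = int(rng.integers(2, 5))
                i = int(rng.integers(0, len(ordered)))
                block = [ordered[i]]
                for m in ordered[i + 1 :]:
                    if len(block) >= size or m.scaffold != block[0].scaffold:
                        break
                    block.append(m)
            else:
                block = [ordered[int(rng.integers(0, len(ordered)))]]
            anchor = block[-1]
            decay = float(rng.uniform(*cfg.identity_decay_range))
            if rng.random() < cfg.p_tandem:
                scaffold_new = anchor.scaffold
                base = tandem_start(scaffold_new, anchor.end)
                cluster_new = anchor.true_cluster
            else:
                scaffold_new = int(rng.integers(0, cfg.n_scaffolds))
                base = int(rng.integers(1, max(int(scaffold_len[scaffold_new]), 2)))
                cluster_new = next_cluster
                next_cluster += 1
            offset0 = block[0].start
            for parent in block:
                counter += 1
                child_id = f"{family}m{counter:03d}"
                start_new = base + (parent.start - offset0)
                child = _Member(
                    member_id=child_id,
                    family=family,
                    founder=founder_id,
                    scaffold=scaffold_new,
                    start=start_new,
                    end=start_new + (parent.end - parent.start),
                    category=draw_category(),
                    true_cluster=cluster_new,
                )
                fam_members.append(child)
                lineage[child_id] = (parent.member_id, decay)
                founder_of[child_id] = founder_id
                if rng.random() < cfg.p_inherit_profile:
                    archetype[child_id] = archetype[parent.member_id]
                else:
                    archetype[child_id] = draw_archetype()
        members.extend(fam_members)

    # ---- feature tables ---------------------------------------------------
    scaffold_names = [f"chr{i + 1:02d}" for i in range(cfg.n_scaffolds)]
    bg_feats = []
    counter = 0
    for s in range(cfg.n_scaffolds):
        for st, en in zip(bg_starts[s], bg_ends[s]):
            counter += 1
            bg_feats.append(
                GenomeFeature(
                    feature_id=f"bg{counter:06d}",
                    scaffold=scaffold_names[s],
                    start=int(st),
                    end=int(en),
                    strand="+",
                )
            )
    fam_feats = [
        GenomeFeature(
            feature_id=m.member_id,
            scaffold=scaffold_names[m.scaffold],
            start=m.start,
            end=m.end,
            strand="+" if rng.random() < 0.5 else "-",
            category=m.category,
            family=m.family,
            name=m.member_id,
        )
        for m in members
    ]
    background = GenomeAnnotation(bg_feats, scaffold_order=scaffold_names)
    family_ann = GenomeAnnotation(fam_feats, scaffold_order=scaffold_names)
    merged = merge_annotations(background, family_ann)

    # ---- truth ------------------------------------------------------------
    ids = [m.member_id for m in members]
    plo, phi = cfg.protein_length_range
    elo, ehi = cfg.exon_length_range
    protein_length = {i: int(rng.integers(plo, phi + 1)) for i in ids}
    exon_length = {i: int(rng.integers(elo, ehi + 1)) for i in ids}
    truth = TruthRecord(
        members=ids,
        founder_of=founder_of,
        lineage=lineage,
        true_cluster={m.member_id: m.true_cluster for m in members},
        category={m.member_id: m.category for m in members},
        archetype=archetype,
        exon_length=exon_length,
        protein_length=protein_length,
    )

    hits = _pairwise_hits(cfg, rng, truth)
    return merged, hits, truth


def lineage_identity(truth: TruthRecord, id_a: str, id_b: str, floor: float = 20.0) -> float:
    """Identity between two members of one lineage: 100 minus the summed
    per-edge decays along the tree path, floored."""
    def path_to_root(i: str) -> list[tuple[str, float]]:
        out = []
        while i in truth.lineage:
            parent, decay = truth.lineage[i]
            out.append((i, decay))
            i = parent
        out.append((i, 0.0))
        return out

    pa = path_to_root(id_a)
    pb = path_to_root(id_b)
    ancestors = {node: sum(d for _, d in pa[:k]) for k, (node, _) in enumerate(pa)}
    total = None
    acc = 0.0
    for k, (node, _) in enumerate(pb):
        acc = sum(d for _, d in pb[:k])
        if node in ancestors:
            total = ancestors[node] + acc
            break
    if total is None:
        raise ValueError(f"{id_a} and {id_b} share no ancestor")
    return max(floor, 100.0 - total)


def _pairwise_hits(
    cfg: SimConfig, rng: np.random.Generator, truth: TruthRecord
) -> pd.DataFrame:
    """All-pairs hit table: lineage-derived identity within a founder
    lineage, a uniform sub-family-threshold identity across lineages."""
    ids = truth.members
    n = len(ids)
    if n < 2:
        return pd.DataFrame(columns=HIT_COLUMNS)
    founders = np.array([truth.founder_of[i] for i in ids])
    identity = rng.uniform(*cfg.cross_family_identity_range, size=(n, n))
    identity = np.triu(identity, 1)
    identity = identity + identity.T
    # overwrite within-lineage blocks with path identities
    for founder in np.unique(founders):
        idx = np.flatnonzero(founders == founder)
        for ai in range(len(idx)):
            for bi in range(ai + 1, len(idx)):
                val = lineage_identity(
                    truth, ids[idx[ai]], ids[idx[bi]], floor=cfg.identity_floor
                )
                identity[idx[ai], idx[bi]] = val
                identity[idx[bi], idx[ai]] = val
    coverage = rng.uniform(*cfg.coverage_range, size=(n, n))
    coverage = np.triu(coverage, 1)
    coverage = coverage + coverage.T

    qlen = np.array([truth.protein_length[i] for i in ids], dtype=np.int64)
    qi, si = np.nonzero(~np.eye(n, dtype=bool))
    aln = np.maximum(1, np.rint(coverage[qi, si] * qlen[qi]).astype(np.int64))
    pct = identity[qi, si]
    score = np.round(2.0 * pct / 100.0 * aln, 1)
    ids_arr = np.array(ids)
    return pd.DataFrame(
        {
            "query_id": ids_arr[qi],
            "subject_id": ids_arr[si],
            "pct_identity": pct,
            "aln_length": aln,
            "query_length": qlen[qi],
            "subject_length": qlen[si],
            "score": score,
        }
    )


def simulate_expression(
    cfg: SimConfig, truth: TruthRecord
) -> tuple[CountMatrix, dict[str, str]]:
    """Fragment-count matrix and experiment -> category map.

    Expected FPKM follows each member's archetype (preferred category at
    the archetype magnitude, baseline elsewhere); degenerate copies
    (anything but complete genes) are expressed at
    ``pseudogene_expression_scale`` of their archetype with probability
    ``pseudogene_expression_prob`` and silent otherwise.  Counts are
    Poisson around fpkm * exon_kb * library_millions with multiplicative
    log-normal noise of coefficient of variation ``noise_cv``; with
    ``noise_cv = 0`` the exact expected counts are returned (noise-free
    limit).
    """
    rng = np.random.default_rng((cfg.seed, 1))
    experiments = [
        f"{cat}_{i + 1:02d}"
        for cat in CATEGORIES
        for i in range(cfg.n_experiments_per_category)
    ]
    cmap = {e: e.rsplit("_", 1)[0] for e in experiments}
    lib = rng.normal(cfg.library_size_mean, 0.1 * cfg.library_size_mean, len(experiments))
    lib = np.maximum(lib, 1e6).astype(np.int64)
    library_sizes = pd.Series(lib, index=experiments, dtype=float)

    ids = truth.members
    cat_of_exp = np.array([CATEGORIES.index(cmap[e]) for e in experiments])
    mean_fpkm = np.empty((len(ids), len(experiments)))
    for gi, g in enumerate(ids):
        pref, mag = truth.archetype[g]
        row = np.full(len(experiments), cfg.baseline_fpkm)
        row[cat_of_exp == CATEGORIES.index(pref)] = mag
        if truth.category[g] is not AnnotationCategory.GENE:
            if rng.random() < cfg.pseudogene_expression_prob:
                row = row * cfg.pseudogene_expression_scale
            else:
                row = np.zeros_like(row)
        mean_fpkm[gi] = row

    exon_kb = np.array([truth.exon_length[i] for i in ids]) / 1e3
    expected = mean_fpkm * exon_kb[:, None] * (lib / 1e6)[None, :]
    if cfg.noise_cv > 0:
        sigma2 = np.log1p(cfg.noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), expected.shape)
        counts = rng.poisson(expected * noise).astype(float)
    else:
        counts = expected
    frame = pd.DataFrame(counts, index=ids, columns=experiments)
    exon_lengths = pd.Series({i: truth.exon_length[i] for i in ids}, dtype=float)
    return CountMatrix(frame, exon_lengths, library_sizes), cmap


def simulate_proteins(cfg: SimConfig, truth: TruthRecord) -> dict[str, str]:
    """Optional residue-level sequences matching the lineage identities.

    Each founder gets a random 20-letter sequence; every duplication edge
    mutates a fraction of positions equal to its identity decay, so
    alignment-derived identities approximate the lineage-path values.
    """
    rng = np.random.default_rng((cfg.seed, 2))
    seqs: dict[str, np.ndarray] = {}
    order = [i for i in truth.members if i not in truth.lineage] + [
        i for i in truth.members if i in truth.lineage
    ]
    for i in order:
        if i not in truth.lineage:
            seqs[i] = rng.choice(_AA, size=truth.protein_length[i])
        else:
            parent, decay = truth.lineage[i]
            seq = seqs[parent].copy()
            n_mut = int(round(decay / 100.0 * len(seq)))
            pos = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
            seq[pos] = rng.choice(_AA, size=len(pos))
            seqs[i] = seq
    return {i: "".join(s) for i, s in seqs.items()}


def write_bundle(
    outdir: str | Path,
    merged: GenomeAnnotation,
    hits: pd.DataFrame,
    truth: TruthRecord,
    counts: CountMatrix | None = None,
    cmap: dict[str, str] | None = None,
) -> dict[str, str]:
    """Write a simulated data set as plain-text files (GFF3, BLAST-style
    TSV, count matrix TSV, category map TSV, truth JSON)."""
    from .annotation import write_gff3
    from .expression import write_category_map, write_matrix_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_gff3(merged, outdir / "merged.gff3")
    paths["merged_gff3"] = str(outdir / "merged.gff3")
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False, header=False)
    paths["hits_tsv"] = str(outdir / "hits.tsv")
    truth.to_json(outdir / "truth.json")
    paths["truth_json"] = str(outdir / "truth.json")
    if counts is not None:
        write_matrix_tsv(counts.counts, outdir / "counts.tsv")
        counts.exon_lengths.rename("exon_length").to_csv(outdir / "exon_lengths.tsv", sep="\t")
        counts.library_sizes.rename("library_size").to_csv(outdir / "library_sizes.tsv", sep="\t")
        paths["counts_tsv"] = str(outdir / "counts.tsv")
    if cmap is not None:
        write_category_map(cmap, outdir / "categories.tsv")
        paths["categories_tsv"] = str(outdir / "categories.tsv")
    return paths
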