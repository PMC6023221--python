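import numpy as np
import pandas as pd
import pytest

from cypome.annotation import AnnotationCategory
from cypome.clusters import detect_clusters
from cypome.coexpression import cluster_profiles, correlation_distance
from cypome.expression import category_average, compute_fpkm
from cypome.paralogs import eligible_clustered_genes, rank_paralogs, same_cluster_fraction
from cypome.similarity import pairwise_identity
from cypome.simulate import (
    SimConfig,
    lineage_identity,
    simulate_expression,
    simulate_genome,
    simulate_proteins,
)

TANDEM_CFG = dict(
    n_background_genes=2_000,
    n_scaffolds=8,
    n_founders=4,
    dups_per_founder=4.0,
    p_tandem=1.0,
    p_pseudogenize=0.0,
    coverage_range=(0.72, 1.0),
)


def test_identical_seed_identical_outputs():
    cfg = SimConfig(seed=11, n_background_genes=500, n_founders=3, dups_per_founder=3.0)
    a = simulate_genome(cfg)
    b = simulate_genome(cfg)
    assert [f for f in a[0]] == [f for f in b[0]]
    pd.testing.assert_frame_equal(a[1], b[1])
    ca, _ = simulate_expression(cfg, a[2])
    cb, _ = simulate_expression(cfg, b[2])
    pd.testing.assert_frame_equal(ca.counts, cb.counts)


def test_single_tandem_lineage_recovered_exactly():
    cfg = SimConfig(seed=5, n_background_genes=1_000, n_scaffolds=4, n_founders=1,
                    dups_per_founder=4.0, p_tandem=1.0, p_segmental=0.0,
                    p_pseudogenize=0.0)
    merged, hits, truth = simulate_genome(cfg)
    res = detect_clusters(merged)
    if len(truth.members) >= 2:
        assert len(res.clusters) == 1
        assert set(res.clusters[0].members) == set(truth.members)
        assert res.isolated == set()


def test_identity_decays_along_lineage_chain():
    cfg = SimConfig(seed=1, n_founders=1, n_background_genes=100,
                    identity_decay_range=(5.0, 5.0), dups_per_founder=3.0)
    _, _, truth = simulate_genome(cfg)
    # walk a chain founder -> child -> grandchild if present
    for child, (parent, decay) in truth.lineage.items():
        assert decay == pytest.approx(5.0)
    chains = {m: 0 for m in truth.members}
    for child in truth.lineage:
        node, depth = child, 0
        while node in truth.lineage:
            node = truth.lineage[node][0]
            depth += 1
        chains[child] = depth
    three_deep = [m for m, d in chains.items() if d == 3]
    if three_deep:
        founder = truth.founder_of[three_deep[0]]
        assert lineage_identity(truth, founder, three_deep[0]) == pytest.approx(85.0)


def test_identity_floor_applies():
    cfg = SimConfig(seed=2, n_founders=1, n_background_genes=100,
                    identity_decay_range=(30.0, 30.0), dups_per_founder=6.0)
    _, hits, truth = simulate_genome(cfg)
    assert (hits["pct_identity"] >= cfg.identity_floor).all()


def test_tandem_only_truth_matches_detection_ari_one():
    from sklearn.metrics import adjusted_rand_score

    cfg = SimConfig(seed=17, **TANDEM_CFG)
    merged, hits, truth = simulate_genome(cfg)
    res = detect_clusters(merged)
    cluster_of = res.cluster_of()
    detected = []
    truth_labels = []
    next_singleton = -1
    for m in truth.members:
        truth_labels.append(truth.true_cluster[m])
        if m in cluster_of:
            detected.append(cluster_of[m])
        else:
            detected.append(next_singleton)
            next_singleton -= 1
    assert adjusted_rand_score(truth_labels, detected) == 1.0


def test_tandem_only_closest_paralog_in_own_cluster():
    cfg = SimConfig(seed=17, **TANDEM_CFG)
    merged, hits, truth = simulate_genome(cfg)
    res = detect_clusters(merged)
    complete = {m for m, c in truth.category.items() if c is AnnotationCategory.GENE}
    rankings = rank_paralogs(hits, complete)
    eligible = eligible_clustered_genes(res, complete)
    assert eligible
    assert same_cluster_fraction(rankings, res, 1, eligible) == 1.0


def test_noise_free_inherited_pair_correlates_perfectly():
    cfg = SimConfig(seed=23, n_background_genes=300, n_scaffolds=2, n_founders=1,
                    dups_per_founder=2.0, p_tandem=1.0, p_inherit_profile=1.0,
                    p_pseudogenize=0.0, noise_cv=0.0)
    merged, _, truth = simulate_genome(cfg)
    counts, cmap = simulate_expression(cfg, truth)
    avgs = category_average(compute_fpkm(counts), cmap)
    if len(truth.members) >= 2:
        a, b = truth.members[:2]
        r = np.corrcoef(avgs.loc[a], avgs.loc[b])[0, 1]
        assert r == pytest.approx(1.0)


def test_fpkm_round_trip_recovers_archetype_means():
    cfg = SimConfig(seed=31, n_background_genes=300, n_scaffolds=2, n_founders=2,
                    dups_per_founder=3.0, p_pseudogenize=0.0, noise_cv=0.0)
    _, _, truth = simulate_genome(cfg)
    counts, cmap = simulate_expression(cfg, truth)
    fpkm = compute_fpkm(counts)
    # library sizes are the external totals, so FPKM != mean exactly; but
    # the noise-free limit reproduces the archetype matrix cell-for-cell
    for g in truth.members:
        pref, mag = truth.archetype[g]
        row = fpkm.loc[g]
        for e in fpkm.columns:
            expected = mag if cmap[e] == pref else cfg.baseline_fpkm
            assert row[e] == pytest.approx(expected, rel=1e-9)


def test_poisson_counts_recover_means_within_error():
    cfg = SimConfig(seed=37, n_background_genes=300, n_scaffolds=2, n_founders=2,
                    dups_per_founder=4.0, p_pseudogenize=0.0, noise_cv=0.2)
    _, _, truth = simulate_genome(cfg)
    counts, cmap = simulate_expression(cfg, truth)
    fpkm = compute_fpkm(counts)
    rel_err = []
    for g in truth.members:
        pref, mag = truth.archetype[g]
        exps = [e for e in fpkm.columns if cmap[e] == pref]
        rel_err.append(abs(fpkm.loc[g, exps].mean() - mag) / mag)
    assert np.median(rel_err) < 0.25


def test_archetype_independence_gives_one_sixth_sharing():
    """With p_inherit = 0 the probability that two members of one physical
    cluster share an archetype category is 1/6 (uniform over six)."""
    share, total = 0, 0
    for seed in range(40):
        cfg = SimConfig(seed=seed, n_background_genes=400, n_scaffolds=4,
                        n_founders=3, dups_per_founder=4.0, p_tandem=1.0,
                        p_inherit_profile=0.0)
        _, _, truth = simulate_genome(cfg)
        by_cluster: dict[int, list[str]] = {}
        for m in truth.members:
            by_cluster.setdefault(truth.true_cluster[m], []).append(m)
        for members in by_cluster.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    total += 1
                    if truth.archetype[members[i]][0] == truth.archetype[members[j]][0]:
                        share += 1
    observed = share / total
    se = np.sqrt((1 / 6) * (5 / 6) / total)
    assert abs(observed - 1 / 6) < 4 * se + 0.01


def test_pseudogene_expression_attenuated_or_silent():
    cfg = SimConfig(seed=41, n_background_genes=300, n_scaffolds=2, n_founders=4,
                    dups_per_founder=5.0, p_pseudogenize=1.0, noise_cv=0.0)
    _, _, truth = simulate_genome(cfg)
    counts, cmap = simulate_expression(cfg, truth)
    fpkm = compute_fpkm(counts)
    pseudo = [m for m in truth.members if truth.category[m] is not AnnotationCategory.GENE]
    assert pseudo
    for g in pseudo:
        pref, mag = truth.archetype[g]
        exps = [e for e in fpkm.columns if cmap[e] == pref]
        peak = fpkm.loc[g, exps].max()
        assert peak == pytest.approx(0.0) or peak == pytest.approx(0.1 * mag, rel=1e-6)


def test_simulated_proteins_track_lineage_identity():
    cfg = SimConfig(seed=45, n_background_genes=100, n_scaffolds=2, n_founders=1,
                    dups_per_founder=2.0, identity_decay_range=(8.0, 8.0))
    _, _, truth = simulate_genome(cfg)
    assert truth.lineage  # this seed draws duplication events
    seqs = simulate_proteins(cfg, truth)
    child, (parent, decay) = next(iter(truth.lineage.items()))
    hit = pairwise_identity(seqs[parent], seqs[child])
    assert hit.pct_identity == pytest.approx(100.0 - decay, abs=4.0)
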