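import numpy as np
import pytest

from cypome.annotation import GenomeAnnotation
from cypome.clusters import (
    ClusterParams,
    cluster_statistics,
    clusters_to_frame,
    detect_clusters,
)

from conftest import make_feature
from oracles import brute_force_clusters


def random_instance(rng, n_features=60, n_scaffolds=3, family_prob=0.3):
    feats = []
    for i in range(n_features):
        scaffold = f"chr{rng.integers(1, n_scaffolds + 1)}"
        start = int(rng.integers(1, 1_000_000))
        end = start + int(rng.integers(100, 50_000))
        is_family = rng.random() < family_prob
        feats.append(
            make_feature(
                f"x{i:03d}", scaffold, start, end,
                "gene" if is_family else "background",
                family="CYPS01" if is_family else None,
            )
        )
    return GenomeAnnotation(feats)


def as_tuples(ann):
    return [(f.feature_id, f.scaffold, f.start, f.end, f.is_family) for f in ann]


def test_single_family_feature_is_isolated():
    ann = GenomeAnnotation(
        [make_feature("f1", "chr1", 100, 200, "gene", family="CYP82")]
    )
    res = detect_clusters(ann)
    assert res.clusters == [] and res.isolated == {"f1"}


def test_worked_example_gap_and_intervening_rule(three_scaffold_ann):
    # chr1: f1(1000-2500), f2(150000-152000) link (gap 147500, 2 intervening);
    # f3(400000-401000) isolated (gap 248000 > 200kb); chr2: f4 isolated.
    res = detect_clusters(three_scaffold_ann)
    assert [c.members for c in res.clusters] == [("f1", "f2")]
    assert res.isolated == {"f3", "f4"}
    assert res.clusters[0].span == (1_000, 152_000)
    assert res.clusters[0].families == {"CYP82": 2}


def test_intervening_gene_limit_breaks_link():
    feats = [make_feature("fa", "chr1", 1_000, 2_000, "gene", family="F")]
    feats += [
        make_feature(f"g{i}", "chr1", 3_000 + 100 * i, 3_050 + 100 * i)
        for i in range(9)
    ]
    feats.append(make_feature("fb", "chr1", 50_000, 51_000, "gene", family="F"))
    res = detect_clusters(GenomeAnnotation(feats))
    assert res.isolated == {"fa", "fb"}
    res8 = detect_clusters(GenomeAnnotation(feats[:-2] + [feats[-1]]))
    assert res8.clusters[0].members == ("fa", "fb")


@pytest.mark.parametrize("seed", range(12))
def test_matches_brute_force_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    ann = random_instance(rng, n_features=int(rng.integers(5, 120)))
    params = ClusterParams(
        max_gap_bp=int(rng.integers(10_000, 400_000)),
        max_intervening=int(rng.integers(0, 6)),
    )
    res = detect_clusters(ann, params)
    expected_clusters, expected_isolated = brute_force_clusters(
        as_tuples(ann), params.max_gap_bp, params.max_intervening, params.min_cluster_size
    )
    assert sorted(list(c.members) for c in res.clusters) == sorted(expected_clusters)
    assert res.isolated == expected_isolated


@pytest.mark.parametrize("seed", range(4))
def test_monotone_in_gap_and_intervening(seed):
    rng = np.random.default_rng(100 + seed)
    ann = random_instance(rng, n_features=80)
    base = detect_clusters(ann, ClusterParams(50_000, 2))
    wider = detect_clusters(ann, ClusterParams(200_000, 2))
    more = detect_clusters(ann, ClusterParams(50_000, 8))
    assert wider.n_clustered >= base.n_clustered
    assert more.n_clustered >= base.n_clustered


def test_background_outside_gaps_does_not_change_result(three_scaffold_ann):
    res = detect_clusters(three_scaffold_ann)
    extra = [
        make_feature("far1", "chr1", 900_000, 901_000),
        make_feature("far2", "chr2", 500_000, 501_000),
    ]
    ann2 = GenomeAnnotation(
        list(three_scaffold_ann.features) + extra,
        scaffold_order=three_scaffold_ann.scaffold_order,
    )
    res2 = detect_clusters(ann2)
    assert [c.members for c in res2.clusters] == [c.members for c in res.clusters]
    assert res2.isolated == res.isolated


@pytest.mark.parametrize("seed", range(3))
def test_member_removal_leaves_valid_subclusters(seed):
    """Removing one member and re-running yields a clustering in which the
    survivors of its old cluster are again chained or split validly."""
    rng = np.random.default_rng(200 + seed)
    ann = random_instance(rng, n_features=60, family_prob=0.5)
    res = detect_clusters(ann)
    if not res.clusters:
        pytest.skip("no clusters in this instance")
    victim = res.clusters[0].members[0]
    remaining = [f for f in ann.features if f.feature_id != victim]
    res2 = detect_clusters(GenomeAnnotation(remaining))
    expected_clusters, expected_isolated = brute_force_clusters(
        [(f.feature_id, f.scaffold, f.start, f.end, f.is_family) for f in remaining]
    )
    assert sorted(list(c.members) for c in res2.clusters) == sorted(expected_clusters)


def test_unsorted_input_raises():
    ann = GenomeAnnotation(
        [
            make_feature("a", "chr1", 100, 200, "gene", family="F"),
            make_feature("b", "chr1", 500, 600, "gene", family="F"),
        ]
    )
    ann._features = tuple(reversed(ann._features))  # violate the invariant
    with pytest.raises(ValueError, match="sorted"):
        detect_clusters(ann)


def test_overlapping_annotations_gap_counts_as_zero():
    feats = [
        make_feature("fa", "chr1", 1_000, 5_000, "gene", family="F"),
        make_feature("fb", "chr1", 4_000, 6_000, "gene", family="F"),
    ]
    res = detect_clusters(GenomeAnnotation(feats), ClusterParams(max_gap_bp=0))
    assert res.clusters[0].members == ("fa", "fb")


def test_cluster_statistics_arithmetic():
    feats = []
    positions = iter(range(1, 10**6, 1000))
    for ci, size in enumerate([2, 3, 7]):
        for m in range(size):
            p = next(positions)
            feats.append(
                make_feature(f"c{ci}m{m}", f"chr{ci}", p, p + 10, "gene", family=f"F{ci}")
            )
    res = detect_clusters(GenomeAnnotation(feats))
    stats = cluster_statistics(res)
    assert stats["sizes"] == [2, 3, 7]
    assert stats["mean_size"] == 4.0
    assert stats["median_size"] == 3.0
    assert stats["max_size"] == 7
    assert stats["fraction_single_family"] == 1.0


def test_statistics_of_empty_result():
    ann = GenomeAnnotation([make_feature("f1", "chr1", 1, 10, "gene", family="F")])
    stats = cluster_statistics(detect_clusters(ann))
    assert stats["n_clusters"] == 0 and stats["sizes"] == []
    assert stats["mean_size"] == 0.0


def test_cluster_frame_columns(three_scaffold_ann):
    frame = clusters_to_frame(detect_clusters(three_scaffold_ann))
    assert frame.loc[0, "members"] == "f1,f2"
    assert frame.loc[0, "families"] == "CYP82:2"
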