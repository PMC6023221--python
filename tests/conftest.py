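import pytest

from cypome.annotation import AnnotationCategory, GenomeAnnotation, GenomeFeature
from cypome.simulate import SimConfig, simulate_expression, simulate_genome


def make_feature(fid, scaffold, start, end, category="background", family=None, name=None):
    return GenomeFeature(
        feature_id=fid,
        scaffold=scaffold,
        start=start,
        end=end,
        strand=".",
        category=AnnotationCategory(category),
        family=family,
        name=name,
    )


@pytest.fixture
def feat():
    return make_feature


@pytest.fixture
def three_scaffold_ann():
    """Small merged annotation: family and background genes interleaved."""
    feats = [
        make_feature("f1", "chr1", 1_000, 2_500, "gene", family="CYP82"),
        make_feature("g1", "chr1", 10_000, 11_000),
        make_feature("g2", "chr1", 50_000, 51_000),
        make_feature("f2", "chr1", 150_000, 152_000, "gene", family="CYP82"),
        make_feature("f3", "chr1", 400_000, 401_000, "pseudogene", family="CYP76"),
        make_feature("g3", "chr2", 5_000, 6_000),
        make_feature("f4", "chr2", 20_000, 21_000, "gene", family="CYP76"),
    ]
    return GenomeAnnotation(feats, scaffold_order=["chr1", "chr2"])


@pytest.fixture(scope="session")
def small_bundle():
    """Deterministic mid-sized simulation shared across tests."""
    cfg = SimConfig(seed=7, n_background_genes=3_000, n_scaffolds=6,
                    n_founders=10, dups_per_founder=6.0)
    merged, hits, truth = simulate_genome(cfg)
    counts, cmap = simulate_expression(cfg, truth)
    return cfg, merged, hits, truth, counts, cmap
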