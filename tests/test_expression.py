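import numpy as np
import pandas as pd
import pytest

from cypome.annotation import AnnotationCategory
from cypome.expression import (
    CATEGORIES,
    CountMatrix,
    category_average,
    compute_fpkm,
    expressed_set,
    expression_summary,
    pooled_quantile_levels,
)


def matrix(values, genes=None, exps=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    exps = exps or [f"e{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=exps)


class TestComputeFpkm:
    def test_forced_arithmetic(self):
        cm = CountMatrix(
            matrix([[10]]),
            exon_lengths=pd.Series({"g0": 2_000.0}),
            library_sizes=pd.Series({"e0": 5_000_000.0}),
        )
        assert compute_fpkm(cm).iloc[0, 0] == pytest.approx(1.0)

    def test_zero_count_zero_fpkm(self):
        cm = CountMatrix(
            matrix([[0, 5]]),
            pd.Series({"g0": 1_000.0}),
            pd.Series({"e0": 1e6, "e1": 1e6}),
        )
        fpkm = compute_fpkm(cm)
        assert fpkm.iloc[0, 0] == 0.0 and fpkm.iloc[0, 1] > 0

    def test_scale_invariance(self):
        counts = matrix([[3, 8], [0, 2]])
        lib = pd.Series({"e0": 2e6, "e1": 4e6})
        exon = pd.Series({"g0": 1_500.0, "g1": 900.0})
        a = compute_fpkm(CountMatrix(counts, exon, lib))
        b = compute_fpkm(CountMatrix(counts * 2, exon, lib * 2))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_linear_in_counts(self):
        counts = matrix([[3, 8]])
        lib = pd.Series({"e0": 2e6, "e1": 4e6})
        exon = pd.Series({"g0": 1_500.0})
        a = compute_fpkm(CountMatrix(counts, exon, lib))
        b = compute_fpkm(CountMatrix(counts * 3, exon, lib))
        assert np.allclose(3 * a.to_numpy(), b.to_numpy())

    def test_invalid_normalizers_raise(self):
        with pytest.raises(ValueError, match="exon"):
            CountMatrix(matrix([[1]]), pd.Series({"g0": 0.0}), pd.Series({"e0": 1e6}))
        with pytest.raises(ValueError, match="library"):
            CountMatrix(matrix([[1]]), pd.Series({"g0": 100.0}), pd.Series({"e0": 0.0}))


class TestExpressedSet:
    def test_needs_two_positive_experiments(self):
        fpkm = matrix([[0, 0, 5], [0, 1, 2], [0, 0, 0]])
        assert expressed_set(fpkm) == {"g1"}

    def test_threshold_configurable(self):
        fpkm = matrix([[0, 0, 5]])
        assert expressed_set(fpkm, min_experiments=1) == {"g0"}


class TestCategoryAverage:
    def test_single_experiment_per_category_identity(self):
        exps = [f"{c}_1" for c in CATEGORIES]
        fpkm = matrix([range(6)], exps=exps)
        cmap = {e: e.rsplit("_", 1)[0] for e in exps}
        avgs = category_average(fpkm, cmap)
        assert list(avgs.iloc[0]) == list(range(6))

    def test_mean_of_two_replicates(self):
        exps = [f"{c}_1" for c in CATEGORIES[:-1]] + ["ripe_berries_1", "ripe_berries_2"]
        fpkm = matrix([[1, 1, 1, 1, 1, 4, 6]], exps=exps)
        cmap = {e: e.rsplit("_", 1)[0] for e in exps}
        avgs = category_average(fpkm, cmap)
        assert avgs.loc["g0", "ripe_berries"] == pytest.approx(5.0)

    def test_empty_category_raises(self):
        fpkm = matrix([[1]], exps=["leaves_1"])
        with pytest.raises(ValueError, match="flowers|category"):
            category_average(fpkm, {"leaves_1": "leaves"})


class TestQuantileLevels:
    def test_interpolated_thresholds_and_binning(self):
        # pooled non-zero values {10, 20, 30}: q33 = 16.6, q66 = 23.2
        fpkm = matrix([[10, 20, 30]])
        avgs = matrix([[5, 20, 25]], exps=["a", "b", "c"])
        thresholds, levels = pooled_quantile_levels(fpkm, avgs)
        assert thresholds.q33 == pytest.approx(16.6)
        assert thresholds.q66 == pytest.approx(23.2)
        assert list(levels.iloc[0]) == ["low", "average", "high"]

    def test_zero_average_is_none(self):
        fpkm = matrix([[1, 2]])
        avgs = matrix([[0.0]], exps=["x"])
        _, levels = pooled_quantile_levels(fpkm, avgs)
        assert levels.iloc[0, 0] == "none"

    def test_single_pooled_value_boundary(self):
        # one pooled value makes both thresholds equal; the right-closed
        # low band (0, q33] then captures v and (q33, q66] is empty
        fpkm = matrix([[7, 0]])
        avgs = matrix([[7.0]], exps=["x"])
        thresholds, levels = pooled_quantile_levels(fpkm, avgs)
        assert thresholds.q33 == thresholds.q66 == 7.0
        assert levels.iloc[0, 0] == "low"

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        fpkm = matrix(rng.gamma(2.0, 5.0, size=(8, 6)))
        avgs = matrix(rng.gamma(2.0, 5.0, size=(8, 4)), exps=list("abcd"))
        t1, l1 = pooled_quantile_levels(fpkm, avgs)
        t2, l2 = pooled_quantile_levels(fpkm * 10, avgs * 10)
        assert t2.q33 == pytest.approx(10 * t1.q33)
        assert l1.equals(l2)

    def test_level_counts_split_in_thirds(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(1, 100, size=(30, 10))
        fpkm = matrix(values)
        # bin the per-experiment values themselves: thirds within +/-2
        thresholds, levels = pooled_quantile_levels(fpkm, fpkm)
        counts = pd.Series(levels.to_numpy().ravel()).value_counts()
        third = values.size / 3
        for level in ("low", "average", "high"):
            assert abs(counts[level] - third) <= 2

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError, match="non-zero"):
            pooled_quantile_levels(matrix([[0, 0]]), matrix([[0.0]], exps=["x"]))


class TestExpressionSummary:
    def test_direct_arithmetic(self):
        fpkm = matrix([[0, 2, 4]])
        cats = {"g0": AnnotationCategory.GENE}
        table = expression_summary(fpkm, {"g0"}, cats)
        row = table.set_index("class").loc["gene"]
        assert row["mean_fpkm"] == pytest.approx(2.0)
        assert row["median_fpkm"] == pytest.approx(2.0)

    def test_pseudogene_classes_pooled(self):
        fpkm = matrix([[1, 1], [3, 3]])
        cats = {
            "g0": AnnotationCategory.PSEUDOGENE,
            "g1": AnnotationCategory.PUTATIVE_PSEUDOGENE,
        }
        table = expression_summary(fpkm, {"g0", "g1"}, cats)
        assert list(table["class"]) == ["pseudogene"]
        assert table.iloc[0]["mean_fpkm"] == pytest.approx(2.0)

    def test_empty_expressed_set(self):
        table = expression_summary(matrix([[1]]), set(), {"g0": AnnotationCategory.GENE})
        assert table.empty
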