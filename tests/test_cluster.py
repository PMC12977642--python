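import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from protnorm.cluster import (
    average_linkage,
    first_merge_partner,
    merge_table,
    pairwise_distance,
    to_newick,
    zscore_rows,
)
from protnorm.errors import (
    MatrixError,
    ShapeError,
    UndefinedCorrelationError,
    UnknownLeafError,
)

from ._oracles import oracle_average_linkage


def _dist_frame(points, labels):
    arr = np.asarray(points, dtype=float)
    d = np.sqrt(((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=labels, columns=labels)


class TestZscoreRows:
    def test_row_standardisation(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=list("abc"))
        z = zscore_rows(m)
        assert list(z.loc["p"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zeros(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0]], index=["p"], columns=list("abc"))
        assert list(zscore_rows(m).loc["p"]) == [0.0, 0.0, 0.0]

    def test_single_column_rejected(self):
        with pytest.raises(ShapeError):
            zscore_rows(pd.DataFrame([[1.0]], columns=["a"]))

    def test_idempotent_on_nonconstant_rows(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(20, 6)))
        once = zscore_rows(m)
        twice = zscore_rows(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)


class TestPairwiseDistance:
    def test_identical_vectors_distance_zero(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [1.0, 2.0, 4.0]})
        for metric in ("euclidean", "pearson"):
            d = pairwise_distance(m, metric=metric, axis="cols")
            assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five_triangle(self):
        m = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        d = pairwise_distance(m, metric="euclidean", axis="cols")
        assert d.loc["a", "b"] == pytest.approx(5.0)

    def test_anticorrelated_rows_pearson_distance_two(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["p", "q"]
        )
        d = pairwise_distance(m, metric="pearson", axis="rows")
        assert d.loc["p", "q"] == pytest.approx(2.0)

    def test_zero_variance_vector_under_pearson_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(UndefinedCorrelationError, match="a"):
            pairwise_distance(m, metric="pearson", axis="cols")

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        d = pairwise_distance(m, axis="cols")
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)


class TestAverageLinkage:
    def test_two_leaves_single_merge(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        tree = average_linkage(d)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(3.0)
        assert first_merge_partner(tree, "a") == "b"

    def test_four_points_on_a_line(self):
        # points at 0, 1, 10, 11: two tight pairs, then one far merge whose
        # height is the mean of the four cross distances (10+11+9+10)/4
        d = _dist_frame([[0.0], [1.0], [10.0], [11.0]], list("abcd"))
        tree = average_linkage(d)
        assert tree.merges[0].members == frozenset({"a", "b"})
        assert tree.merges[0].height == pytest.approx(1.0)
        assert tree.merges[1].members == frozenset({"c", "d"})
        assert tree.merges[1].height == pytest.approx(1.0)
        assert tree.merges[2].height == pytest.approx(10.0)

    def test_duplicate_points_merge_at_height_zero(self):
        d = _dist_frame([[2.0], [2.0], [9.0]], list("abc"))
        tree = average_linkage(d)
        assert tree.merges[0].height == pytest.approx(0.0)
        assert tree.merges[0].members == frozenset({"a", "b"})

    def test_non_symmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(MatrixError):
            average_linkage(d)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(9, 3))
        tree = average_linkage(_dist_frame(points, [f"l{i}" for i in range(9)]))
        heights = [m.height for m in tree.merges]
        assert heights == sorted(heights)

    def test_matches_naive_recompute_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            n = int(rng.integers(2, 11))
            points = rng.normal(size=(n, 2))
            labels = [f"l{i}" for i in range(n)]
            d = _dist_frame(points, labels)
            tree = average_linkage(d)
            expected = oracle_average_linkage(d.to_numpy().tolist(), labels)
            assert len(tree.merges) == len(expected)
            for merge, (ea, eb, eh) in zip(tree.merges, expected):
                assert {merge.a, merge.b} == {ea, eb}
                assert merge.height == pytest.approx(eh, rel=1e-9)

    def test_matches_scipy_on_distinct_distances(self):
        # independent cross-check against scipy's average linkage; heights
        # must agree when no ties make the merge order ambiguous
        rng = np.random.default_rng(9)
        points = rng.normal(size=(8, 3))
        d = _dist_frame(points, [f"l{i}" for i in range(8)])
        tree = average_linkage(d)
        z = linkage(squareform(d.to_numpy()), method="average")
        assert [m.height for m in tree.merges] == pytest.approx(
            list(z[:, 2]), rel=1e-9
        )

    def test_row_permutation_gives_same_merges(self):
        rng = np.random.default_rng(13)
        points = rng.normal(size=(7, 2))
        labels = [f"l{i}" for i in range(7)]
        d = _dist_frame(points, labels)
        perm = list(rng.permutation(7))
        d_perm = d.iloc[perm, perm]
        merges_a = {
            (m.members, round(m.height, 9)) for m in average_linkage(d).merges
        }
        merges_b = {
            (m.members, round(m.height, 9))
            for m in average_linkage(d_perm).merges
        }
        assert merges_a == merges_b


class TestTreeViews:
    def test_first_merge_partner_unknown_leaf(self):
        d = _dist_frame([[0.0], [1.0]], ["a", "b"])
        tree = average_linkage(d)
        with pytest.raises(UnknownLeafError):
            first_merge_partner(tree, "nope")

    def test_partner_can_be_a_cluster(self):
        d = _dist_frame([[0.0], [1.0], [10.0]], ["a", "b", "c"])
        tree = average_linkage(d)
        assert first_merge_partner(tree, "c") == frozenset({"a", "b"})

    def test_newick_contains_all_leaves(self):
        d = _dist_frame([[0.0], [1.0], [10.0], [11.0]], list("abcd"))
        nwk = to_newick(average_linkage(d))
        assert nwk.endswith(";")
        for leaf in "abcd":
            assert leaf in nwk

    def test_merge_table_shape(self):
        d = _dist_frame([[0.0], [1.0], [10.0]], list("abc"))
        table = merge_table(average_linkage(d))
        assert list(table.columns) == ["step", "cluster_a", "cluster_b", "height"]
        assert len(table) == 2
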