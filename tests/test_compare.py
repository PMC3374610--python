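"""Distances, UPGMA clustering, tree cutting, classical MDS, heatmap export."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import squareform

from annocompare import fixtures
from annocompare.abundance import relative_frequency
from annocompare.annotation_store import AnnotationRecord, Dataset
from annocompare.compare import (
    METRICS,
    average_linkage,
    build_matrix,
    classical_mds,
    cut_tree,
    distance,
    distance_matrix,
    export_heatmap,
)


def random_distance_frame(rng, n):
    points = rng.random((n, 3))
    d = np.array([[np.linalg.norm(a - b) for b in points] for a in points])
    labels = [f"L{i}" for i in range(n)]
    return pd.DataFrame(d, index=labels, columns=labels)


class TestBuildMatrix:
    def test_rows_equal_per_dataset_profiles(self, habitat_family):
        datasets, truth = habitat_family
        matrix = build_matrix(datasets, "ko", mode="relative", include_unassigned=False)
        for dataset in datasets:
            profile = relative_frequency(dataset, "ko").drop_unassigned()
            for feature in matrix.columns:
                assert matrix.loc[dataset.library_id, feature] == pytest.approx(
                    profile[feature]
                )

    def test_disjoint_features_yield_zero_blocks(self):
        a = Dataset("A", [AnnotationRecord("a", "A", ko_id=("K00001",))])
        b = Dataset("B", [AnnotationRecord("b", "B", ko_id=("K00002",))])
        matrix = build_matrix([a, b], "ko", mode="absolute", include_unassigned=False)
        assert matrix.loc["A", "K00002"] == 0.0
        assert matrix.loc["B", "K00001"] == 0.0

    def test_duplicated_dataset_gives_identical_rows(self, worked_example):
        import dataclasses

        twin_records = [
            dataclasses.replace(r, library_id="TWIN") for r in worked_example.records
        ]
        twin = Dataset("TWIN", twin_records)
        matrix = build_matrix([worked_example, twin], "ko")
        assert np.allclose(matrix.iloc[0].to_numpy(), matrix.iloc[1].to_numpy())

    def test_filter_applied_per_dataset_before_aggregation(self, worked_example):
        import dataclasses

        twin = Dataset(
            "TWIN",
            [dataclasses.replace(r, library_id="TWIN") for r in worked_example.records],
        )
        matrix = build_matrix(
            [worked_example, twin], "ko", filter_query="ko_id:K00849", mode="relative"
        )
        # post-filter denominator: only K00849 records remain
        assert matrix.loc["EXAMPLE100", "K00849"] == pytest.approx(1.0)

    def test_empty_post_filter_dataset_warns_and_zeroes(self, worked_example):
        import dataclasses

        twin = Dataset(
            "TWIN",
            [dataclasses.replace(r, library_id="TWIN") for r in worked_example.records],
        )
        with pytest.warns(UserWarning, match="empty"):
            matrix = build_matrix(
                [worked_example, twin], "ko", filter_query="ko_id:K99999"
            )
        assert (matrix.to_numpy() == 0).all()


class TestDistance:
    def test_identical_profiles_have_zero_distance(self):
        x = np.array([3.0, 1.0, 2.0])
        for metric in METRICS:
            assert distance(x, x, metric) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_have_unit_distance(self):
        x = np.array([2.0, 3.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, 4.0])
        for metric in ("morisita-horn", "bray-curtis", "jaccard"):
            assert distance(x, y, metric) == pytest.approx(1.0)

    def test_longhand_values_on_small_vectors(self):
        # x=(2,1,0), y=(1,1,1), each term evaluated by hand from the formulas
        x, y = [2.0, 1.0, 0.0], [1.0, 1.0, 1.0]
        assert distance(x, y, "morisita-horn") == pytest.approx(0.25)
        assert distance(x, y, "bray-curtis") == pytest.approx(1.0 / 3.0)
        assert distance(x, y, "jaccard") == pytest.approx(1.0 / 3.0)
        assert distance(x, y, "euclidean") == pytest.approx(math.sqrt(2.0))

    def test_all_zero_vector_rejected_for_overlap_metrics(self):
        zero = np.zeros(3)
        other = np.array([1.0, 0.0, 0.0])
        for metric in ("morisita-horn", "bray-curtis", "jaccard"):
            with pytest.raises(ValueError):
                distance(zero, other, metric)
        assert distance(zero, other, "euclidean") == pytest.approx(1.0)

    def test_metric_axioms_on_random_vectors(self, rng):
        for _ in range(50):
            x = rng.random(6) * rng.integers(1, 10)
            y = rng.random(6) * rng.integers(1, 10)
            z = rng.random(6) * rng.integers(1, 10)
            for metric in METRICS:
                dxy = distance(x, y, metric)
                assert dxy >= 0
                assert distance(y, x, metric) == pytest.approx(dxy)
                assert distance(x, x, metric) == pytest.approx(0.0, abs=1e-12)
            # triangle inequality holds for all but Morisita-Horn
            for metric in ("euclidean", "bray-curtis", "jaccard"):
                assert distance(x, z, metric) <= distance(x, y, metric) + distance(
                    y, z, metric
                ) + 1e-12

    def test_scaling_invariance(self, rng):
        x = rng.random(8) + 0.01
        y = rng.random(8) + 0.01
        # Morisita-Horn ignores proportional scaling of either profile alone
        assert distance(3.0 * x, y, "morisita-horn") == pytest.approx(
            distance(x, y, "morisita-horn")
        )
        # Bray-Curtis only when both profiles scale together
        assert distance(3.0 * x, 3.0 * y, "bray-curtis") == pytest.approx(
            distance(x, y, "bray-curtis")
        )

    def test_morisita_horn_range(self, rng):
        for _ in range(100):
            x = rng.random(5)
            y = rng.random(5)
            assert 0.0 <= distance(x + 1e-9, y + 1e-9, "morisita-horn") <= 1.0


class TestAverageLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        frame = pd.DataFrame(
            [[0.0, 0.7], [0.7, 0.0]], index=["A", "B"], columns=["A", "B"]
        )
        dendrogram = average_linkage(frame)
        assert dendrogram.root.height == pytest.approx(0.7)
        assert dendrogram.leaves == ("A", "B")

    def test_three_leaf_hand_example(self):
        # d(A,B)=1, d(A,C)=d(B,C)=4: AB at 1, then C joins at (4+4)/2 = 4
        frame = pd.DataFrame(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        dendrogram = average_linkage(frame)
        assert dendrogram.merge_heights() == pytest.approx([1.0, 4.0])
        inner = [c for c in dendrogram.root.children if not c.is_leaf][0]
        assert inner.members == ("A", "B")

    def test_agrees_with_scipy_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 8))
            frame = random_distance_frame(rng, n)
            dendrogram = average_linkage(frame)
            linkage = scipy_hierarchy.linkage(
                squareform(frame.to_numpy(), checks=False), method="average"
            )
            assert np.allclose(
                dendrogram.merge_heights(), np.sort(linkage[:, 2]), atol=1e-9
            )
            # topology via cophenetic distances
            coph = squareform(scipy_hierarchy.cophenet(linkage))
            mine = cophenetic_map(dendrogram)
            labels = list(frame.index)
            for i in range(n):
                for j in range(i + 1, n):
                    assert mine[frozenset((labels[i], labels[j]))] == pytest.approx(
                        coph[i, j], abs=1e-9
                    )

    def test_heights_monotone_along_root_paths(self, rng):
        frame = random_distance_frame(rng, 7)
        dendrogram = average_linkage(frame)

        def walk(node):
            for child in node.children:
                assert child.height <= node.height + 1e-12
                walk(child)

        walk(dendrogram.root)

    def test_tie_break_is_lexicographic(self):
        # three equidistant leaves: the first merge must be the pair (A, B)
        frame = pd.DataFrame(
            np.ones((3, 3)) - np.eye(3), index=list("CAB"), columns=list("CAB")
        )
        dendrogram = average_linkage(frame)
        first = min(
            (c for c in dendrogram.root.children if not c.is_leaf),
            key=lambda n: n.height,
        )
        assert first.members == ("A", "B")

    def test_nan_rejected(self):
        frame = pd.DataFrame(
            [[0, np.nan], [np.nan, 0]], index=["A", "B"], columns=["A", "B"]
        )
        with pytest.raises(ValueError, match="NaN"):
            average_linkage(frame)

    def test_newick_is_ultrametric_and_parseable(self, rng):
        import dendropy

        frame = random_distance_frame(rng, 6)
        dendrogram = average_linkage(frame)
        tree = dendropy.Tree.get(data=dendrogram.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(frame.index)
        root_height = dendrogram.root.height
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height, abs=1e-6)


def cophenetic_map(dendrogram):
    out = {}

    def walk(node):
        if node.is_leaf:
            return
        left, right = node.children
        for x in left.members:
            for y in right.members:
                out[frozenset((x, y))] = node.height
        walk(left)
        walk(right)

    walk(dendrogram.root)
    return out


class TestCutTree:
    @pytest.fixture()
    def hand_tree(self):
        frame = pd.DataFrame(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        return average_linkage(frame)

    def test_cut_above_root_is_one_cluster(self, hand_tree):
        assert set(cut_tree(hand_tree, 10.0).values()) == {0}

    def test_cut_at_zero_is_all_singletons(self, hand_tree):
        assignment = cut_tree(hand_tree, 0.0)
        assert len(set(assignment.values())) == 3

    def test_cut_between_merges_splits_off_singleton(self, hand_tree):
        assignment = cut_tree(hand_tree, 2.0)
        assert assignment["A"] == assignment["B"] != assignment["C"]

    def test_negative_height_rejected(self, hand_tree):
        with pytest.raises(ValueError):
            cut_tree(hand_tree, -1.0)


class TestClassicalMds:
    def test_equilateral_triangle_recovered(self):
        frame = pd.DataFrame(
            np.ones((3, 3)) - np.eye(3), index=list("ABC"), columns=list("ABC")
        )
        coords = classical_mds(frame, 2)
        for i in range(3):
            for j in range(i + 1, 3):
                recovered = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
                assert recovered == pytest.approx(1.0, abs=1e-9)

    def test_planted_plane_coordinates_recovered(self, rng):
        points = rng.random((6, 2)) * 10
        d = np.array([[np.linalg.norm(a - b) for b in points] for a in points])
        frame = pd.DataFrame(d, index=[f"P{i}" for i in range(6)], columns=[f"P{i}" for i in range(6)])
        coords = classical_mds(frame, 2).to_numpy()
        for i in range(6):
            for j in range(6):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_collinear_configuration_exact_in_one_dimension(self):
        positions = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(positions[:, None] - positions[None, :])
        frame = pd.DataFrame(d, index=list("ABCD"), columns=list("ABCD"))
        coords = classical_mds(frame, 1).to_numpy().ravel()
        recovered = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(recovered, d, atol=1e-9)

    def test_sign_convention_fixed(self):
        frame = pd.DataFrame(
            np.ones((3, 3)) - np.eye(3), index=list("ABC"), columns=list("ABC")
        )
        a = classical_mds(frame, 2)
        b = classical_mds(frame, 2)
        assert np.allclose(a.to_numpy(), b.to_numpy())
        assert (a.to_numpy()[np.abs(a.to_numpy()) > 1e-12][0]) > 0

    def test_k_out_of_range_rejected(self):
        frame = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        for k in (0, 3, 5):
            with pytest.raises(ValueError):
                classical_mds(frame, k)

    def test_non_euclidean_input_warns(self, habitat_family):
        datasets, _ = habitat_family
        matrix = build_matrix(datasets, "ko", include_unassigned=False)
        dist = distance_matrix(matrix, "morisita-horn")
        with pytest.warns(UserWarning, match="negative eigenvalues"):
            classical_mds(dist, len(datasets) - 1)


class TestHeatmapExport:
    def test_reordered_tsv_matches_dendrogram_orders(self, tmp_path, habitat_family):
        datasets, _ = habitat_family
        matrix = build_matrix(datasets, "ko", include_unassigned=False)
        out = tmp_path / "heatmap.tsv"
        ordered, row_tree, col_tree = export_heatmap(matrix, "morisita-horn", out_tsv=out)
        assert list(ordered.index) == row_tree.leaf_order()
        assert list(ordered.columns) == col_tree.leaf_order()
        reloaded = pd.read_csv(out, sep="\t", index_col=0)
        assert np.allclose(reloaded.to_numpy(), ordered.to_numpy(), atol=1e-9)
        # reordering permutes but never alters values
        assert np.allclose(
            ordered.loc[matrix.index, matrix.columns].to_numpy(),
            matrix.to_numpy(),
        )

    def test_image_export_writes_file(self, tmp_path, habitat_family):
        datasets, _ = habitat_family
        matrix = build_matrix(datasets[:3], "ko", include_unassigned=False)
        image = tmp_path / "heatmap.png"
        export_heatmap(matrix, "euclidean", out_image=image)
        assert image.exists() and image.stat().st_size > 0
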