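"""Interaction-map analytics: distances, clusters, difficulty, feedback."""

import numpy as np
import pandas as pd
import pytest

from lsirm import (
    cluster_centers,
    covariate_overlay,
    feedback_report,
    inter_cluster_distance_table,
    item_distance_matrix,
    perceived_difficulty,
    person_cluster_distances,
    person_item_distances,
    person_mean_distance,
)
from lsirm.model import euclidean_distance

from _reference import CLUSTER_CENTERS, CLUSTER_DISTANCES, PERSON_RECORDS


class TestPersonItemDistances:
    def test_known_row(self):
        D = person_item_distances(np.array([[0.0, 0.0]]), np.array([[3, 4], [0, 1]]))
        np.testing.assert_allclose(D, [[5.0, 1.0]])

    def test_matches_scalar_loop(self, rng):
        xi, zeta = rng.standard_normal((6, 2)), rng.standard_normal((4, 2))
        D = person_item_distances(xi, zeta)
        for p in range(6):
            for i in range(4):
                assert D[p, i] == pytest.approx(euclidean_distance(xi[p], zeta[i]))

    def test_coincident_positions(self):
        D = person_item_distances(np.zeros((3, 2)), np.zeros((2, 2)))
        assert np.all(D == 0)


class TestItemDistanceMatrix:
    def test_two_items(self):
        D = item_distance_matrix(np.array([[0, 0], [0, 2]]))
        assert D[0, 1] == D[1, 0] == 2.0

    def test_symmetric_zero_diagonal(self, rng):
        D = item_distance_matrix(rng.standard_normal((7, 2)))
        np.testing.assert_array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_block_structure_for_separated_blobs(self, rng):
        blob1 = rng.normal(0, 0.05, size=(5, 2))
        blob2 = rng.normal(5, 0.05, size=(5, 2))
        D = item_distance_matrix(np.vstack([blob1, blob2]))
        within = max(D[:5, :5].max(), D[5:, 5:].max())
        between = D[:5, 5:].min()
        assert within < between


class TestClusterCenters:
    def test_mean_of_members(self):
        cs = cluster_centers(np.array([[0.0, 0], [2, 2]]), ["a", "a"])
        np.testing.assert_allclose(cs.centers, [[1.0, 1.0]])

    def test_singleton_cluster(self):
        cs = cluster_centers(np.array([[0.5, -1.0], [2, 2]]), ["a", "b"])
        np.testing.assert_allclose(cs.centers[0], [0.5, -1.0])

    def test_blob_centers_near_truth(self, rng):
        truth = np.array([[0.0, 0.0], [4.0, 0.0]])
        labels = np.repeat([0, 1], 50)
        zeta = truth[labels] + rng.normal(0, 0.3, size=(100, 2))
        cs = cluster_centers(zeta, labels)
        se = 0.3 / np.sqrt(50)
        assert np.all(np.abs(cs.centers - truth) < 2 * se + 0.05)

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            cluster_centers(np.zeros((3, 2)), ["a", "b"])


class TestInterClusterDistances:
    def test_reproduces_printed_table(self):
        """All 21 printed pairwise center distances match within 0.005."""
        table = inter_cluster_distance_table(CLUSTER_CENTERS)
        for (i, j), printed in CLUSTER_DISTANCES.items():
            assert table.distances[i - 1, j - 1] == pytest.approx(printed, abs=0.005)

    def test_symmetry_and_mean_column(self):
        table = inter_cluster_distance_table(CLUSTER_CENTERS)
        np.testing.assert_array_equal(table.distances, table.distances.T)
        assert np.all(np.diag(table.distances) == 0)
        for c in range(7):
            expected = table.distances[c].sum() / 6
            assert table.mean_distance[c] == pytest.approx(expected)

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            inter_cluster_distance_table(np.zeros((1, 2)))


class TestPersonClusterDistances:
    def test_centroid_method_reproduces_printed_rows(self):
        """Printed person-to-cluster distances are distances to the centers."""
        xi = np.vstack([rec["position"] for rec in PERSON_RECORDS.values()])
        labels = np.arange(7)  # one item per cluster placed at the center
        pcd = person_cluster_distances(
            xi, CLUSTER_CENTERS, labels, method="centroid",
            person_ids=list(PERSON_RECORDS),
        )
        for pid, rec in PERSON_RECORDS.items():
            np.testing.assert_allclose(
                pcd.table.loc[pid].to_numpy(), rec["cluster_distances"], atol=0.005
            )

    def test_farthest_cluster_matches_row_argmax(self):
        xi = np.vstack([rec["position"] for rec in PERSON_RECORDS.values()])
        pcd = person_cluster_distances(
            xi, CLUSTER_CENTERS, np.arange(7), method="centroid",
            person_ids=list(PERSON_RECORDS),
        )
        # persons 64 and 1359 are farthest from cluster 7 (0-indexed: 6)
        assert pcd.farthest.loc["64"] == 6
        assert pcd.farthest.loc["1359"] == 6
        assert pcd.farthest.loc["1653"] == 4
        assert pcd.farthest.loc["1655"] == 3

    def test_singleton_clusters_make_methods_agree(self, rng):
        xi = rng.standard_normal((5, 2))
        zeta = rng.standard_normal((3, 2))
        a = person_cluster_distances(xi, zeta, [0, 1, 2], method="per-item-mean")
        b = person_cluster_distances(xi, zeta, [0, 1, 2], method="centroid")
        np.testing.assert_allclose(a.table.to_numpy(), b.table.to_numpy())

    def test_per_item_mean_dominates_centroid(self, rng):
        """Mean distance to members >= distance to the mean (convexity)."""
        for _ in range(10):
            xi = rng.standard_normal((6, 2))
            zeta = rng.standard_normal((9, 2))
            labels = rng.integers(0, 3, size=9)
            if len(set(labels.tolist())) < 3:
                continue
            a = person_cluster_distances(xi, zeta, labels, method="per-item-mean")
            b = person_cluster_distances(xi, zeta, labels, method="centroid")
            assert np.all(a.table.to_numpy() >= b.table.to_numpy() - 1e-12)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            person_cluster_distances(np.zeros((2, 2)), np.zeros((2, 2)), [0, 1], "mode")


class TestPersonMeanDistance:
    def test_row_means(self):
        np.testing.assert_allclose(person_mean_distance(np.array([[5.0, 1.0]])), [3.0])

    def test_constant_matrix(self):
        np.testing.assert_allclose(person_mean_distance(np.full((4, 3), 2.5)), 2.5)

    def test_matches_loop(self, rng):
        D = rng.random((5, 7))
        expected = [np.mean([D[p, i] for i in range(7)]) for p in range(5)]
        np.testing.assert_allclose(person_mean_distance(D), expected)


class TestPerceivedDifficulty:
    def test_zero_lambda_collapses_interval(self, rng):
        b = rng.standard_normal(4)
        pd_ = perceived_difficulty(b, 0.0, rng.random((6, 4)))
        np.testing.assert_allclose(pd_.summary["low"], b)
        np.testing.assert_allclose(pd_.summary["high"], b)
        np.testing.assert_allclose(pd_.summary["mean_effect"], b)

    def test_arithmetic_example(self):
        D = np.array([[1.0], [2.0], [3.0]])
        pd_ = perceived_difficulty(np.zeros(1), 1.0, D)
        assert pd_.summary["mean_effect"].iloc[0] == pytest.approx(-2.0)
        assert pd_.summary["low"].iloc[0] == pytest.approx(-3.0)
        assert pd_.summary["high"].iloc[0] == pytest.approx(-1.0)

    def test_mean_effect_oracle(self, rng):
        b = rng.standard_normal(5)
        lam = 1.7
        D = rng.random((8, 5))
        pd_ = perceived_difficulty(b, lam, D)
        np.testing.assert_allclose(
            pd_.summary["mean_effect"], b - lam * D.mean(axis=0)
        )

    def test_mean_inside_interval(self, rng):
        pd_ = perceived_difficulty(rng.standard_normal(6), 0.9, rng.random((10, 6)))
        assert (pd_.summary["mean_effect"] >= pd_.summary["low"] - 1e-12).all()
        assert (pd_.summary["mean_effect"] <= pd_.summary["high"] + 1e-12).all()


class TestCovariateOverlay:
    def test_categorical_group_means(self):
        xi = np.zeros((4, 2))
        md = np.array([1.0, 1.0, 3.0, 3.0])
        cov = pd.DataFrame({"person": ["a", "b", "c", "d"], "grp": ["x", "x", "y", "y"]})
        out = covariate_overlay(xi, md, ["a", "b", "c", "d"], cov, "grp")
        g = out.group_summary.set_index("grp")
        assert g.loc["x", "mean"] == 1.0
        assert g.loc["y", "mean"] == 3.0

    def test_continuous_perfect_correlation(self):
        md = np.array([0.5, 1.5, 2.5])
        cov = pd.DataFrame({"person": ["a", "b", "c"], "age": md})
        out = covariate_overlay(np.zeros((3, 2)), md, ["a", "b", "c"], cov, "age")
        assert out.correlation == pytest.approx(1.0)

    def test_unmatched_ids_dropped_and_reported(self):
        cov = pd.DataFrame({"person": ["a", "c"], "grp": ["x", "y"]})
        out = covariate_overlay(
            np.zeros((3, 2)), np.ones(3), ["a", "b", "c"], cov, "grp"
        )
        assert out.unmatched_ids == ["b"]
        assert len(out.records) == 2

    def test_missing_variable(self):
        with pytest.raises(KeyError):
            covariate_overlay(
                np.zeros((2, 2)), np.ones(2), ["a", "b"],
                pd.DataFrame({"person": ["a"]}), "grp",
            )


class TestFeedbackReport:
    def test_ranking_matches_sort_oracle(self, recovery_run):
        truth, samples, aligned = recovery_run
        Y = truth.responses
        pid = Y.person_ids[0]
        rep = feedback_report(pid, aligned, Y, labels=truth.item_labels)
        dists = [r["distance"] for r in rep["items_by_distance"]]
        assert dists == sorted(dists, reverse=True)
        assert len(dists) == Y.n_items
        cl = [r["distance"] for r in rep["clusters_by_distance"]]
        assert cl == sorted(cl, reverse=True)
        assert rep["farthest_cluster"] == rep["clusters_by_distance"][0]["cluster"]
        assert 0.0 <= rep["accuracy"] <= 1.0

    def test_unknown_person(self, recovery_run):
        truth, _, aligned = recovery_run
        with pytest.raises(KeyError):
            feedback_report("nobody", aligned, truth.responses)


class TestDistanceAbilityIndependence:
    def test_true_positions_independent_of_ability(self, recovery_run):
        """The generator draws positions independently of ability, so true
        mean distances carry no ability signal."""
        truth, _, _ = recovery_run
        md_true = person_mean_distance(
            person_item_distances(truth.xi, truth.zeta)
        )
        assert abs(np.corrcoef(truth.theta, md_true)[0, 1]) < 0.2

    def test_estimated_map_is_not_an_ability_proxy(self, recovery_run):
        """Fitted mean distances must not re-express ability.  A moderate
        negative association is expected at this test length: a person's
        margin is split between theta and -lambda*(mean distance), and the
        split is only softly identified from response patterns, so the two
        estimation errors are anti-correlated."""
        truth, samples, aligned = recovery_run
        theta_hat = samples.pooled("theta").mean(axis=0)
        md = person_mean_distance(
            person_item_distances(aligned.xi_mean, aligned.zeta_mean)
        )
        r = np.corrcoef(theta_hat, md)[0, 1]
        assert abs(r) < 0.5
        # the map still tracks the true distances far better than ability
        md_true = person_mean_distance(person_item_distances(truth.xi, truth.zeta))
        assert np.corrcoef(md, md_true)[0, 1] > abs(r)
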