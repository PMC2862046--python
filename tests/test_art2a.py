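"""ART 2-A clustering: recovery, convergence, scans, XML results, occupancy."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import chemflow as cf
from chemflow.art2a import ART2AClassifier

RECOVERY_PARAMS = cf.ART2AParams(
    scale_to_unit_interval=False, contrast_threshold=0.0, seed=0
)
RECOVERY_VIGILANCE = 0.7  # between the between-cloud and within-cloud cosines


def cloud_table(seed, n_clusters=2, points=10, dim=8):
    spec = cf.CloudSpec(
        n_clusters=n_clusters, points_per_cluster=points, dim=dim, seed=seed
    )
    return cf.gen_vector_clouds(spec)


def make_table(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    t = pd.DataFrame(
        arr,
        index=[f"{prefix}-{i + 1:06d}" for i in range(arr.shape[0])],
        columns=[f"x{j}" for j in range(arr.shape[1])],
    )
    t.index.name = "uid"
    return t


class TestScaling:
    def test_affine_map_to_unit_interval(self):
        t = make_table([[2.0, 1.0], [4.0, 3.0], [6.0, 2.0]])
        scaled = cf.scale_unit_interval(t)
        assert scaled["x0"].tolist() == [0.0, 0.5, 1.0]
        assert scaled.to_numpy().min() == 0.0 and scaled.to_numpy().max() == 1.0

    def test_already_unit_interval_unchanged(self):
        t = make_table([[0.0, 1.0], [1.0, 0.0], [0.5, 0.25]])
        pd.testing.assert_frame_equal(cf.scale_unit_interval(t), t)

    def test_random_table_lands_in_unit_interval(self):
        rng = np.random.default_rng(4)
        scaled = cf.scale_unit_interval(make_table(rng.normal(size=(30, 4))))
        arr = scaled.to_numpy()
        assert arr.min() == 0.0 and arr.max() == 1.0
        assert (arr.min(axis=0) == 0.0).all() and (arr.max(axis=0) == 1.0).all()

    def test_constant_column_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            cf.scale_unit_interval(make_table([[1.0, 2.0], [1.0, 3.0]]))


class TestClassify:
    def test_identical_vectors_form_one_cluster(self):
        t = make_table(np.tile([0.3, 0.4, 0.5], (6, 1)))
        res = cf.art2a_classify(t, RECOVERY_PARAMS, 0.9)
        assert res.n_clusters == 1
        assert res.converged_by == "assignment-stability"
        assert res.epochs_run <= 2

    def test_separated_clouds_recover_generator_labels(self):
        table, labels = cloud_table(seed=5)
        res = cf.art2a_classify(table, RECOVERY_PARAMS, RECOVERY_VIGILANCE)
        uids = list(table.index)
        ari = adjusted_rand_score(
            [labels[u] for u in uids], [res.assignments[u] for u in uids]
        )
        assert ari == 1.0

    def test_orthogonal_vectors_go_singleton_at_high_vigilance(self):
        t = make_table(np.eye(5))
        res = cf.art2a_classify(t, RECOVERY_PARAMS, 0.9)
        # no vector passes another's vigilance test (pairwise dot = 0 < 0.9)
        assert res.n_clusters == 5
        assert sorted(res.assignments.values()) == [0, 1, 2, 3, 4]

    def test_every_uid_assigned_no_empty_clusters(self):
        table, _ = cloud_table(seed=6, n_clusters=3, dim=9)
        res = cf.art2a_classify(table, RECOVERY_PARAMS, 0.5)
        assert set(res.assignments) == set(table.index)
        used = set(res.assignments.values())
        assert used == set(range(res.n_clusters))

    def test_prototypes_unit_norm_and_input_dimensionality(self):
        table, _ = cloud_table(seed=7)
        res = cf.art2a_classify(table, RECOVERY_PARAMS, 0.6)
        for v in res.class_vectors:
            assert v.shape == (table.shape[1],)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_bitwise_reproducibility(self):
        table, _ = cloud_table(seed=8, n_clusters=3, dim=9)
        a = cf.art2a_classify(table, RECOVERY_PARAMS, 0.6)
        b = cf.art2a_classify(table, RECOVERY_PARAMS, 0.6)
        assert a.assignments == b.assignments
        assert all(
            (x == y).all() for x, y in zip(a.class_vectors, b.class_vectors)
        )

    def test_random_random_order_still_seed_reproducible(self):
        table, _ = cloud_table(seed=9)
        p = cf.ART2AParams(
            scale_to_unit_interval=False, contrast_threshold=0.0,
            presentation_order="random-random", seed=42,
        )
        assert cf.art2a_classify(table, p, 0.6).assignments == cf.art2a_classify(
            table, p, 0.6
        ).assignments

    def test_zero_dimensional_table_rejected(self):
        t = pd.DataFrame(index=["a", "b"])
        with pytest.raises(ValueError):
            cf.art2a_classify(t, RECOVERY_PARAMS, 0.5)

    def test_agrees_with_kmeans_on_separated_clouds(self):
        """Independent comparator: k-means with the true k finds the same partition."""
        table, labels = cloud_table(seed=10)
        res = cf.art2a_classify(table, RECOVERY_PARAMS, RECOVERY_VIGILANCE)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
            table.to_numpy()
        )
        uids = list(table.index)
        assert adjusted_rand_score(km, [res.assignments[u] for u in uids]) == 1.0


class TestEstimatorAPI:
    def test_get_set_params_roundtrip(self):
        est = ART2AClassifier(vigilance=0.55)
        est2 = ART2AClassifier(**est.get_params())
        assert est2.get_params() == est.get_params()
        est.set_params(learning_rate=0.2)
        assert est.get_params()["learning_rate"] == 0.2

    def test_fit_predict_labels_shape(self):
        table, _ = cloud_table(seed=12)
        labels = ART2AClassifier(
            vigilance=0.7, contrast_threshold=0.0, random_state=0
        ).fit_predict(table.to_numpy())
        assert labels.shape == (table.shape[0],)

    def test_invalid_vigilance_rejected(self):
        with pytest.raises(ValueError):
            ART2AClassifier(vigilance=1.5).fit(np.eye(3))


class TestScan:
    def test_scan_length_matches_range(self):
        table, _ = cloud_table(seed=13)
        p = cf.ART2AParams(
            scale_to_unit_interval=False, contrast_threshold=0.0,
            vigilance_range=(0.1, 0.3, 0.1),
        )
        results = cf.art2a_scan(table, p)
        assert [r.vigilance for r in results] == pytest.approx([0.1, 0.2, 0.3])

    def test_single_value_range(self):
        table, _ = cloud_table(seed=13)
        p = cf.ART2AParams(
            scale_to_unit_interval=False, contrast_threshold=0.0,
            vigilance_range=(0.5, 0.5, 0.1),
        )
        assert len(cf.art2a_scan(table, p)) == 1

    def test_cluster_count_weakly_increasing_over_seeds(self):
        """Vigilance monotonicity holds in at least 95% of adjacent steps."""
        good = total = 0
        for seed in range(20):
            table, _ = cloud_table(seed=seed, n_clusters=3, dim=9, points=8)
            p = cf.ART2AParams(
                scale_to_unit_interval=False, contrast_threshold=0.0,
                vigilance_range=(0.1, 0.9, 0.1), seed=seed,
            )
            counts = [r.n_clusters for r in cf.art2a_scan(table, p)]
            steps = list(zip(counts, counts[1:]))
            good += sum(1 for a, b in steps if b >= a)
            total += len(steps)
        assert good / total >= 0.95


class TestResultXML:
    def test_round_trip(self, tmp_path):
        table, _ = cloud_table(seed=14)
        p = cf.ART2AParams(
            scale_to_unit_interval=False, contrast_threshold=0.0,
            vigilance_range=(0.3, 0.7, 0.2),
        )
        results = cf.art2a_scan(table, p)
        path = tmp_path / "run.xml.gz"
        cf.write_result_xml(results, path)
        back = cf.read_result_xml(path)
        assert len(back) == len(results)
        for a, b in zip(results, back):
            assert a.assignments == b.assignments
            assert a.vigilance == b.vigilance
            assert a.epochs_run == b.epochs_run
            assert a.converged_by == b.converged_by
            np.testing.assert_allclose(
                np.array(a.class_vectors), np.array(b.class_vectors), rtol=1e-12
            )
        assert back[0].params == p

    def test_empty_result_list(self, tmp_path):
        path = tmp_path / "empty.xml.gz"
        cf.write_result_xml([], path)
        assert cf.read_result_xml(path) == []

    def test_not_gzip_is_a_format_error(self, tmp_path):
        path = tmp_path / "plain.xml"
        path.write_text("<art2a-run/>")
        with pytest.raises(ValueError, match="gzip"):
            cf.read_result_xml(path)


class TestOccupancy:
    def test_single_cluster_single_source(self):
        res = cf.ART2AResult(0.5, {"a": 0, "b": 0}, [np.ones(2)], 1, "assignment-stability")
        occ = cf.occupancy(res, {"a": "lib", "b": "lib"})
        assert occ["fraction"].tolist() == [1.0]

    def test_two_pure_clusters_split_sources(self):
        res = cf.ART2AResult(
            0.5, {"a": 0, "b": 0, "c": 1, "d": 1}, [np.ones(2)] * 2, 1, "assignment-stability"
        )
        occ = cf.occupancy(res, {"a": "s1", "b": "s1", "c": "s2", "d": "s2"})
        lookup = {(r.cluster, r.source): r.fraction for r in occ.itertuples()}
        assert lookup == {(0, "s1"): 1.0, (1, "s2"): 1.0}

    def test_fractions_per_source_sum_to_one(self):
        table, labels = cloud_table(seed=15, n_clusters=3, dim=9)
        res = cf.art2a_classify(table, RECOVERY_PARAMS, 0.6)
        sources = {u: f"src{labels[u] % 2}" for u in table.index}
        occ = cf.occupancy(res, sources)
        sums = occ.groupby("source")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_unlabeled_uid_rejected(self):
        res = cf.ART2AResult(0.5, {"a": 0}, [np.ones(2)], 1, "assignment-stability")
        with pytest.raises(ValueError):
            cf.occupancy(res, {})
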