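import numpy as np
import pandas as pd
import pytest

from tractoshape.alignment import pca_align
from tractoshape.clustering import (
    average_shape,
    composition_table,
    joint_group_analysis,
    kmeans,
    sweep_k,
)
from tractoshape.geometry import PointCloud
from tractoshape.manifold import Embedding
from tractoshape.synthetic import generate_shape, mixture_spec, random_rigid_pose


def _embedding(coords, ids=None):
    coords = np.asarray(coords, float)
    n, d = coords.shape
    ids = tuple(ids or (f"c{i}" for i in range(n)))
    return Embedding(
        coordinates=coords,
        ids=ids,
        n_neighbors=0,
        n_dims=d,
        eigenvalues=np.zeros(d),
        residual_variance=0.0,
        component_map={i: 0 for i in ids},
    )


def _blobs(rng, centers, n_per=20, sd=0.3):
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, sd, size=(n_per, 2)))
        labels += [i] * n_per
    return np.vstack(pts), np.array(labels)


class TestKMeans:
    def test_two_blobs_recovered(self, rng):
        coords, truth = _blobs(rng, [(0, 0), (10, 10)])
        cl = kmeans(_embedding(coords), 2, seed=0)
        # partition equals blob membership up to label naming
        assert len(set(zip(truth.tolist(), cl.labels.tolist()))) == 2

    def test_k1_center_is_mean_and_inertia_total_sse(self, rng):
        coords, _ = _blobs(rng, [(0, 0)], n_per=30)
        cl = kmeans(_embedding(coords), 1, seed=0)
        np.testing.assert_allclose(cl.centers[0], coords.mean(axis=0), atol=1e-9)
        assert cl.inertia == pytest.approx(np.sum((coords - coords.mean(0)) ** 2))

    def test_deterministic_under_seed(self, rng):
        coords, _ = _blobs(rng, [(0, 0), (5, 5), (0, 9)])
        a = kmeans(_embedding(coords), 3, seed=7)
        b = kmeans(_embedding(coords), 3, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_more_restarts_never_worse(self, rng):
        coords, _ = _blobs(rng, [(0, 0), (4, 0), (2, 5), (8, 3)], n_per=15)
        emb = _embedding(coords)
        assert kmeans(emb, 4, seed=3, n_init=10).inertia <= kmeans(emb, 4, seed=3, n_init=1).inertia + 1e-9

    def test_k_bounds(self, rng):
        coords, _ = _blobs(rng, [(0, 0)], n_per=5)
        with pytest.raises(ValueError):
            kmeans(_embedding(coords), 6, seed=0)


class TestAverageShape:
    def _clustered(self, clouds, labels, centers=None):
        coords = np.array([[float(lab), 0.0] for lab in labels])
        emb = _embedding(coords, ids=[c.source_id for c in clouds])
        k = len(set(labels))
        return kmeans(emb, k, seed=0)

    def test_singleton_cluster_returns_member(self, rng):
        c0 = generate_shape("U", rng=rng, source_id="a")
        c1 = generate_shape("I", rng=rng, source_id="b")
        cl = self._clustered([c0, c1], [0, 1])
        avg = average_shape([c0, c1], cl, cl.labels[0])
        np.testing.assert_allclose(avg.points, c0.points, atol=1e-9)

    def test_identical_copies_in_random_poses_average_to_shape(self, rng):
        base = generate_shape("C", rng=rng, pose=False, source_id="base")
        members = [base]
        for i in range(3):
            Q, t = random_rigid_pose(rng, 30.0)
            members.append(PointCloud(base.points @ Q.T + t, source_id=f"m{i}"))
        cl = self._clustered(members, [0, 0, 0, 0])
        avg = average_shape(members, cl, 0)
        from tractoshape.alignment import align_to_reference

        _, rmsd, _ = align_to_reference(avg, base)
        assert rmsd <= 1e-6

    def test_reversed_member_is_flip_aligned_before_averaging(self, rng):
        base = generate_shape("J", rng=rng, pose=False, source_id="fwd")
        rev = PointCloud(base.points[::-1].copy(), source_id="rev")
        cl = self._clustered([base, rev], [0, 0])
        avg = average_shape([base, rev], cl, 0)
        from tractoshape.alignment import align_to_reference

        _, rmsd, _ = align_to_reference(avg, base)
        assert rmsd <= 1e-6

    def test_rigid_equivariance(self, rng):
        members = [
            generate_shape("U", rng=rng, noise_sigma=1.0, source_id=f"m{i}")
            for i in range(4)
        ]
        cl = self._clustered(members, [0, 0, 0, 0])
        avg = average_shape(members, cl, 0)
        Q, t = random_rigid_pose(rng, 20.0)
        moved = [PointCloud(m.points @ Q.T + t, source_id=m.source_id) for m in members]
        avg_moved = average_shape(moved, cl, 0)
        from tractoshape.alignment import align_to_reference

        _, rmsd, _ = align_to_reference(avg_moved, avg)
        assert rmsd <= 1e-6


class TestCompositionTable:
    def test_single_cluster_percentages(self):
        labels = {f"b{i}": 0 for i in range(4)}
        annotations = {"b0": "A", "b1": "A", "b2": "A", "b3": "B"}
        pct, counts = composition_table(labels, annotations)
        assert pct.loc[0, "A"] == pytest.approx(75.0)
        assert pct.loc[0, "B"] == pytest.approx(25.0)
        assert counts.loc[0].sum() == 4

    def test_labels_equal_annotations_gives_pure_rows(self):
        labels = {"a": 0, "b": 1, "c": 0, "d": 1}
        annotations = {"a": "x", "b": "y", "c": "x", "d": "y"}
        pct, _ = composition_table(labels, annotations)
        assert pct.loc[0, "x"] == 100.0
        assert pct.loc[1, "y"] == 100.0

    def test_rows_sum_to_100_and_unannotated_column(self):
        labels = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1}
        annotations = {"a": "x", "c": "y", "d": "x"}
        pct, counts = composition_table(labels, annotations)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=1e-9)
        assert counts.loc[0, "unannotated"] == 1

    def test_hand_computed_2x2(self):
        labels = dict([("a", 0)] * 1, **{f"x{i}": 0 for i in range(3)}, **{f"y{i}": 1 for i in range(5)})
        annotations = {**{f"x{i}": "U" for i in range(3)}, "a": "C", **{f"y{i}": ("U" if i < 2 else "C") for i in range(5)}}
        pct, _ = composition_table(labels, annotations)
        assert pct.loc[0, "U"] == pytest.approx(75.0)
        assert pct.loc[1, "C"] == pytest.approx(60.0)


class TestSweepK:
    def test_three_blobs_silhouette_peaks_at_three(self, rng):
        coords, _ = _blobs(rng, [(0, 0), (12, 0), (6, 10)])
        emb = _embedding(coords)
        table = sweep_k(emb, range(2, 7), seed=0)
        best = table.loc[table["silhouette"].idxmax(), "k"]
        assert best == 3

    def test_inertia_non_increasing_and_large_k_ok(self, rng):
        coords, _ = _blobs(rng, [(0, 0), (8, 2)], n_per=10)
        emb = _embedding(coords)
        table = sweep_k(emb, range(2, len(coords) - 1), seed=1)
        assert (np.diff(table["inertia"]) <= 1e-9).all()


class TestJointGroupAnalysis:
    def test_identical_groups_have_equal_shares(self, rng):
        clouds = [
            generate_shape(f, rng=rng, noise_sigma=1.2, source_id=f"{f}{i}")
            for f in ("I", "U", "C") for i in range(5)
        ]
        copy = [PointCloud(c.points.copy(), source_id=c.source_id) for c in clouds]
        res = joint_group_analysis({"A": clouds, "B": copy}, k=2, seed=0, n_neighbors=4)
        np.testing.assert_allclose(
            res.group_composition["A"], res.group_composition["B"], atol=1e-9
        )
        np.testing.assert_allclose(res.group_composition.sum(axis=0), 100.0)

    def test_empty_group_rejected(self, rng):
        c = generate_shape("U", rng=rng)
        with pytest.raises(ValueError, match="empty"):
            joint_group_analysis({"A": [c], "B": []})


def test_mixture_spec_counts():
    spec = mixture_spec(0.7, 100)
    assert sum(spec.values()) == 100
    assert spec["I"] + spec["L"] == 70
    with pytest.raises(ValueError):
        mixture_spec(1.5, 10)
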