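import itertools

import numpy as np
import pytest

import whitefly_msi as wm
from whitefly_msi.segmentation import (
    ANATOMY_BACKGROUND,
    ANATOMY_BODY,
    ANATOMY_WING,
    PCABasis,
    ScalerStats,
    SegmentationModel,
    apply_scaler,
    assign_clusters_from_centroids,
    fit_segmentation_model,
)

from conftest import make_table


class TestRobustScaler:
    def test_hand_quartiles(self):
        """Band {1..5}: median 3, IQR 2 under linear-interpolation quartiles."""
        table = make_table(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        scaled, stats = wm.robust_center_spectra(table)
        assert stats.center[0] == 3.0 and stats.scale[0] == 2.0
        assert np.allclose(scaled.spectra[:, 0], [-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_constant_band_fallback(self, caplog):
        table = make_table(np.full((4, 2), 7.0))
        scaled, stats = wm.robust_center_spectra(table)
        assert np.all(stats.scale == 1.0)
        assert np.all(scaled.spectra == 0.0)

    def test_stored_statistics_reproduce_transform(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.normal(size=(50, 6)))
        scaled, stats = wm.robust_center_spectra(table)
        again = apply_scaler(table, stats)
        assert np.array_equal(scaled.spectra, again.spectra)

    def test_centre_only_mode(self):
        table = make_table(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        scaled, stats = wm.robust_center_spectra(table, with_scaling=False)
        assert np.all(stats.scale == 1.0)
        assert np.allclose(scaled.spectra[:, 0], [-2, -1, 0, 1, 2])


def svd_pca_oracle(x, k):
    """Full-batch PCA by SVD of the centred matrix."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (len(x) - 1)
    return vt[:k], var[:k] / var.sum()


class TestIncrementalPCA:
    def test_rank_one_explains_everything(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=8)
        x = np.outer(rng.normal(size=40), direction) + 3.0
        basis = wm.fit_incremental_pca(make_table(x), n_components=3, batch_size=40)
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_batch_matches_svd_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=(200, 10))
            basis = wm.fit_incremental_pca(make_table(x), 3, batch_size=200)
            comps, evr = svd_pca_oracle(x, 3)
            assert np.allclose(basis.explained_variance_ratio, evr, atol=1e-8)
            for got, want in zip(basis.components, comps):
                assert min(np.abs(got - want).max(), np.abs(got + want).max()) < 1e-8

    def test_multi_batch_close_to_single_batch(self):
        """Incremental SVD updates approximate (not equal) the one-batch fit."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 10))
        one = wm.fit_incremental_pca(make_table(x), 3, batch_size=200)
        four = wm.fit_incremental_pca(make_table(x), 3, batch_size=50)
        assert np.abs(one.explained_variance_ratio - four.explained_variance_ratio).max() < 0.05

    def test_batch_size_below_components_errors(self):
        with pytest.raises(ValueError):
            wm.fit_incremental_pca(make_table(np.eye(6)), 3, batch_size=2)

    def test_evr_non_increasing_and_bounded(self):
        x = np.random.default_rng(4).normal(size=(100, 7))
        basis = wm.fit_incremental_pca(make_table(x), 3, batch_size=100)
        evr = basis.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-12


class TestProjection:
    def _basis(self):
        comps = np.zeros((3, 5))
        comps[0, 0] = comps[1, 1] = comps[2, 2] = 1.0
        return PCABasis(mean=np.arange(5.0), components=comps,
                        explained_variance_ratio=np.array([0.6, 0.3, 0.1]))

    def test_mean_maps_to_origin(self):
        basis = self._basis()
        assert np.allclose(wm.project_pca(np.arange(5.0)[None, :], basis), 0.0)

    def test_basis_image(self):
        basis = self._basis()
        row = (np.arange(5.0) + basis.components[0])[None, :]
        assert np.allclose(wm.project_pca(row, basis), [[1.0, 0.0, 0.0]])

    def test_fit_and_transform_scores_agree(self):
        x = np.random.default_rng(6).normal(size=(80, 6))
        table = make_table(x)
        basis = wm.fit_incremental_pca(table, 3, batch_size=80)
        s1 = wm.project_pca(table, basis)
        s2 = wm.project_pca(x, basis)
        assert np.array_equal(s1, s2)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            wm.project_pca(np.zeros((2, 4)), self._basis())


def brute_force_min_wcss(points):
    """Exhaustive minimum within-cluster sum of squares over all 3-partitions."""
    best = np.inf
    for assign in itertools.product(range(3), repeat=len(points)):
        if len(set(assign)) < 3:
            continue
        assign = np.array(assign)
        wcss = 0.0
        for k in range(3):
            members = points[assign == k]
            wcss += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best


def wcss_of(points, assignments):
    total = 0.0
    for k in np.unique(assignments):
        members = points[assignments == k]
        total += ((members - members.mean(axis=0)) ** 2).sum()
    return total


class TestKMeans3:
    def test_separable_blobs_recovered_exactly(self):
        rng = np.random.default_rng(8)
        centres = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
        truth = np.repeat(np.arange(3), 30)
        pts = centres[truth] + rng.normal(0, 0.01, size=(90, 3))
        _, assign = wm.fit_kmeans3(pts, seed=0)
        # same partition up to relabelling
        for k in range(3):
            assert len(np.unique(assign[truth == k])) == 1
        assert len(np.unique(assign)) == 3

    def test_matches_brute_force_on_line(self):
        pts = np.array([[v, 0.0, 0.0] for v in (0, 0.1, 5, 5.1, 10, 10.1)])
        _, assign = wm.fit_kmeans3(pts, seed=1)
        assert wcss_of(pts, assign) == pytest.approx(brute_force_min_wcss(pts), abs=1e-9)
        groups = {tuple(np.flatnonzero(assign == k)) for k in range(3)}
        assert groups == {(0, 1), (2, 3), (4, 5)}

    def test_duplication_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(30, 3)) + np.repeat(np.eye(3) * 8, 10, axis=0)
        c1, _ = wm.fit_kmeans3(pts, seed=2)
        c2, _ = wm.fit_kmeans3(np.vstack([pts, pts]), seed=2)
        assert np.allclose(np.sort(c1, axis=0), np.sort(c2, axis=0), atol=1e-8)

    def test_fewer_than_three_distinct_points_errors(self):
        with pytest.raises(ValueError):
            wm.fit_kmeans3(np.zeros((10, 3)), seed=0)

    def test_restarts_never_worse_than_single(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(40, 3))
        _, multi = wm.fit_kmeans3(pts, seed=3, n_restarts=10)
        _, single = wm.fit_kmeans3(pts, seed=3, n_restarts=1)
        assert wcss_of(pts, multi) <= wcss_of(pts, single) + 1e-9


def model_with_centroids(centroids, anatomy=None):
    b = 4
    return SegmentationModel(
        scaler=ScalerStats(center=np.zeros(b), scale=np.ones(b)),
        basis=PCABasis(mean=np.zeros(b), components=np.eye(3, b),
                       explained_variance_ratio=np.array([0.5, 0.3, 0.2])),
        centroids=np.asarray(centroids, dtype=float),
        anatomy=anatomy,
    )


class TestAssignment:
    centroids = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 4, 0]])

    def test_point_at_centroid(self):
        model = model_with_centroids(self.centroids)
        assert assign_clusters_from_centroids(self.centroids, model).tolist() == [0, 1, 2]

    def test_equidistant_tie_goes_to_lowest_index(self):
        model = model_with_centroids(self.centroids)
        mid = np.array([[2.0, 0.0, 0.0]])  # equidistant from centroids 0 and 1
        assert assign_clusters_from_centroids(mid, model)[0] == 0

    def test_training_assignments_reproduced(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(60, 3)) + np.repeat(np.eye(3) * 6, 20, axis=0)
        centroids, assign = wm.fit_kmeans3(pts, seed=4)
        model = model_with_centroids(centroids)
        assert np.array_equal(assign_clusters_from_centroids(pts, model), assign)


class TestAnatomyMapping:
    def test_majority_vote_bijection(self):
        model = model_with_centroids(np.eye(3))
        assign = np.array([0] * 5 + [1] * 5 + [2] * 5)
        truth = np.array([ANATOMY_WING] * 5 + [ANATOMY_BODY] * 5 + [ANATOMY_BACKGROUND] * 5)
        mapped = wm.map_clusters_to_anatomy(model, assign, truth)
        assert mapped.anatomy == {0: ANATOMY_WING, 1: ANATOMY_BODY, 2: ANATOMY_BACKGROUND}

    def test_manual_mapping_stored_verbatim(self):
        model = model_with_centroids(np.eye(3))
        mapped = wm.map_clusters_to_anatomy(model, manual={0: "wing", 1: "body", 2: "background"})
        assert mapped.anatomy == {0: ANATOMY_WING, 1: ANATOMY_BODY, 2: ANATOMY_BACKGROUND}

    def test_degenerate_scene_errors(self):
        model = model_with_centroids(np.eye(3))
        assign = np.array([0] * 5 + [1] * 5 + [2] * 5)
        truth = np.full(15, ANATOMY_BACKGROUND)
        with pytest.raises(ValueError, match="bijection|manual"):
            wm.map_clusters_to_anatomy(model, assign, truth)


def test_model_json_round_trip(tmp_path, greycard_scene):
    cube, truth = greycard_scene
    table = wm.cube_to_table(wm.trim_bands(cube))
    model, assign = fit_segmentation_model(table, seed=5)
    codes = truth.anatomy[table.coords[:, 0], table.coords[:, 1]]
    model = wm.map_clusters_to_anatomy(model, assign, codes)
    path = str(tmp_path / "seg.model.json")
    model.save(path)
    back = SegmentationModel.load(path)
    assert np.array_equal(back.centroids, model.centroids)
    assert back.anatomy == model.anatomy
    labels_a = wm.segment_cube(wm.trim_bands(cube), model)
    labels_b = wm.segment_cube(wm.trim_bands(cube), back)
    assert np.array_equal(labels_a, labels_b)


def test_single_scene_segmentation_recovers_truth(greycard_scene):
    cube, truth = greycard_scene
    table = wm.cube_to_table(wm.trim_bands(cube))
    model, assign = fit_segmentation_model(table, seed=6)
    codes = truth.anatomy[table.coords[:, 0], table.coords[:, 1]]
    model = wm.map_clusters_to_anatomy(model, assign, codes)
    labels = wm.segment_cube(wm.trim_bands(cube), model)
    assert (labels == truth.anatomy).mean() >= 0.99
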