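"""Hybrid-kernel K-means: seeding, assignment oracle, convergence, elbow,
and the triplet-library protocol."""

import numpy as np
import pytest
from sklearn.base import clone

from hcwssc import (
    HybridKernelKMeans,
    HyperCube,
    MEASURES,
    assign,
    classify_triplet,
    dissimilarity,
    elbow,
    fit_cube,
    init_centroids,
    make_endmembers,
    triplet_suite_accuracy,
    update_centroids,
)
from hcwssc.errors import ConfigurationError


class TestInitCentroids:
    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(0.1, 1.0, size=(30, 6))
        for init in ("random", "d2"):
            c1 = init_centroids(X, 4, random_state=7, init=init)
            c2 = init_centroids(X, 4, random_state=7, init=init)
            assert np.array_equal(c1, c2)

    def test_centroids_are_sample_rows(self, rng):
        X = rng.uniform(0.1, 1.0, size=(20, 5))
        for init in ("random", "d2"):
            for c in init_centroids(X, 5, random_state=1, init=init):
                assert any(np.array_equal(c, row) for row in X)

    def test_k_equals_pixel_count_is_exhaustive(self, rng):
        X = rng.uniform(0.1, 1.0, size=(6, 4))
        cents = init_centroids(X, 6, random_state=0)
        assert np.array_equal(np.sort(cents, axis=0), np.sort(X, axis=0))

    def test_k_beyond_distinct_pixels_rejected(self):
        X = np.tile([0.2, 0.4], (10, 1))  # one distinct pixel
        with pytest.raises(ConfigurationError):
            init_centroids(X, 2, random_state=0)


class TestAssign:
    def test_single_centroid(self, rng):
        X = rng.uniform(0.1, 1.0, size=(11, 5))
        assert np.all(assign(X, X[:1]) == 0)

    def test_pixel_equal_to_centroid_wins(self, rng):
        cents = rng.uniform(0.1, 1.0, size=(2, 6))
        X = cents[1][None, :]
        for m in MEASURES:
            assert assign(X, cents, measures=(m,))[0] == 1

    def test_matches_brute_force_oracle(self, rng):
        """Vectorised assignment equals the explicit triple loop."""
        for _ in range(25):
            n_bands = rng.randint(3, 9)
            X = rng.uniform(0.05, 1.0, size=(rng.randint(4, 65), n_bands))
            C = rng.uniform(0.05, 1.0, size=(rng.randint(2, 6), n_bands))
            k = rng.randint(1, 3)
            measures = list(rng.choice(MEASURES, size=k, replace=False))
            weights = rng.uniform(0.2, 3.0, size=k)
            labels = assign(X, C, measures, weights)
            for i in range(X.shape[0]):
                scores = [
                    sum(w * dissimilarity(m, X[i], C[j])
                        for m, w in zip(measures, weights))
                    for j in range(C.shape[0])
                ]
                assert labels[i] == int(np.argmin(scores))


class TestUpdateCentroids:
    def test_hand_mean(self):
        X = np.array([[0.0, 0.0], [2.0, 4.0]])
        cents = update_centroids(X, np.array([0, 0]), 1)
        assert np.allclose(cents[0], [1.0, 2.0])

    def test_singleton_cluster(self, rng):
        X = rng.uniform(size=(4, 3))
        labels = np.array([0, 1, 1, 1])
        cents = update_centroids(X, labels, 2)
        assert np.allclose(cents[0], X[0])

    def test_idempotent_on_unchanged_labels(self, rng):
        X = rng.uniform(size=(10, 4))
        labels = rng.randint(0, 3, size=10)
        labels[:3] = [0, 1, 2]
        c1 = update_centroids(X, labels, 3)
        c2 = update_centroids(X, labels, 3)
        assert np.array_equal(c1, c2)

    def test_empty_cluster_reseeds_to_farthest_pixel(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]])
        labels = np.array([0, 0, 0])
        current = np.array([[0.05, 0.0], [0.0, 0.0]])
        cents = update_centroids(X, labels, 2, centroids=current)
        assert np.allclose(cents[1], [5.0, 5.0])  # farthest from old centroid 1


class TestFit:
    def test_recovers_two_separated_blobs(self, rng):
        a = rng.normal([0.2] * 6, 0.01, size=(30, 6))
        b = rng.normal([0.9] * 6, 0.01, size=(30, 6))
        X = np.abs(np.vstack([a, b]))
        model = HybridKernelKMeans(n_clusters=2, max_iter=20, n_init=5,
                                   random_state=0)
        labels = model.fit_predict(X)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_fixed_point_converges_in_one_pass(self):
        X = np.array([[0.0, 0.0], [0.0, 0.1], [5.0, 5.0], [5.0, 5.1]])
        model = HybridKernelKMeans(n_clusters=2, max_iter=10,
                                   change_threshold=0.0, n_init=1, init="d2",
                                   random_state=3)
        model.fit(X)
        assert model.converged_
        assert model.n_iter_ == 1
        assert model.changed_fraction_[-1] == 0.0

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(0.05, 1.0, size=(60, 8))
        kw = dict(n_clusters=3, measures=("ED", "SAC"), weights=(1.0, 2.0),
                  max_iter=8, random_state=11)
        m1 = HybridKernelKMeans(**kw).fit(X)
        m2 = HybridKernelKMeans(**kw).fit(X)
        assert np.array_equal(m1.labels_, m2.labels_)
        assert np.array_equal(m1.cluster_centers_, m2.cluster_centers_)
        assert m1.inertia_ == m2.inertia_

    def test_single_ed_objective_descends(self, rng):
        X = rng.uniform(0.05, 1.0, size=(120, 6))
        model = HybridKernelKMeans(n_clusters=4, measures=("ED",),
                                   max_iter=15, random_state=2).fit(X)
        trace = np.array(model.objective_trace_)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_hybrid_trace_recorded_not_asserted(self, rng):
        X = rng.uniform(0.05, 1.0, size=(50, 6))
        model = HybridKernelKMeans(n_clusters=3, measures=("ED", "SAC"),
                                   max_iter=6, random_state=2).fit(X)
        assert len(model.objective_trace_) == model.n_iter_ + 1
        assert len(model.changed_fraction_) == model.n_iter_

    def test_change_threshold_stops_early(self, noisy_scene):
        cube, _ = noisy_scene
        X = cube.valid_pixels()
        strict = HybridKernelKMeans(n_clusters=5, max_iter=30,
                                    change_threshold=0.0, init="d2",
                                    random_state=1).fit(X)
        loose = HybridKernelKMeans(n_clusters=5, max_iter=30,
                                   change_threshold=0.2, init="d2",
                                   random_state=1).fit(X)
        assert loose.n_iter_ <= strict.n_iter_
        assert loose.converged_

    def test_sklearn_api(self, rng):
        model = HybridKernelKMeans(n_clusters=2)
        assert clone(model).get_params() == model.get_params()
        X = rng.uniform(0.05, 1.0, size=(20, 5))
        labels = model.fit_predict(X)
        assert np.array_equal(model.predict(X), labels)

    def test_masked_pixels_get_sentinel_label(self, small_cube):
        model = HybridKernelKMeans(n_clusters=2, random_state=0)
        labels = fit_cube(small_cube, model)
        assert labels[0, 0] == -1
        assert (labels[small_cube.mask] >= 0).all()


class TestElbow:
    def test_three_planted_classes_suggest_three(self, rng):
        # equidistant (simplex) class centres: merging any two at K=2 is as
        # costly as pooling everything, so the inertia knee sits at K=3
        centers = np.full((3, 5), 0.1)
        centers[np.arange(3), np.arange(3)] = 0.9
        X = np.abs(np.repeat(centers, 40, axis=0)
                   + rng.normal(0, 0.01, size=(120, 5)))
        curve = elbow(X, range(1, 7), random_state=0)
        assert curve.suggested_k == 3
        assert all(v >= 0 for v in curve.inertia)

    def test_inertia_zero_at_k_equals_distinct_pixels(self, rng):
        X = rng.uniform(0.1, 1.0, size=(8, 4))
        curve = elbow(X, [8], random_state=0, n_init=1)
        assert curve.inertia[0] == pytest.approx(0.0, abs=1e-20)

    def test_inertia_non_increasing_with_restarts(self, rng):
        X = rng.uniform(0.05, 1.0, size=(100, 6))
        curve = elbow(X, range(1, 8), random_state=4, n_init=5)
        assert np.all(np.diff(curve.inertia) <= 1e-9)


class TestTriplets:
    def test_identical_pair_plus_orthogonal_succeeds_everywhere(self):
        u = np.array([1.0, 0.0, 0.5, 0.1])
        v = np.array([0.0, 1.0, 0.1, 0.5])
        spectra = [u, u.copy(), v]
        labels = ["a", "a", "b"]
        for m in MEASURES:
            assert classify_triplet(spectra, labels, measures=(m,),
                                    random_state=0)

    def test_brightness_gap_fools_ed_but_not_sac(self, rng):
        # same shape at scales 0.7 / 1.3; odd spectrum at a small angle with
        # intermediate brightness: the brightness gap exceeds the shape gap
        # in ED terms, so ED splits the pair while SAC does not.
        u = rng.uniform(0.3, 1.0, 16)
        u /= np.linalg.norm(u)
        w = rng.uniform(0.3, 1.0, 16)
        w -= u * np.dot(w, u) / np.dot(u, u)
        w /= np.linalg.norm(w)
        theta = 0.3
        v = np.cos(theta) * u + np.sin(theta) * w
        spectra = [0.7 * u, 1.3 * u, 1.0 * v]
        labels = ["a", "a", "b"]
        assert classify_triplet(spectra, labels, measures=("SAC",),
                                random_state=0)
        assert not classify_triplet(spectra, labels, measures=("ED",),
                                    random_state=0)

    def test_malformed_groups_rejected(self):
        u = np.array([1.0, 2.0])
        with pytest.raises(ConfigurationError):
            classify_triplet([u, u], ["a", "a"], random_state=0)
        with pytest.raises(ConfigurationError):
            classify_triplet([u, u, u], ["a", "b", "c"], random_state=0)
        with pytest.raises(ConfigurationError):
            classify_triplet([u, u, u], ["a", "a", "a"], random_state=0)

    def test_suite_accuracy_bounds_and_shape(self):
        ems = make_endmembers(3, 20, 0.4, seed=2)
        from hcwssc import TripletSpec, make_triplets

        suite = make_triplets(TripletSpec(n_groups=12, seed=2), ems)
        acc, outcomes = triplet_suite_accuracy(suite, measures=("SAC",),
                                               random_state=0)
        assert 0.0 <= acc <= 1.0
        assert outcomes.shape == (12,)
        assert acc == pytest.approx(outcomes.mean())


def test_runtime_grows_roughly_linearly_in_pixels():
    """Log-log slope of fit time versus pixel count stays near one."""
    import time

    from hcwssc import SceneSpec, make_scene, run_hcwssc

    sizes = [24, 48, 96]
    times = []
    for s in sizes:
        cube, _ = make_scene(SceneSpec(rows=s, cols=s, n_bands=16,
                                       n_classes=4, seed=9))
        best = np.inf
        for _ in range(2):
            t0 = time.perf_counter()
            run_hcwssc(cube, n_clusters=4, random_state=0, n_init=1,
                       max_iter=5)
            best = min(best, time.perf_counter() - t0)
        times.append(best)
    slope = np.polyfit(np.log([s * s for s in sizes]), np.log(times), 1)[0]
    assert 0.5 < slope < 1.5  # broad guard; the acceptance suite is stricter
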