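"""Filter feature selection: Pearson, CV, weights, pair choice."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from hcwssc import (
    FeatureMap,
    MEASURES,
    MeasurePairSelector,
    Spectrum,
    coefficient_of_variation,
    compute_weights,
    feature_map,
    pearson,
    run_selection,
    select_pair,
)
from hcwssc.errors import DegenerateInputError, SelectionError


def _map_from(values, measure):
    values = np.asarray(values, dtype=float).reshape(1, -1)
    return FeatureMap(
        measure=measure,
        values=values,
        reference=Spectrum(np.array([1.0, 1.0])),
        mask=np.ones_like(values, dtype=bool),
    )


class TestPearson:
    def test_self_correlation(self, rng):
        a = rng.uniform(size=50)
        assert pearson(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_exact_anticorrelation(self):
        assert pearson([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0, abs=1e-12)

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = rng.normal(size=(2, 20))
            assert abs(pearson(a, b)) <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCoefficientOfVariation:
    def test_constant_positive_map_is_zero(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0

    def test_population_sigma_convention(self):
        # values {1, 3}: population sigma 1, mean 2
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(0.5)

    def test_ddof_configurable(self):
        vals = [1.0, 3.0]
        assert coefficient_of_variation(vals, ddof=1) == pytest.approx(
            np.std(vals, ddof=1) / 2.0
        )

    def test_scale_invariance(self, rng):
        v = rng.uniform(0.5, 2.0, 40)
        assert coefficient_of_variation(v * 7.3) == pytest.approx(
            coefficient_of_variation(v), abs=1e-12
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            coefficient_of_variation([0.0, 0.0])


class TestComputeWeights:
    def test_symmetric_case(self):
        norm, w = compute_weights(1.0, 1.0, 1.0, 1.0)
        assert norm == (0.5, 0.5)
        assert w == (0.5, 0.5)

    def test_hand_example(self):
        # shares (0.25, 0.75); divided by means (2, 5)
        norm, w = compute_weights(1.0, 3.0, 2.0, 5.0)
        assert norm == pytest.approx((0.25, 0.75))
        assert w == pytest.approx((0.125, 0.15))

    def test_norm_weights_sum_to_one_and_keep_cv_ratio(self, rng):
        for _ in range(100):
            cv1, cv2 = rng.uniform(0.01, 3.0, 2)
            m1, m2 = rng.uniform(0.1, 10.0, 2)
            norm, w = compute_weights(cv1, cv2, m1, m2)
            assert norm[0] + norm[1] == pytest.approx(1.0, abs=1e-12)
            assert norm[0] / norm[1] == pytest.approx(cv1 / cv2, rel=1e-12)
            assert w[0] > 0 and w[1] > 0

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_weights(1.0, 1.0, 0.0, 1.0)


class TestSelectPair:
    def test_designed_minimum_pair(self, rng):
        # ED and SAC independent noise; SCC copies ED, SID copies SAC, so
        # every mixed pair shares the same |rho| and the lexicographic rule
        # resolves the tie in favour of (ED, SAC).
        a = rng.uniform(0.1, 1.0, 400)
        b = rng.uniform(0.1, 1.0, 400)
        maps = {
            "ED": _map_from(a, "ED"),
            "SAC": _map_from(b, "SAC"),
            "SCC": _map_from(a, "SCC"),
            "SID": _map_from(b, "SID"),
        }
        pair, rho, excluded = select_pair(maps)
        assert pair == ("ED", "SAC")
        assert excluded == []
        # exhaustive oracle over the six pairs
        vecs = {"ED": a, "SAC": b, "SCC": a, "SID": b}
        best = min(
            itertools.combinations(MEASURES, 2),
            key=lambda p: abs(np.corrcoef(vecs[p[0]], vecs[p[1]])[0, 1]),
        )
        assert abs(rho[MEASURES.index(pair[0]), MEASURES.index(pair[1])]) <= abs(
            np.corrcoef(vecs[best[0]], vecs[best[1]])[0, 1]
        ) + 1e-12

    def test_all_identical_maps_tie_breaks_lexicographically(self, rng):
        a = rng.uniform(0.1, 1.0, 50)
        maps = {m: _map_from(a, m) for m in MEASURES}
        pair, rho, _ = select_pair(maps)
        assert pair == ("ED", "SAC")
        off_diag = rho[~np.eye(4, dtype=bool)]
        assert np.allclose(off_diag, 1.0)

    def test_returned_pair_minimises_abs_rho(self, small_cube):
        maps = {m: feature_map(small_cube, m) for m in MEASURES}
        pair, rho, _ = select_pair(maps)
        i, j = MEASURES.index(pair[0]), MEASURES.index(pair[1])
        for a, b in itertools.combinations(range(4), 2):
            assert abs(rho[i, j]) <= abs(rho[a, b]) + 1e-15

    def test_constant_map_excluded_with_warning(self, rng):
        maps = {m: _map_from(rng.uniform(0.1, 1.0, 60), m) for m in MEASURES}
        maps["SID"] = _map_from(np.full(60, 0.4), "SID")
        with pytest.warns(RuntimeWarning, match="constant"):
            pair, _, excluded = select_pair(maps)
        assert "SID" not in pair
        assert excluded == ["SID"]

    def test_too_few_candidates_is_an_error(self, rng):
        maps = {m: _map_from(np.full(30, 0.4), m) for m in MEASURES}
        maps["ED"] = _map_from(rng.uniform(0.1, 1.0, 30), "ED")
        with pytest.warns(RuntimeWarning):
            with pytest.raises(SelectionError):
                select_pair(maps)


class TestRunSelection:
    def test_rho_matches_brute_force(self, small_cube):
        result = run_selection(small_cube)
        maps = {m: feature_map(small_cube, m) for m in MEASURES}
        for a, b in itertools.combinations(range(4), 2):
            va = maps[MEASURES[a]].valid_values()
            vb = maps[MEASURES[b]].valid_values()
            num = np.sum((va - va.mean()) * (vb - vb.mean()))
            den = np.sqrt(np.sum((va - va.mean()) ** 2)
                          * np.sum((vb - vb.mean()) ** 2))
            assert result.rho[a, b] == pytest.approx(num / den, abs=1e-10)

    def test_deterministic(self, small_cube):
        r1 = run_selection(small_cube)
        r2 = run_selection(small_cube)
        assert r1.pair == r2.pair
        assert np.array_equal(r1.rho, r2.rho)
        assert r1.weights == r2.weights

    def test_weights_positive_and_finite(self, noisy_scene):
        cube, _ = noisy_scene
        result = run_selection(cube)
        assert all(w > 0 and np.isfinite(w) for w in result.weights)
        assert sum(result.norm_weights) == pytest.approx(1.0, abs=1e-12)

    def test_shape_noise_scene_selects_a_shape_measure(self):
        from hcwssc import SceneSpec, make_scene

        # uniform brightness, shape-only jitter: the brightness measure map
        # is nearly flat, so at least one shape measure must enter the pair
        cube, _ = make_scene(SceneSpec(
            rows=24, cols=24, brightness_noise_sd=0.0,
            additive_noise_sd=0.02, seed=5,
        ))
        result = run_selection(cube)
        assert set(result.pair) & {"SAC", "SCC", "SID"}

    def test_serialisation_lists_all_six_pair_correlations(self, small_cube):
        d = run_selection(small_cube).to_dict()
        assert len(d["pair_correlations"]) == 6
        assert set(d["weights"]) == set(d["pair"])


class TestMeasurePairSelectorEstimator:
    def test_sklearn_api(self, noisy_scene):
        cube, _ = noisy_scene
        X = cube.valid_pixels()[:500]
        sel = MeasurePairSelector()
        assert clone(sel).get_params() == sel.get_params()
        sel.fit(X)
        assert sel.feature_values_.shape == (500, 4)
        assert sel.rho_.shape == (4, 4)
        cols = sel.transform(X[:10])
        assert cols.shape == (10, 2)
        weighted = MeasurePairSelector(weighted_transform=True).fit(X)
        ratio = weighted.transform(X[:10]) / weighted.weights_
        assert np.allclose(ratio, cols, atol=1e-12)

    def test_matches_run_selection(self, small_cube):
        res_fn = run_selection(small_cube)
        sel = MeasurePairSelector().fit(small_cube.valid_pixels())
        assert sel.pair_ == res_fn.pair
        assert np.allclose(sel.rho_, res_fn.rho, equal_nan=True)
        assert sel.weights_ == pytest.approx(res_fn.weights, rel=1e-12)


def test_norm_weight_monotone_in_noise(rng):
    """More dispersion in one map (mean fixed) never lowers its weight share."""
    base = rng.uniform(0.4, 0.6, 500)
    other = rng.uniform(0.1, 1.0, 500)
    cv_other = coefficient_of_variation(other)
    prev_share = -1.0
    for spread in (0.0, 0.1, 0.2, 0.4):
        noisy = 0.5 + (base - base.mean()) * (1 + spread / 0.1)
        noisy = np.clip(noisy, 1e-6, None)
        cv = coefficient_of_variation(noisy)
        share, _ = compute_weights(cv, cv_other, noisy.mean(), other.mean())
        assert share[0] >= prev_share - 1e-12
        prev_share = share[0]
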