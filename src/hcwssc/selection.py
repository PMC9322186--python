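"""Filter feature selection over spectral dissimilarity feature maps.

The filter works in three steps:

1. extract one feature map per measure (dissimilarity of every pixel to the
   scene mean spectrum);
2. correlate the maps pairwise (Pearson) and keep the pair with the minimum
   absolute correlation — the two measures carrying the least duplicated
   information;
3. weight the two retained measures by their coefficients of variation (CV),
   normalised to sum to one and then divided by each map's mean so the two
   kernels become unitless and comparable inside K-means.

Both weight sets are kept: ``norm_weights`` (sum to one, the reported form)
and ``weights`` (after division by the map means, the form the clustering
kernel consumes).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DegenerateInputError, SelectionError
from .measures import (
    MEASURES,
    FeatureMap,
    HyperCube,
    Spectrum,
    feature_map,
    pairwise_dissimilarity,
)

__all__ = [
    "pearson",
    "coefficient_of_variation",
    "compute_weights",
    "select_pair",
    "run_selection",
    "SelectionResult",
    "MeasurePairSelector",
]


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation between two equal-length value sequences."""
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.size != bv.size:
        raise DegenerateInputError("sequences must have equal length")
    if av.size < 2:
        raise DegenerateInputError("need at least two values")
    ac, bc = av - av.mean(), bv - bv.mean()
    sa, sb = np.linalg.norm(ac), np.linalg.norm(bc)
    if sa == 0.0 or sb == 0.0:
        raise DegenerateInputError("Pearson correlation undefined for constant input")
    return float(np.clip(np.dot(ac, bc) / (sa * sb), -1.0, 1.0))


def coefficient_of_variation(values, ddof: int = 0) -> float:
    """Coefficient of variation: standard deviation over mean.

    ``values`` may be a :class:`~hcwssc.measures.FeatureMap` or an array.
    The default is the population standard deviation (``ddof=0``): a scene's
    pixel set is treated as a complete population, not a sample.
    """
    if isinstance(values, FeatureMap):
        values = values.valid_values()
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    mean = v.mean() if v.size else 0.0
    if v.size == 0 or mean <= 0:
        raise DegenerateInputError("CV requires a positive mean feature value")
    return float(v.std(ddof=ddof) / mean)


def compute_weights(
    cv1: float, cv2: float, mean1: float, mean2: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Turn two CVs into kernel weights.

    Returns ``(norm_weights, weights)`` where ``norm_weights`` are the CV
    shares ``cv_k / (cv1 + cv2)`` (they sum to one and their ratio equals the
    CV ratio) and ``weights`` divide each share by the corresponding feature
    map mean so both kernels become unitless.
    """
    if cv1 < 0 or cv2 < 0 or cv1 + cv2 <= 0:
        raise DegenerateInputError("CVs must be non-negative with a positive sum")
    if mean1 <= 0 or mean2 <= 0:
        raise DegenerateInputError("feature-map means must be positive")
    n1 = cv1 / (cv1 + cv2)
    n2 = cv2 / (cv1 + cv2)
    return (n1, n2), (n1 / mean1, n2 / mean2)


def _pair_index(measures: Sequence[str]) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(len(measures)), 2))


def select_pair(
    maps: Mapping[str, FeatureMap] | Sequence[FeatureMap],
) -> tuple[tuple[str, str], np.ndarray, list[str]]:
    """Pick the least-correlated pair of feature maps.

    Parameters
    ----------
    maps : mapping measure -> FeatureMap, or sequence of the four FeatureMaps

    Returns
    -------
    pair : (measure, measure)
        The unordered pair minimising the absolute Pearson correlation,
        ties broken by the canonical order ED < SAC < SCC < SID.
    rho : ndarray (4, 4)
        Full symmetric correlation matrix in canonical measure order; NaN on
        rows/columns of excluded (constant) maps.
    excluded : list of str
        Measures excluded from candidacy because their map is constant.
    """
    if not isinstance(maps, Mapping):
        maps = {fm.measure: fm for fm in maps}
    missing = [m for m in MEASURES if m not in maps]
    if missing:
        raise SelectionError(f"feature maps missing for {missing}")
    vectors = {m: maps[m].valid_values() for m in MEASURES}
    sizes = {v.size for v in vectors.values()}
    if len(sizes) != 1:
        raise SelectionError("feature maps cover different pixel sets")

    excluded = [m for m in MEASURES if np.ptp(vectors[m]) == 0.0]
    for m in excluded:
        warnings.warn(
            f"feature map {m} is constant; excluded from pair selection",
            RuntimeWarning,
            stacklevel=2,
        )
    candidates = [m for m in MEASURES if m not in excluded]
    if len(candidates) < 2:
        raise SelectionError("fewer than two non-constant feature maps")

    rho = np.full((len(MEASURES), len(MEASURES)), np.nan)
    np.fill_diagonal(rho, 1.0)
    best: Optional[tuple[str, str]] = None
    best_abs = np.inf
    for i, j in _pair_index(MEASURES):
        mi, mj = MEASURES[i], MEASURES[j]
        if mi in excluded or mj in excluded:
            continue
        r = pearson(vectors[mi], vectors[mj])
        rho[i, j] = rho[j, i] = r
        if abs(r) < best_abs:  # strict: earlier (lexicographic) pair wins ties
            best_abs = abs(r)
            best = (mi, mj)
    assert best is not None
    return best, rho, excluded


@dataclass
class SelectionResult:
    """Outcome of the filter feature selection on one scene or library."""

    pair: tuple[str, str]
    rho: np.ndarray
    cv: tuple[float, float]
    norm_weights: tuple[float, float]
    weights: tuple[float, float]
    map_means: tuple[float, float]
    excluded: list[str] = field(default_factory=list)
    measures: tuple[str, ...] = MEASURES

    def to_dict(self) -> dict:
        pairs = {}
        for i, j in _pair_index(self.measures):
            r = self.rho[i, j]
            pairs[f"{self.measures[i]}-{self.measures[j]}"] = (
                None if not np.isfinite(r) else float(r)
            )
        return {
            "pair": list(self.pair),
            "pair_correlations": pairs,
            "rho": [[None if not np.isfinite(v) else float(v) for v in row]
                    for row in self.rho],
            "cv": {self.pair[0]: self.cv[0], self.pair[1]: self.cv[1]},
            "norm_weights": {self.pair[0]: self.norm_weights[0],
                             self.pair[1]: self.norm_weights[1]},
            "weights": {self.pair[0]: self.weights[0],
                        self.pair[1]: self.weights[1]},
            "map_means": {self.pair[0]: self.map_means[0],
                          self.pair[1]: self.map_means[1]},
            "excluded": list(self.excluded),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


class MeasurePairSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn style filter selector over the four spectral measures.

    ``fit`` takes a pixel matrix ``X`` of shape (n_pixels, n_bands), extracts
    the four dissimilarity features against the mean spectrum of ``X``, and
    selects the least-correlated pair with CV-based weights.  ``transform``
    maps any pixel matrix onto the two selected features (computed against
    the *fitted* mean spectrum), optionally pre-multiplied by the weights.

    Parameters
    ----------
    ddof : int, default 0
        Degrees of freedom for the standard deviation inside the CV.
    sid_base : float or None, default None
        Log base for the SID measure (natural log when None).
    weighted_transform : bool, default False
        If True, ``transform`` scales each selected feature by its weight.

    Attributes
    ----------
    mean_spectrum_ : ndarray (n_bands,)
    feature_values_ : ndarray (n_pixels, 4) — training feature maps.
    rho_ : ndarray (4, 4)
    pair_ : tuple of two measure names
    cv_, norm_weights_, weights_, map_means_ : tuples aligned with ``pair_``
    excluded_ : list of constant measures excluded from candidacy
    """

    def __init__(self, ddof: int = 0, sid_base: Optional[float] = None,
                 weighted_transform: bool = False):
        self.ddof = ddof
        self.sid_base = sid_base
        self.weighted_transform = weighted_transform

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_features=2)
        self.mean_spectrum_ = X.mean(axis=0)
        self.feature_values_ = np.column_stack(
            [self._features(X, m) for m in MEASURES]
        )
        maps = {
            m: FeatureMap(
                measure=m,
                values=self.feature_values_[:, k].reshape(-1, 1),
                reference=Spectrum(self.mean_spectrum_),
                mask=np.ones((X.shape[0], 1), dtype=bool),
            )
            for k, m in enumerate(MEASURES)
        }
        self.pair_, self.rho_, self.excluded_ = select_pair(maps)
        idx = [MEASURES.index(m) for m in self.pair_]
        vals = [self.feature_values_[:, i] for i in idx]
        self.cv_ = tuple(coefficient_of_variation(v, ddof=self.ddof) for v in vals)
        self.map_means_ = tuple(float(v.mean()) for v in vals)
        self.norm_weights_, self.weights_ = compute_weights(
            self.cv_[0], self.cv_[1], self.map_means_[0], self.map_means_[1]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _features(self, X: np.ndarray, measure: str) -> np.ndarray:
        return pairwise_dissimilarity(
            X, self.mean_spectrum_[None, :], measure,
            sid_base=self.sid_base, on_degenerate="max",
        )[:, 0]

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pair_")
        X = check_array(X, dtype=float)
        cols = np.column_stack([self._features(X, m) for m in self.pair_])
        if self.weighted_transform:
            cols = cols * np.asarray(self.weights_)
        return cols

    def result(self) -> SelectionResult:
        """Package the fitted state as a serialisable :class:`SelectionResult`."""
        check_is_fitted(self, "pair_")
        return SelectionResult(
            pair=self.pair_,
            rho=self.rho_.copy(),
            cv=self.cv_,
            norm_weights=self.norm_weights_,
            weights=self.weights_,
            map_means=self.map_means_,
            excluded=list(self.excluded_),
        )


def run_selection(
    cube: HyperCube, ddof: int = 0, sid_base: Optional[float] = None
) -> SelectionResult:
    """End-to-end filter selection on a cube.

    Composes the four feature maps, the minimum-|rho| pair search and the
    CV-based weighting; deterministic for a given cube.
    """
    maps = {m: feature_map(cube, m, sid_base=sid_base) for m in MEASURES}
    pair, rho, excluded = select_pair(maps)
    vals = [maps[m].valid_values() for m in pair]
    cv = tuple(coefficient_of_variation(v, ddof=ddof) for v in vals)
    means = tuple(float(v.mean()) for v in vals)
    norm_w, w = compute_weights(cv[0], cv[1], means[0], means[1])
    return SelectionResult(
        pair=pair, rho=rho, cv=cv, norm_weights=norm_w, weights=w,
        map_means=means, excluded=excluded,
    )
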