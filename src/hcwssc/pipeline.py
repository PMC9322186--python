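"""End-to-end hybrid changing-weight classifier.

Chains the filter feature selection (pick the two least-correlated measures,
weight them by CV over map mean) with the hybrid-kernel K-means, as one
scikit-learn estimator.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .cluster import HybridKernelKMeans
from .measures import HyperCube
from .selection import MeasurePairSelector, SelectionResult

__all__ = ["HCWSSCClassifier", "run_hcwssc"]


class HCWSSCClassifier(ClusterMixin, BaseEstimator):
    """Hybrid changing-weight spectral classifier (selection + clustering).

    ``fit`` runs the filter feature selection on the pixel matrix, then
    clusters with the selected two-measure kernel and CV-derived weights.

    Parameters
    ----------
    n_clusters : int, default 5
    max_iter : int, default 10
    change_threshold : float, default 0.02
        Stop when fewer than this fraction of pixels change label.
    n_init : int, default 4
        Best-of restarts of the K-means stage (lowest inertia wins).
    init : {"d2", "random"}, default "d2"
        Centroid seeding.  Kernel-D² seeding is the default here because a
        single uniform draw of K pixels frequently seeds two centroids in
        one class and none in another; the core K-means keeps "random" as
        its own default for protocol-faithful single runs.
    ddof : int, default 0
        Standard-deviation convention inside the CV (population).
    random_state : int, RandomState or None
    sid_base : float or None

    Attributes
    ----------
    selector_ : fitted :class:`MeasurePairSelector`
    selection_ : :class:`SelectionResult`
    kmeans_ : fitted :class:`HybridKernelKMeans`
    labels_, cluster_centers_, inertia_, n_iter_ : forwarded from ``kmeans_``
    """

    def __init__(
        self,
        n_clusters: int = 5,
        max_iter: int = 10,
        change_threshold: float = 0.02,
        n_init: int = 4,
        init: str = "d2",
        ddof: int = 0,
        random_state=None,
        sid_base: Optional[float] = None,
    ):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.change_threshold = change_threshold
        self.n_init = n_init
        self.init = init
        self.ddof = ddof
        self.random_state = random_state
        self.sid_base = sid_base

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2, ensure_min_features=2)
        self.selector_ = MeasurePairSelector(
            ddof=self.ddof, sid_base=self.sid_base
        ).fit(X)
        self.selection_: SelectionResult = self.selector_.result()
        self.kmeans_ = HybridKernelKMeans(
            n_clusters=self.n_clusters,
            measures=self.selector_.pair_,
            weights=self.selector_.weights_,
            max_iter=self.max_iter,
            change_threshold=self.change_threshold,
            n_init=self.n_init,
            init=self.init,
            random_state=self.random_state,
            sid_base=self.sid_base,
        ).fit(X)
        self.labels_ = self.kmeans_.labels_
        self.cluster_centers_ = self.kmeans_.cluster_centers_
        self.inertia_ = self.kmeans_.inertia_
        self.n_iter_ = self.kmeans_.n_iter_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "kmeans_")
        return self.kmeans_.predict(X)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def run_hcwssc(
    cube: HyperCube,
    n_clusters: int = 5,
    **kwargs,
) -> tuple[np.ndarray, SelectionResult, HCWSSCClassifier]:
    """Run the full pipeline on a cube.

    Returns the rows x cols label map (-1 on masked pixels), the selection
    result and the fitted classifier.
    """
    model = HCWSSCClassifier(n_clusters=n_clusters, **kwargs)
    model.fit(cube.valid_pixels())
    labels = np.full(cube.data.shape[:2], -1, dtype=int)
    labels[cube.mask] = model.labels_
    return labels, model.selection_, model
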