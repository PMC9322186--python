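"""Spectral dissimilarity measures and per-pixel feature extraction.

Four measures are supported, each returning 0 for identical spectra and
growing as the spectra diverge:

``ED``
    Euclidean distance between the band vectors — sensitive to brightness.
``SAC``
    Spectral angle cosine dissimilarity, ``1 - cos(theta)`` — sensitive to
    the shape of the spectral curve, invariant to positive rescaling.
``SCC``
    Spectral correlation dissimilarity, ``1 - r`` with Pearson ``r`` across
    bands — invariant to positive affine transforms of either spectrum.
``SID``
    Spectral information divergence — the symmetric Kullback–Leibler
    divergence between the band-normalised probability vectors.

A *feature map* is the image of per-pixel dissimilarities between each pixel
spectrum and the scene mean spectrum, one map per measure; these maps are the
inputs to the filter feature selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, DimensionMismatchError

__all__ = [
    "MEASURES",
    "Spectrum",
    "HyperCube",
    "FeatureMap",
    "ed",
    "sac",
    "scc",
    "sid",
    "dissimilarity",
    "pairwise_dissimilarity",
    "feature_map",
]

#: Canonical measure order; also the tie-break order used in pair selection.
MEASURES: tuple[str, ...] = ("ED", "SAC", "SCC", "SID")

#: Probability floor added to band-normalised spectra before taking logs in SID.
SID_EPS = 1e-12


@dataclass
class Spectrum:
    """A single reflectance spectrum.

    Parameters
    ----------
    values : array-like
        Reflectance per band, unitless and non-negative.
    wavelengths : array-like, optional
        Band centres in nanometres, strictly increasing.  When omitted an
        index axis is used.
    label : str, optional
        Class name, e.g. the library species.
    """

    values: np.ndarray
    wavelengths: Optional[np.ndarray] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise DimensionMismatchError(
                f"a spectrum needs >= 2 bands in one dimension, got shape {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise DegenerateInputError("spectrum contains missing values")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != self.values.shape:
                raise DimensionMismatchError(
                    "wavelengths and values must have equal length"
                )
            if np.any(np.diff(self.wavelengths) <= 0):
                raise DegenerateInputError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.values.size


@dataclass
class HyperCube:
    """A rows x cols x bands reflectance image with an optional validity mask.

    ``mask`` is True for valid pixels; invalid pixels are excluded from the
    mean spectrum, feature maps and clustering.  ``geo`` carries an opaque
    georeference (ENVI ``map info`` string or TIFF tag dict) untouched.
    """

    data: np.ndarray
    wavelengths: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    geo: Optional[object] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionMismatchError(
                f"cube must be rows x cols x bands, got shape {self.data.shape}"
            )
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.size != self.data.shape[2]:
                raise DimensionMismatchError(
                    "bands dimension must match wavelengths length"
                )
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise DimensionMismatchError("mask must be rows x cols")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def valid_pixels(self) -> np.ndarray:
        """Return the (n_valid, bands) matrix of unmasked pixel spectra."""
        return self.data[self.mask]

    def mean_spectrum(self) -> Spectrum:
        """Band-wise mean over valid pixels — the scene-level competitor."""
        pixels = self.valid_pixels()
        if pixels.shape[0] == 0:
            raise DegenerateInputError("cube has no valid pixels")
        return Spectrum(pixels.mean(axis=0), wavelengths=self.wavelengths)


@dataclass
class FeatureMap:
    """Per-pixel dissimilarity of each valid pixel to a reference spectrum."""

    measure: str
    values: np.ndarray  # rows x cols, NaN where masked
    reference: Spectrum
    mask: np.ndarray = field(repr=False, default=None)

    def valid_values(self) -> np.ndarray:
        """Flattened dissimilarities over valid pixels, row-major order."""
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask]


def _as_vector(x) -> np.ndarray:
    if isinstance(x, Spectrum):
        return x.values
    return np.asarray(x, dtype=float).ravel()


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv, yv = _as_vector(x), _as_vector(y)
    if xv.size != yv.size:
        raise DimensionMismatchError(
            f"band counts differ: {xv.size} vs {yv.size}"
        )
    return xv, yv


def ed(x, y) -> float:
    """Euclidean distance between two spectra (brightness difference)."""
    xv, yv = _check_pair(x, y)
    return float(np.linalg.norm(xv - yv))


def sac(x, y) -> float:
    """Spectral angle cosine dissimilarity, ``1 - cos(theta)``, in [0, 2]."""
    xv, yv = _check_pair(x, y)
    nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError("SAC is undefined for an all-zero spectrum")
    c = float(np.clip(np.dot(xv, yv) / (nx * ny), -1.0, 1.0))
    return 1.0 - c


def scc(x, y) -> float:
    """Spectral correlation dissimilarity, ``1 - r``, in [0, 2]."""
    xv, yv = _check_pair(x, y)
    xc, yc = xv - xv.mean(), yv - yv.mean()
    sx, sy = np.linalg.norm(xc), np.linalg.norm(yc)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("SCC is undefined for a band-constant spectrum")
    r = float(np.dot(xc, yc) / (sx * sy))
    return 1.0 - max(-1.0, min(1.0, r))


def sid(x, y, base: Optional[float] = None) -> float:
    """Spectral information divergence: symmetric KL on normalised spectra.

    Both spectra are normalised to probability vectors ``p = x / sum(x)`` and
    ``q = y / sum(y)``; the result is ``D(p||q) + D(q||p)`` in nats, or in the
    given log ``base``.  A floor of 1e-12 is added inside the logs so that
    zero bands stay finite.
    """
    xv, yv = _check_pair(x, y)
    if (xv < 0).any() or (yv < 0).any():
        raise DegenerateInputError("SID requires non-negative reflectance")
    sx, sy = xv.sum(), yv.sum()
    if sx <= 0 or sy <= 0:
        raise DegenerateInputError("SID is undefined for a zero-sum spectrum")
    p, q = xv / sx, yv / sy
    lp, lq = np.log(p + SID_EPS), np.log(q + SID_EPS)
    val = float(np.dot(p - q, lp - lq))
    if base is not None:
        val /= math.log(base)
    return max(0.0, val)


_SCALAR_FUNCS = {"ED": ed, "SAC": sac, "SCC": scc, "SID": sid}


def dissimilarity(measure: str, x, y, sid_base: Optional[float] = None) -> float:
    """Evaluate one named measure on a pair of spectra."""
    fn = _SCALAR_FUNCS[_canon(measure)]
    if fn is sid:
        return fn(x, y, base=sid_base)
    return fn(x, y)


def _canon(measure: str) -> str:
    m = str(measure).upper()
    if m not in MEASURES:
        raise KeyError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    return m


def _sid_matrix(X: np.ndarray, Y: np.ndarray, base: Optional[float]) -> np.ndarray:
    """Vectorised symmetric-KL matrix between the rows of X and of Y.

    Rows with a negative entry or non-positive sum are marked NaN and left to
    the degenerate-row handling of the caller.
    """
    bad_x = (X < 0).any(axis=1) | (X.sum(axis=1) <= 0)
    bad_y = (Y < 0).any(axis=1) | (Y.sum(axis=1) <= 0)
    Xs = np.where(bad_x[:, None], 1.0, X)
    Ys = np.where(bad_y[:, None], 1.0, Y)
    P = Xs / Xs.sum(axis=1, keepdims=True)
    Q = Ys / Ys.sum(axis=1, keepdims=True)
    lp, lq = np.log(P + SID_EPS), np.log(Q + SID_EPS)
    sp = np.einsum("ib,ib->i", P, lp)
    sq = np.einsum("jb,jb->j", Q, lq)
    D = sp[:, None] + sq[None, :] - P @ lq.T - lp @ Q.T
    D[bad_x, :] = np.nan
    D[:, bad_y] = np.nan
    if base is not None:
        D = D / math.log(base)
    return np.maximum(D, 0.0)  # NaN propagates; rounding negatives clipped


def pairwise_dissimilarity(
    X: np.ndarray,
    Y: np.ndarray,
    measure: str,
    sid_base: Optional[float] = None,
    on_degenerate: str = "max",
) -> np.ndarray:
    """Dissimilarity matrix between the rows of ``X`` and the rows of ``Y``.

    Parameters
    ----------
    X, Y : ndarray of shape (n, bands) and (m, bands)
    measure : {"ED", "SAC", "SCC", "SID"}
    sid_base : float, optional
        Log base for SID; natural log when None.
    on_degenerate : {"max", "raise", "nan"}
        What to do with entries whose inputs are outside the measure's domain
        (all-zero rows for SAC/SID, band-constant rows for SCC).  ``"max"``
        substitutes the largest finite entry of the matrix so degenerate
        pixels never win an argmin by NaN ordering.

    Returns
    -------
    ndarray of shape (n, m), non-negative.
    """
    m = _canon(measure)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise DimensionMismatchError(
            f"band counts differ: {X.shape[1]} vs {Y.shape[1]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if m == "ED":
            D = cdist(X, Y, metric="euclidean")
        elif m == "SAC":
            D = cdist(X, Y, metric="cosine")
        elif m == "SCC":
            D = cdist(X, Y, metric="correlation")
        else:
            D = _sid_matrix(X, Y, base=sid_base)
    # cdist cosine/correlation can return tiny negatives from rounding;
    # np.clip propagates NaN so degenerate entries survive to the next step
    D = np.clip(D, 0.0, None)
    bad = ~np.isfinite(D)
    if bad.any():
        if on_degenerate == "raise":
            raise DegenerateInputError(
                f"{m} undefined for {int(bad.sum())} row pair(s)"
            )
        if on_degenerate == "max":
            finite = D[np.isfinite(D)]
            fill = float(finite.max()) if finite.size else 0.0
            warnings.warn(
                f"{m}: {int(bad.sum())} degenerate pair(s) set to the maximum "
                f"observed dissimilarity {fill:.6g}",
                RuntimeWarning,
                stacklevel=2,
            )
            D[bad] = fill
    return D


def feature_map(
    cube: HyperCube,
    measure: str,
    reference: Optional[Spectrum] = None,
    sid_base: Optional[float] = None,
) -> FeatureMap:
    """Extract one per-pixel feature map from a cube.

    Each valid pixel's spectrum is compared against ``reference`` (the scene
    mean spectrum when not given) with the named measure.  Degenerate pixels
    are assigned the map's maximum observed value with a warning, so they can
    never dominate an argmin through NaN ordering.
    """
    ref = reference if reference is not None else cube.mean_spectrum()
    pixels = cube.valid_pixels()
    if pixels.shape[0] == 0:
        raise DegenerateInputError("cube has no valid pixels")
    col = pairwise_dissimilarity(
        pixels, ref.values[None, :], measure, sid_base=sid_base, on_degenerate="max"
    )[:, 0]
    values = np.full(cube.data.shape[:2], np.nan)
    values[cube.mask] = col
    return FeatureMap(measure=_canon(measure), values=values, reference=ref,
                      mask=cube.mask.copy())
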