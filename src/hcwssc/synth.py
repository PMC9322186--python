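"""Synthetic spectra, scenes and triplet libraries.

The generators emulate the two data shapes the classifier consumes:

* multi-class scenes — each pixel is its class endmember scaled by a
  multiplicative lognormal brightness factor (sun angle, topography) plus
  additive Gaussian noise (sensor), clipped at zero.  Brightness noise
  perturbs the Euclidean distance between a pixel and its endmember but not
  the spectral angle, so magnitude- and shape-sensitive measures respond
  differently by construction;
* triplet libraries — groups of three labelled spectra, two drawn from one
  class and one from another, the protocol used to score kernels on
  reference spectral libraries.

Endmembers are smooth, strictly positive curves built from a few Gaussian
reflectance bumps over a configurable wavelength axis (default 400–1000 nm),
rejection-sampled until every pair is separated by a minimum spectral angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, GenerationError
from .measures import HyperCube, Spectrum, sac

__all__ = [
    "SceneSpec",
    "TripletSpec",
    "make_endmembers",
    "make_scene",
    "make_triplets",
]


@dataclass
class SceneSpec:
    """Parameters of a synthetic multi-class scene.

    Defaults describe a desk-scale five-class crop scene: 64 x 64 pixels,
    30 bands over 400–1000 nm, block layout, moderate brightness noise
    (lognormal sigma 0.15) and small additive noise (0.01 reflectance).
    """

    rows: int = 64
    cols: int = 64
    n_bands: int = 30
    n_classes: int = 5
    layout: str = "blocks"
    brightness_noise_sd: float = 0.15
    additive_noise_sd: float = 0.01
    class_separation: float = 0.35
    seed: int = 0
    wavelength_range: tuple[float, float] = (400.0, 1000.0)

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.n_bands) < 1 or self.n_classes < 1:
            raise ConfigurationError("scene dimensions must be positive")
        if self.n_classes > self.rows * self.cols:
            raise ConfigurationError("more classes than pixels")
        if self.layout not in ("blocks", "voronoi"):
            raise ConfigurationError("layout must be 'blocks' or 'voronoi'")
        if self.brightness_noise_sd < 0 or self.additive_noise_sd < 0:
            raise ConfigurationError("noise levels must be >= 0")


@dataclass
class TripletSpec:
    """Parameters of a synthetic triplet-library suite.

    The default of 80 groups matches the size of a standard library test
    suite; ``scaled`` mode perturbs within-class copies by a uniform
    brightness factor in [0.7, 1.3], ``jittered`` mode by small additive
    Gaussian noise.
    """

    n_groups: int = 80
    within_class_mode: str = "scaled"
    scale_range: tuple[float, float] = (0.7, 1.3)
    jitter_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("need at least one triplet group")
        if self.within_class_mode not in ("scaled", "jittered"):
            raise ConfigurationError(
                "within_class_mode must be 'scaled' or 'jittered'"
            )


def make_endmembers(
    n_classes: int,
    n_bands: int,
    class_separation: float = 0.35,
    seed: Optional[int] = None,
    wavelength_range: tuple[float, float] = (400.0, 1000.0),
    max_tries: int = 5000,
    equal_brightness: bool = False,
    max_separation: Optional[float] = None,
) -> list[Spectrum]:
    """Generate smooth positive endmember spectra with a minimum pairwise angle.

    Each endmember is a small baseline plus 2–4 Gaussian bumps with random
    centre, width and amplitude.  Candidates are rejection-sampled until the
    spectral angle to every accepted endmember is at least
    ``class_separation`` radians.

    With ``equal_brightness=True`` every endmember is rescaled to the same
    mean reflectance (0.25): classes then differ in curve shape but not in
    albedo, the regime in which brightness-sensitive measures carry no class
    information.  ``max_separation`` additionally caps the pairwise angle,
    pinning how distinguishable the classes are.
    """
    if n_classes < 2:
        raise ConfigurationError("need at least two classes")
    rng = np.random.RandomState(seed)
    wl = np.linspace(*wavelength_range, n_bands)
    span = wavelength_range[1] - wavelength_range[0]
    accepted: list[np.ndarray] = []
    min_dissim = 1.0 - np.cos(class_separation)
    max_dissim = (np.inf if max_separation is None
                  else 1.0 - np.cos(max_separation))
    if max_dissim < min_dissim:
        raise ConfigurationError("max_separation must be >= class_separation")
    tries = 0
    while len(accepted) < n_classes:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {n_classes} endmembers at separation "
                f"{class_separation} rad within {max_tries} tries"
            )
        tries += 1
        cand = np.full(n_bands, rng.uniform(0.02, 0.10))
        for _ in range(rng.randint(2, 5)):
            centre = rng.uniform(*wavelength_range)
            width = rng.uniform(0.05, 0.25) * span
            amp = rng.uniform(0.1, 0.6)
            cand = cand + amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        if equal_brightness:
            cand = cand * (0.25 / cand.mean())
        if all(min_dissim <= sac(cand, em) <= max_dissim for em in accepted):
            accepted.append(cand)
    return [
        Spectrum(values=em, wavelengths=wl, label=f"class_{i}")
        for i, em in enumerate(accepted)
    ]


def _layout_blocks(rows: int, cols: int, n_classes: int) -> np.ndarray:
    """Vertical class stripes with deterministic, near-equal proportions."""
    col_class = (np.arange(cols) * n_classes) // cols
    return np.tile(col_class, (rows, 1))


def _layout_voronoi(rows: int, cols: int, n_classes: int,
                    rng: np.random.RandomState) -> np.ndarray:
    sites = np.column_stack([
        rng.uniform(0, rows, n_classes), rng.uniform(0, cols, n_classes)
    ])
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = ((rr[..., None] - sites[:, 0]) ** 2
          + (cc[..., None] - sites[:, 1]) ** 2)
    return d2.argmin(axis=2)


def make_scene(
    spec: SceneSpec,
    endmembers: Optional[Sequence[Spectrum]] = None,
) -> tuple[HyperCube, np.ndarray]:
    """Render a scene from a spec: returns (cube, truth raster).

    Every pixel is ``endmember[class] * LogNormal(0, brightness_sd) +
    Normal(0, additive_sd)`` per band, clipped at zero.  The truth raster
    holds the class index per pixel.
    """
    rng = np.random.RandomState(spec.seed)
    if endmembers is None:
        endmembers = make_endmembers(
            spec.n_classes, spec.n_bands, spec.class_separation,
            seed=rng.randint(2**31), wavelength_range=spec.wavelength_range,
        )
    if len(endmembers) != spec.n_classes:
        raise ConfigurationError("endmember count must equal n_classes")
    em = np.vstack([e.values for e in endmembers])
    if spec.layout == "blocks":
        truth = _layout_blocks(spec.rows, spec.cols, spec.n_classes)
    else:
        truth = _layout_voronoi(spec.rows, spec.cols, spec.n_classes, rng)
    data = em[truth]  # rows x cols x bands
    if spec.brightness_noise_sd > 0:
        factor = rng.lognormal(0.0, spec.brightness_noise_sd,
                               size=(spec.rows, spec.cols))
        data = data * factor[..., None]
    if spec.additive_noise_sd > 0:
        data = data + rng.normal(0.0, spec.additive_noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)
    wl = endmembers[0].wavelengths
    return HyperCube(data=data, wavelengths=wl), truth


def make_triplets(
    spec: TripletSpec,
    endmembers: Sequence[Spectrum],
) -> list[tuple[list[Spectrum], list[str]]]:
    """Build a suite of three-spectrum groups from labelled endmembers.

    Each group draws two distinct classes, perturbs two copies of the first
    and one copy of the second, and returns (spectra, labels) pairs.
    """
    if len(endmembers) < 2:
        raise ConfigurationError("need endmembers from at least two classes")
    rng = np.random.RandomState(spec.seed)
    groups: list[tuple[list[Spectrum], list[str]]] = []
    for _ in range(spec.n_groups):
        a, b = rng.choice(len(endmembers), size=2, replace=False)
        spectra, labels = [], []
        for cls, n in ((a, 2), (b, 1)):
            base = endmembers[cls]
            for _ in range(n):
                if spec.within_class_mode == "scaled":
                    vals = base.values * rng.uniform(*spec.scale_range)
                else:
                    vals = np.clip(
                        base.values + rng.normal(0.0, spec.jitter_sd,
                                                 base.values.shape),
                        0.0, None,
                    )
                spectra.append(Spectrum(vals, wavelengths=base.wavelengths,
                                        label=base.label))
                labels.append(base.label)
        groups.append((spectra, labels))
    return groups
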