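"""Raster and spectral-library input/output.

Rasters are read and written in two plain formats:

* ENVI — raw binary image alongside a text ``.hdr`` header (BSQ, BIL or BIP
  interleave, band wavelengths and an optional ``data ignore value`` and
  ``map info`` carried through);
* TIFF — multi-band via :mod:`tifffile`, with wavelengths and nodata stored
  as a JSON image description.

Spectral libraries are delimited text: a wavelength column plus one
reflectance column per spectrum, the header row carrying the class labels.
Triplet suites use the same layout with ``group:label`` column headers.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .errors import FormatError
from .measures import HyperCube, Spectrum

__all__ = [
    "read_cube",
    "write_cube",
    "read_label_raster",
    "write_label_raster",
    "read_library",
    "write_library",
    "read_triplets",
    "write_triplets",
    "resample_spectra",
]

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


# -- ENVI --------------------------------------------------------------------


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _brace_list(value: str) -> list[str]:
    return [v.strip() for v in value.strip().strip("{}").split(",") if v.strip()]


def _find_header(path: Path) -> Path:
    for cand in (path.with_suffix(path.suffix + ".hdr"), path.with_suffix(".hdr")):
        if cand.exists():
            return cand
    raise FormatError(f"no ENVI header found next to {path}")


def _read_envi(path: Path) -> HyperCube:
    hdr = _parse_envi_header(_find_header(path).read_text())
    try:
        samples = int(hdr["samples"])
        lines = int(hdr["lines"])
        bands = int(hdr["bands"])
        code = int(hdr["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field {exc} in {path}") from exc
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {code} in {path}")
    interleave = hdr.get("interleave", "bsq").lower()
    offset = int(hdr.get("header offset", 0))
    raw = np.fromfile(path, dtype=_ENVI_DTYPES[code], offset=offset)
    if raw.size != samples * lines * bands:
        raise FormatError(
            f"{path}: expected {samples * lines * bands} values "
            f"({lines}x{samples}x{bands}), found {raw.size}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unknown interleave {interleave!r} in {path}")
    data = np.ascontiguousarray(data, dtype=float)

    wavelengths = None
    if "wavelength" in hdr:
        wl = [float(v) for v in _brace_list(hdr["wavelength"])]
        if len(wl) == bands:
            wavelengths = np.asarray(wl)
        else:
            warnings.warn(f"{path}: wavelength list length != bands; ignored")
    elif bands > 1:  # single-band class rasters carry no spectral axis
        warnings.warn(
            f"{path}: no wavelengths in header; using band indices", stacklevel=2
        )
    mask = None
    if "data ignore value" in hdr:
        ignore = float(hdr["data ignore value"])
        mask = ~(data == ignore).all(axis=2)
    geo = hdr.get("map info")
    return HyperCube(data=data, wavelengths=wavelengths, mask=mask, geo=geo)


def _write_envi(
    path: Path,
    data: np.ndarray,
    wavelengths: Optional[np.ndarray],
    geo: Optional[object],
    nodata: Optional[float],
    interleave: str = "bsq",
    dtype=np.float32,
) -> None:
    rows, cols, bands = data.shape
    arr = np.asarray(data, dtype=dtype)
    if interleave == "bsq":
        raw = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        raw = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        raw = arr
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    raw.tofile(path)
    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:g}" for w in np.asarray(wavelengths))
        lines.append("wavelength units = Nanometers")
        lines.append(f"wavelength = {{ {wl} }}")
    if nodata is not None:
        lines.append(f"data ignore value = {nodata:g}")
    if geo:
        lines.append(f"map info = {geo}")
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(lines) + "\n")


# -- TIFF --------------------------------------------------------------------


def _read_tiff(path: Path) -> HyperCube:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if arr.ndim == 2:
        arr = arr[None, ...]
    data = np.ascontiguousarray(arr.transpose(1, 2, 0), dtype=float)
    wavelengths = meta.get("wavelengths")
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.size != data.shape[2]:
            wavelengths = None
    elif data.shape[2] > 1:
        warnings.warn(
            f"{path}: no wavelengths recorded; using band indices", stacklevel=2
        )
    mask = None
    nodata = meta.get("nodata")
    if nodata is not None:
        mask = ~(data == float(nodata)).all(axis=2)
    return HyperCube(data=data, wavelengths=wavelengths, mask=mask,
                     geo=meta.get("geo"))


def _write_tiff(
    path: Path,
    data: np.ndarray,
    wavelengths: Optional[np.ndarray],
    geo: Optional[object],
    nodata: Optional[float],
    dtype=np.float32,
) -> None:
    meta = {}
    if wavelengths is not None:
        meta["wavelengths"] = [float(w) for w in np.asarray(wavelengths)]
    if nodata is not None:
        meta["nodata"] = float(nodata)
    if geo is not None:
        meta["geo"] = geo
    tifffile.imwrite(
        path,
        np.asarray(data, dtype=dtype).transpose(2, 0, 1),
        photometric="minisblack",
        description=json.dumps(meta),
    )


# -- public raster API -------------------------------------------------------


def read_cube(path) -> HyperCube:
    """Read a hyperspectral cube from an ENVI (.img/.dat + .hdr) or TIFF file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such raster: {path}")
    try:
        if _is_tiff(path):
            return _read_tiff(path)
        return _read_envi(path)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 — re-wrap with file context
        raise FormatError(f"failed to read {path}: {exc}") from exc


def write_cube(
    path,
    cube: HyperCube,
    nodata: Optional[float] = None,
    interleave: str = "bsq",
) -> None:
    """Write a cube as ENVI (default) or TIFF depending on the extension.

    When the cube has masked pixels a ``nodata`` value is required so the
    mask survives the round trip.
    """
    path = Path(path)
    data = cube.data
    if cube.mask is not None and not cube.mask.all():
        if nodata is None:
            raise FormatError("cube has masked pixels; a nodata value is required")
        data = data.copy()
        data[~cube.mask] = nodata
    if _is_tiff(path):
        _write_tiff(path, data, cube.wavelengths, cube.geo, nodata)
    else:
        _write_envi(path, data, cube.wavelengths, cube.geo, nodata,
                    interleave=interleave)


def read_label_raster(path) -> np.ndarray:
    """Read a single-band integer class/cluster raster (-1 = unlabelled)."""
    cube = read_cube(path)
    if cube.n_bands != 1:
        raise FormatError(f"{path}: label raster must be single-band")
    return np.asarray(np.rint(cube.data[:, :, 0]), dtype=int)


def write_label_raster(path, labels: np.ndarray, geo=None) -> None:
    """Write a rows x cols integer label map as a single-band raster."""
    labels = np.asarray(labels, dtype=np.int32)
    path = Path(path)
    if _is_tiff(path):
        _write_tiff(path, labels[..., None], None, geo, None, dtype=np.int32)
    else:
        _write_envi(path, labels[..., None].astype(np.int32), None, geo, None,
                    dtype=np.int32)


# -- spectral libraries ------------------------------------------------------


def write_library(path, spectra: Sequence[Spectrum], delimiter: str = "\t") -> None:
    """Write labelled spectra as delimited text.

    First column is the wavelength; each further column is one spectrum and
    its header cell is the class label.  All spectra must share a grid
    (resample first if they do not).
    """
    spectra = list(spectra)
    if not spectra:
        raise FormatError("empty library")
    wl = spectra[0].wavelengths
    if wl is None:
        wl = np.arange(spectra[0].n_bands, dtype=float)
    for s in spectra:
        if s.n_bands != wl.size:
            raise FormatError("spectra on different grids; resample first")
    header = delimiter.join(
        ["wavelength"] + [s.label or f"spectrum_{i}" for i, s in enumerate(spectra)]
    )
    mat = np.column_stack([wl] + [s.values for s in spectra])
    np.savetxt(path, mat, delimiter=delimiter, header=header, comments="",
               fmt="%.8g")


def read_library(path, delimiter: Optional[str] = None) -> list[Spectrum]:
    """Read labelled spectra from delimited text (see :func:`write_library`)."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: a library needs a header and >= 2 rows")
    header = lines[0].split(delimiter)
    header = [h.strip() for h in header if h.strip()]
    try:
        mat = np.loadtxt(lines[1:], delimiter=delimiter)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed numeric data: {exc}") from exc
    mat = np.atleast_2d(mat)
    if mat.shape[1] != len(header):
        raise FormatError(
            f"{path}: header has {len(header)} columns, data has {mat.shape[1]}"
        )
    wl = mat[:, 0]
    if np.any(np.diff(wl) <= 0):
        raise FormatError(f"{path}: wavelengths must be strictly increasing")
    return [
        Spectrum(values=mat[:, k], wavelengths=wl, label=header[k])
        for k in range(1, mat.shape[1])
    ]


def resample_spectra(
    spectra: Sequence[Spectrum], grid: Optional[np.ndarray] = None
) -> list[Spectrum]:
    """Linearly interpolate spectra onto a common wavelength grid.

    Defaults to the grid of the first spectrum.  Values at shared knots are
    unchanged.
    """
    spectra = list(spectra)
    if grid is None:
        grid = spectra[0].wavelengths
        if grid is None:
            raise FormatError("first spectrum has no wavelength grid")
    grid = np.asarray(grid, dtype=float)
    out = []
    for s in spectra:
        if s.wavelengths is None:
            raise FormatError("cannot resample a spectrum without wavelengths")
        if s.wavelengths.size == grid.size and np.allclose(s.wavelengths, grid):
            out.append(Spectrum(s.values.copy(), grid.copy(), s.label))
        else:
            out.append(Spectrum(np.interp(grid, s.wavelengths, s.values),
                                grid.copy(), s.label))
    return out


# -- triplet suites ----------------------------------------------------------


def write_triplets(path, groups, delimiter: str = "\t") -> None:
    """Write a triplet suite; column headers are ``group:label``."""
    flat, headers = [], []
    for gid, (spectra, labels) in enumerate(groups):
        for s, lab in zip(spectra, labels):
            flat.append(s)
            headers.append(f"g{gid}:{lab}")
    tagged = [Spectrum(s.values, s.wavelengths, h)
              for s, h in zip(flat, headers)]
    write_library(path, tagged, delimiter=delimiter)


def read_triplets(path, delimiter: Optional[str] = None):
    """Read a triplet suite written by :func:`write_triplets`."""
    spectra = read_library(path, delimiter=delimiter)
    groups: dict[str, tuple[list[Spectrum], list[str]]] = {}
    order: list[str] = []
    for s in spectra:
        if ":" not in (s.label or ""):
            raise FormatError(f"{path}: expected 'group:label' headers")
        gid, _, lab = s.label.partition(":")
        if gid not in groups:
            groups[gid] = ([], [])
            order.append(gid)
        groups[gid][0].append(Spectrum(s.values, s.wavelengths, lab))
        groups[gid][1].append(lab)
    suite = [groups[g] for g in order]
    for spectra_g, labels_g in suite:
        if len(spectra_g) != 3:
            raise FormatError(f"{path}: every group must hold three spectra")
    return suite
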