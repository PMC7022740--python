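"""Hyperspectral cube I/O, reflectance calibration and ROI extraction.

Cubes are stored on disk in the ENVI convention: a plain-text ``.hdr``
file with ``key = value`` lines (including the wavelength list) next to a
flat little-endian binary payload in band-interleaved-by-line (BIL),
band-sequential (BSQ) or band-interleaved-by-pixel (BIP) order.

In memory a :class:`Hypercube` is always ``lines x samples x bands`` with a
strictly increasing wavelength axis in nanometres.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("tuberspec")

# ENVI numeric codes for the two payload dtypes this package writes.
_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("uint16"): 12}

VALID_INTERLEAVES = ("bil", "bsq", "bip")


class DimensionError(ValueError):
    """Header dimensions disagree with the binary payload."""


class DegenerateReferenceError(ValueError):
    """White minus dark reference is non-positive somewhere it is used."""


class ProvenanceError(ValueError):
    """Data offered to a model does not match the model's preprocessing
    or band-subset provenance."""


@dataclass
class Hypercube:
    """A lines x samples x bands reflectance (or raw-count) image."""

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"  # "raw" | "reflectance"
    interleave: str = "bil"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError("cube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise DimensionError(
                f"{self.data.shape[2]} bands in data but "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.interleave not in VALID_INTERLEAVES:
            raise ValueError(f"unknown interleave {self.interleave!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_index(self, band_nm: float) -> int:
        """Index of the grid band nearest ``band_nm`` (ties -> lower band)."""
        wl = self.wavelengths
        if band_nm < wl[0] or band_nm > wl[-1]:
            raise ValueError(f"{band_nm} nm outside grid [{wl[0]}, {wl[-1]}]")
        dist = np.abs(wl - band_nm)
        return int(np.argmin(dist))  # argmin returns the first (lower) tie


@dataclass
class CalibrationPair:
    """White (~100 %) and dark (~0 %) reference cubes.

    References may be full cubes or single-line profiles (lines == 1)
    recorded once per scan and broadcast along the scan axis.
    """

    white: Hypercube
    dark: Hypercube


@dataclass
class Mask:
    """Boolean foreground mask with the thresholding provenance attached."""

    values: np.ndarray
    provenance: tuple[float, float] | None = None  # (band_nm, threshold)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


@dataclass
class SpectraMatrix:
    """Pixel or sample spectra: one row per spectrum on a shared grid.

    ``preprocessed`` records whether wavelet denoising + normalization has
    already been applied, so downstream stages can refuse double
    application or unpreprocessed input.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    preprocessed: bool = False
    preprocess_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.shape[1] != self.wavelengths.size:
            raise DimensionError("column count must equal wavelength count")

    @property
    def n_spectra(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# ENVI read / write
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    """Parse an ENVI ``key = value`` header; brace lists may span lines."""
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{}").strip()
        fields[key.strip().lower()] = value
    return fields


def read_envi_cube(header_path: str | os.PathLike) -> Hypercube:
    """Read an ENVI header + flat binary cube from disk."""
    header_path = os.fspath(header_path)
    with open(header_path) as fh:
        fields = _parse_header(fh.read())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise ValueError(f"header missing required field {key!r}")
    if "wavelength" not in fields:
        raise ValueError("header missing wavelength list")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    dtype = _ENVI_DTYPES[code]
    wavelengths = np.array(
        [float(v) for v in fields["wavelength"].split(",") if v.strip()]
    )
    if wavelengths.size != bands:
        raise DimensionError("wavelength list length != bands")

    data_path = os.path.splitext(header_path)[0] + ".dat"
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != lines * samples * bands:
        raise DimensionError(
            f"payload holds {raw.size} values, header declares "
            f"{lines * samples * bands}"
        )
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    kind = fields.get("tuberspec kind", "raw")
    return Hypercube(np.ascontiguousarray(data), wavelengths, kind, interleave)


def write_envi_cube(cube: Hypercube, path: str | os.PathLike) -> str:
    """Write ``cube`` as ``<path>.hdr`` + ``<path>.dat``; returns hdr path."""
    path = os.fspath(path)
    base = path[:-4] if path.endswith(".hdr") else path
    lines, samples, bands = cube.shape
    dtype = cube.data.dtype
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype("float32")
    code = _DTYPE_CODES[np.dtype(dtype)]

    data = np.asarray(cube.data, dtype=dtype)
    if cube.interleave == "bil":
        flat = data.transpose(0, 2, 1)
    elif cube.interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    else:  # bip
        flat = data
    flat.astype(_ENVI_DTYPES[code]).tofile(base + ".dat")

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {cube.interleave}\n"
        "byte order = 0\n"
        f"tuberspec kind = {cube.kind}\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(base + ".hdr", "w") as fh:
        fh.write(header)
    return base + ".hdr"


# ---------------------------------------------------------------------------
# Calibration, masking, extraction, trimming
# ---------------------------------------------------------------------------

def calibrate(raw: Hypercube, pair: CalibrationPair) -> Hypercube:
    """White/dark reflectance calibration: (raw - dark) / (white - dark).

    References with a single line are broadcast along the scan (line) axis,
    matching line-scan instruments that record one reference line per band.
    Out-of-range reflectance is permitted (clipping is deferred to
    visualization) but logged when >5 % of pixels fall outside [0, 1].
    """
    white, dark = pair.white.data, pair.dark.data
    if white.shape[2] != raw.shape[2] or dark.shape[2] != raw.shape[2]:
        raise DimensionError("reference band count differs from raw cube")
    denom = white.astype(float) - dark.astype(float)
    if np.any(denom <= 0):
        raise DegenerateReferenceError(
            "white - dark is non-positive in at least one element"
        )
    refl = (raw.data.astype(float) - dark) / denom
    frac_out = np.mean((refl < 0) | (refl > 1))
    if frac_out > 0.05:
        logger.warning(
            "calibrate: %.1f%% of pixels outside [0, 1] reflectance",
            100 * frac_out,
        )
    return Hypercube(refl, raw.wavelengths, "reflectance", raw.interleave)


def build_mask(
    cube: Hypercube, band_nm: float = 590.0, threshold: float = 0.1
) -> Mask:
    """Foreground mask: reflectance at the band nearest ``band_nm`` above
    ``threshold``.

    The background/slice contrast is strongest around 590 nm, where slice
    tissue reflects well and the black sample plate stays near zero.
    """
    idx = cube.band_index(band_nm)
    values = cube.data[:, :, idx] > threshold
    return Mask(values, provenance=(float(band_nm), float(threshold)))


def extract_spectra(cube: Hypercube, mask: Mask) -> tuple[SpectraMatrix, np.ndarray]:
    """Spectra of all masked pixels (row-major order) and their mean."""
    if mask.values.shape != cube.shape[:2]:
        raise DimensionError("mask shape differs from cube spatial shape")
    if mask.n_pixels == 0:
        raise ValueError("empty mask: no pixels to extract")
    pixels = cube.data[mask.values]  # row-major over True pixels
    matrix = SpectraMatrix(pixels.astype(float), cube.wavelengths)
    return matrix, matrix.data.mean(axis=0)


def trim_bands(x, low_nm: float = 477.0, high_nm: float = 947.0):
    """Drop noisy head/tail bands, keeping ``low_nm <= lambda <= high_nm``.

    Works on a :class:`Hypercube` or a :class:`SpectraMatrix`; the
    wavelength axis is updated alongside the data.
    """
    if low_nm >= high_nm:
        raise ValueError("low_nm must be below high_nm")
    keep = (x.wavelengths >= low_nm) & (x.wavelengths <= high_nm)
    if not keep.any():
        raise ValueError("no bands inside the requested window")
    if isinstance(x, Hypercube):
        return replace(x, data=x.data[:, :, keep], wavelengths=x.wavelengths[keep])
    if isinstance(x, SpectraMatrix):
        return SpectraMatrix(
            x.data[:, keep],
            x.wavelengths[keep],
            preprocessed=x.preprocessed,
            preprocess_spec=dict(x.preprocess_spec),
        )
    raise TypeError(f"cannot trim object of type {type(x).__name__}")
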