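"""Spectral preprocessing: Daubechies wavelet denoising then area
normalization.

The same two-step chain is applied to sample mean spectra before modeling
and to every pixel spectrum before map prediction, so a single
:class:`PreprocessSpec` is threaded through both paths and recorded as
provenance on every matrix it touches.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pywt

from .image_io import SpectraMatrix


@dataclass(frozen=True)
class PreprocessSpec:
    """Denoising/normalization settings.

    wavelet_name: PyWavelets identifier; "db9" = Daubechies, 9 vanishing
        moments.
    decomposition_level: multilevel decomposition depth.
    normalize: "area" divides each spectrum by its sum; "none" skips it.
    threshold_rule: "universal" soft-thresholds detail coefficients at
        sigma * sqrt(2 ln N) with sigma estimated from the median absolute
        deviation of the finest-level details.
    """

    wavelet_name: str = "db9"
    decomposition_level: int = 3
    normalize: str = "area"
    threshold_rule: str = "universal"

    def __post_init__(self) -> None:
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if self.normalize not in ("area", "none"):
            raise ValueError("normalize must be 'area' or 'none'")


def wavelet_denoise(spectrum: np.ndarray, spec: PreprocessSpec | None = None) -> np.ndarray:
    """Denoise one spectrum by multilevel wavelet soft-thresholding.

    Decomposes to ``spec.decomposition_level`` with symmetric boundary
    padding, soft-thresholds every detail level at the universal threshold
    and reconstructs to the original length. A constant spectrum passes
    through unchanged (all detail coefficients are zero).
    """
    spec = spec or PreprocessSpec()
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1:
        raise ValueError("wavelet_denoise expects a 1-D spectrum")
    try:
        wavelet = pywt.Wavelet(spec.wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {spec.wavelet_name!r}") from exc
    max_level = pywt.dwt_max_level(x.size, wavelet.dec_len)
    if spec.decomposition_level > max_level:
        raise ValueError(
            f"level {spec.decomposition_level} too deep for length {x.size} "
            f"(max {max_level})"
        )
    coeffs = pywt.wavedec(x, wavelet, level=spec.decomposition_level, mode="symmetric")
    finest = coeffs[-1]
    # MAD of finest details; 0.6745 = Phi^-1(0.75) makes it unbiased for sigma
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(x.size))
    denoised = [coeffs[0]] + [
        pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
    ]
    return pywt.waverec(denoised, wavelet, mode="symmetric")[: x.size]


def area_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Divide a spectrum by its sum so it integrates (sums) to one.

    On a uniform wavelength grid this equals normalizing by the trapezoidal
    integral up to a constant factor, so the two conventions coincide after
    normalization.
    """
    x = np.asarray(spectrum, dtype=float)
    total = x.sum()
    if total == 0:
        raise ValueError("cannot area-normalize a zero-sum spectrum")
    return x / total


def preprocess_spectrum(spectrum: np.ndarray, spec: PreprocessSpec | None = None) -> np.ndarray:
    """Denoise, then (optionally) area-normalize one spectrum."""
    spec = spec or PreprocessSpec()
    out = wavelet_denoise(spectrum, spec)
    if spec.normalize == "area":
        out = area_normalize(out)
    return out


def preprocess_matrix(
    matrix: SpectraMatrix, spec: PreprocessSpec | None = None, force: bool = False
) -> SpectraMatrix:
    """Row-wise preprocessing of a spectra matrix with provenance tracking.

    Refuses to preprocess an already-preprocessed matrix unless ``force``
    is set, so the chain cannot silently be applied twice.
    """
    spec = spec or PreprocessSpec()
    if matrix.preprocessed and not force:
        raise ValueError(
            "matrix already preprocessed; pass force=True to reapply"
        )
    out = np.empty_like(matrix.data)
    for i in range(matrix.n_spectra):
        out[i] = preprocess_spectrum(matrix.data[i], spec)
    return SpectraMatrix(
        out, matrix.wavelengths, preprocessed=True, preprocess_spec=asdict(spec)
    )
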