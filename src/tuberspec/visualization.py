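"""Pixel-wise model application and pseudo-color prediction maps.

A trained model is applied to every masked (slice) pixel of a calibrated
cube, after the same trimming/preprocessing chain used in training, to
produce a :class:`PredictionMap`: the per-pixel value field, its mean
P* over the slice, and (when a measured value T* is supplied) the
relative error between the two.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .image_io import Hypercube, Mask, ProvenanceError, extract_spectra, trim_bands
from .preprocess import PreprocessSpec, preprocess_matrix


@dataclass
class PredictionMap:
    """Per-pixel predicted target values over a slice mask."""

    values: np.ndarray          # NaN outside the mask
    mask: Mask
    target: str
    units: str = ""
    measured: float | None = None  # T*, the reference measurement

    @property
    def predicted_average(self) -> float:
        """P*: mean predicted value over the masked pixels."""
        return float(np.nanmean(self.values[self.mask.values]))

    @property
    def relative_error_percent(self) -> float | None:
        if self.measured is None:
            return None
        return relative_error(self.predicted_average, self.measured)


def relative_error(p_star: float, t_star: float) -> float:
    """Percent deviation of the predicted slice average from the measured
    value: 100 |P* - T*| / T*."""
    if t_star == 0:
        raise ZeroDivisionError("measured value is zero")
    return 100.0 * abs(p_star - t_star) / abs(t_star)


def pixelwise_predict(
    cube: Hypercube,
    mask: Mask,
    model,
    preprocess_spec: PreprocessSpec | None = None,
    low_nm: float = 477.0,
    high_nm: float = 947.0,
    target: str = "",
    units: str = "",
    measured: float | None = None,
) -> PredictionMap:
    """Apply a trained model to every masked pixel of a reflectance cube.

    Pixel spectra are trimmed to the analysis window, preprocessed exactly
    as the training spectra were, subset to the model's bands, and
    predicted. Background pixels are never touched.
    """
    if cube.kind != "reflectance":
        raise ProvenanceError("pixelwise_predict requires a calibrated cube")
    spec = preprocess_spec or PreprocessSpec()
    pixels, _ = extract_spectra(cube, mask)
    pixels = trim_bands(pixels, low_nm, high_nm)
    pixels = preprocess_matrix(pixels, spec)
    subset = model.provenance.band_indices
    if subset is not None:
        arr = pixels.data[:, subset]
    else:
        arr = pixels.data
    if arr.shape[1] != model.provenance.n_bands:
        raise ProvenanceError(
            f"cube provides {arr.shape[1]} bands after trimming/subsetting, "
            f"model expects {model.provenance.n_bands}"
        )
    predicted = model.predict(arr)
    values = np.full(mask.values.shape, np.nan)
    values[mask.values] = predicted
    return PredictionMap(values, mask, target=target, units=units, measured=measured)


def render_map(
    pmap: PredictionMap,
    color_scale: tuple[float, float],
    out_path: str | os.PathLike,
) -> str:
    """Render a prediction map as a PNG with a blue-green-red scale.

    Values are clipped to ``color_scale`` for display only (the value
    array is not altered); background pixels are drawn as a flat grey.
    Output bytes are deterministic for identical inputs.
    """
    low, high = color_scale
    if not low < high:
        raise ValueError("color scale must satisfy low < high")
    out_path = os.fspath(out_path)
    display = np.ma.masked_invalid(pmap.values)
    fig, ax = plt.subplots(figsize=(4, 4))
    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad("0.6")  # background
    im = ax.imshow(display, cmap=cmap, vmin=low, vmax=high)
    label = pmap.target + (f" [{pmap.units}]" if pmap.units else "")
    fig.colorbar(im, ax=ax, label=label)
    title = f"P* = {pmap.predicted_average:.3f}"
    if pmap.measured is not None:
        title += f", T* = {pmap.measured:.3f}"
    ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(out_path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return out_path


def save_map(pmap: PredictionMap, base_path: str | os.PathLike) -> tuple[str, str]:
    """Serialize the value array (ENVI-style single band) + JSON summary.

    The rendered PNG is a derived view; this keeps the numbers lossless.
    """
    from .image_io import Hypercube, write_envi_cube

    base_path = os.fspath(base_path)
    cube = Hypercube(
        np.nan_to_num(pmap.values, nan=0.0)[:, :, None].astype(np.float32),
        np.array([0.0]),
        kind="reflectance",
    )
    hdr = write_envi_cube(cube, base_path)
    summary = {
        "target": pmap.target,
        "units": pmap.units,
        "P_star": pmap.predicted_average,
        "T_star": pmap.measured,
        "relative_error_percent": pmap.relative_error_percent,
        "n_pixels": pmap.mask.n_pixels,
    }
    json_path = base_path + ".json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=1)
    return hdr, json_path
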