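"""Synthetic hyperspectral scenes of fresh-cut tuber slices with known
ground truth.

Every downstream stage (calibration, masking, preprocessing, wavelength
selection, regression, mapping) is tested against data from this module,
so the generator reproduces the statistical structure those stages assume:

* line-scan reflectance cubes on a 380-1030 nm grid whose 477-947 nm
  window holds exactly 370 bands;
* slice spectra built as a smooth baseline multiplied by Beer-Lambert
  style Gaussian absorption bands — a narrow pigment band at 678 nm
  (producing the characteristic valley at 678 nm and local peak near
  705 nm), a broad browning band near 520 nm whose depth grows with
  browning, and NIR water bands near 760 and 930 nm;
* ground-truth color values mapped affinely from a latent browning level
  in [0, 1] so that browning 0 and 1 hit the observed extremes of
  L* (64.738-43.794), a* (-3.096-+2.050) and b* (11.247-20.681); the
  derived indices BI and L*/b* follow from their defining formulas;
* raw/white/dark cubes constructed so that white/dark calibration
  inverts the construction exactly.

Within-slice spatial variation is a smooth low-frequency cosine field,
mimicking the gradually varying browning observed across a cut surface
(no speckle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import Hypercube, Mask
from .reference import browning_index, build_reference_table

PLACEMENT_GROUPS = (0, 1, 2, 4, 8, 12, 24, 36)  # hours; labels only

# Observed extremes of the measured color values; browning 0 -> fresh
# endpoint, browning 1 -> fully browned endpoint.
L_RANGE = (64.738, 43.794)   # L* decreases with browning
A_RANGE = (-3.096, 2.050)    # a* increases (greener -> redder)
B_RANGE = (11.247, 20.681)   # b* increases (bluer -> yellower)
WC_RANGE = (0.753, 0.879)    # g water / g wet matter


def make_wavelength_grid(start_nm: float, end_nm: float, n_bands: int) -> np.ndarray:
    """Evenly spaced wavelength grid with inclusive endpoints."""
    if n_bands < 2:
        raise ValueError("n_bands must be at least 2")
    if start_nm >= end_nm:
        raise ValueError("start_nm must be below end_nm")
    return np.linspace(start_nm, end_nm, n_bands)


def default_full_grid() -> np.ndarray:
    """Full acquisition grid: the 477-947 nm / 370-band analysis window
    extended at the same spacing to cover 380-1030 nm (511 bands), so
    trimming to 477-947 nm retains exactly 370 bands."""
    step = (947.0 - 477.0) / 369.0
    return 477.0 + step * np.arange(-76, 370 + 65)


@dataclass(frozen=True)
class SliceTruth:
    """Ground truth for one simulated slice."""

    slice_id: str
    browning_level: float
    water_content_true: float
    L_true: float
    a_true: float
    b_true: float
    BI_true: float
    Lb_true: float
    placement_group: int


@dataclass
class SpectralModelConfig:
    """Parameters of the synthetic reflectance model.

    Reflectance(lambda) = baseline(lambda) * exp(-sum strengths * Gaussians)
    + N(0, noise_sd), clipped to (0, 1). The pigment and browning band
    strengths scale with the local browning level; the water band strengths
    scale with local dryness (1 - water content), so band depth is a
    monotone, invertible encoding of both quantities.
    """

    wavelength_grid: np.ndarray = field(default_factory=default_full_grid)
    # baseline: quadratic in nm peaked near 710 nm, values well inside (0,1)
    baseline_peak: float = 0.75
    baseline_curvature: float = 0.9
    baseline_center_nm: float = 710.0
    pigment_center: float = 678.0
    pigment_width: float = 12.0
    pigment_strength: float = 0.35   # x local browning
    browning_center: float = 520.0
    browning_width: float = 80.0
    browning_strength: float = 0.8   # x local browning
    water_centers: tuple[float, float] = (760.0, 930.0)
    water_widths: tuple[float, float] = (30.0, 45.0)
    water_strength: float = 1.2      # x (1 - local water content)
    noise_sd: float = 0.005          # reflectance units
    pixel_field_scale: float = 0.05  # within-slice browning variability
    background_reflectance: float = 0.02

    def baseline(self) -> np.ndarray:
        wl = np.asarray(self.wavelength_grid, dtype=float)
        u = (wl - self.baseline_center_nm) / 650.0
        return self.baseline_peak - self.baseline_curvature * u**2

    def band_shapes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit-strength Gaussian profiles (pigment, browning, water)."""
        wl = np.asarray(self.wavelength_grid, dtype=float)

        def g(c, w):
            return np.exp(-0.5 * ((wl - c) / w) ** 2)

        water = sum(g(c, w) for c, w in zip(self.water_centers, self.water_widths))
        return (
            g(self.pigment_center, self.pigment_width),
            g(self.browning_center, self.browning_width),
            water,
        )


def color_from_browning(browning_level) -> tuple:
    """Affine browning -> (L*, a*, b*) maps spanning the observed extremes."""
    t = np.asarray(browning_level, dtype=float)
    L = L_RANGE[0] + t * (L_RANGE[1] - L_RANGE[0])
    a = A_RANGE[0] + t * (A_RANGE[1] - A_RANGE[0])
    b = B_RANGE[0] + t * (B_RANGE[1] - B_RANGE[0])
    return L, a, b


def sample_slice_truths(n_slices: int, seed: int = 0) -> list[SliceTruth]:
    """Draw reproducible slice ground truths.

    Browning levels are uniform on [0, 1]; water content is drawn
    independently within its observed range. Placement-group labels are
    assigned in equal blocks (30 slices per group when n = 240).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    browning = rng.uniform(0.0, 1.0, n_slices)
    wc = rng.uniform(*WC_RANGE, n_slices)
    truths = []
    for i in range(n_slices):
        L, a, b = color_from_browning(browning[i])
        group = PLACEMENT_GROUPS[min(i * len(PLACEMENT_GROUPS) // n_slices,
                                     len(PLACEMENT_GROUPS) - 1)]
        truths.append(
            SliceTruth(
                slice_id=f"slice{i:04d}",
                browning_level=float(browning[i]),
                water_content_true=float(wc[i]),
                L_true=float(L),
                a_true=float(a),
                b_true=float(b),
                BI_true=float(browning_index(L, a, b)),
                Lb_true=float(L / b),
                placement_group=group,
            )
        )
    return truths


def simulate_pixel_spectrum(
    truth: SliceTruth,
    local_browning: float,
    local_water: float,
    config: SpectralModelConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reflectance spectrum of one pixel (see :class:`SpectralModelConfig`)."""
    refl = _pixel_spectra(
        np.atleast_1d(float(local_browning)),
        np.atleast_1d(float(local_water)),
        config,
        rng,
    )
    return refl[0]


def _pixel_spectra(
    browning: np.ndarray,
    water: np.ndarray,
    config: SpectralModelConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Vectorized pixel spectra: one row per (browning, water) pair."""
    wl = np.asarray(config.wavelength_grid, dtype=float)
    if wl.size == 0:
        raise ValueError("config wavelength grid is empty")
    base = config.baseline()
    g_pig, g_brown, g_water = config.band_shapes()
    od = (
        np.outer(config.pigment_strength * browning, g_pig)
        + np.outer(config.browning_strength * browning, g_brown)
        + np.outer(config.water_strength * (1.0 - water), g_water)
    )
    refl = base[None, :] * np.exp(-od)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        refl = refl + rng.normal(0.0, config.noise_sd, refl.shape)
    return np.clip(refl, 1e-6, 1.0 - 1e-6)


# ---------------------------------------------------------------------------
# Scene simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseGeometry:
    """Axis-aligned ellipse footprint of one slice in the image frame."""

    center_line: float
    center_sample: float
    radius_line: float
    radius_sample: float


def grid_geometry(
    n_slices: int, tile: int = 22, radius_line: float = 8.0, radius_sample: float = 7.0
) -> tuple[list[EllipseGeometry], tuple[int, int]]:
    """Lay out ``n_slices`` non-overlapping ellipses on a rectangular grid;
    returns the geometry list and the (lines, samples) frame shape."""
    n_cols = int(np.ceil(np.sqrt(n_slices)))
    n_rows = int(np.ceil(n_slices / n_cols))
    geoms = [
        EllipseGeometry(
            center_line=(i // n_cols) * tile + tile / 2,
            center_sample=(i % n_cols) * tile + tile / 2,
            radius_line=radius_line,
            radius_sample=radius_sample,
        )
        for i in range(n_slices)
    ]
    return geoms, (n_rows * tile, n_cols * tile)


def _cosine_field(shape: tuple[int, int], rng: np.random.Generator,
                  n_terms: int = 3) -> np.ndarray:
    """Smooth zero-mean low-frequency random field with unit max amplitude."""
    lines = np.arange(shape[0])[:, None]
    samples = np.arange(shape[1])[None, :]
    f = np.zeros(shape)
    for _ in range(n_terms):
        fu, fv = rng.uniform(0.02, 0.08, 2)  # cycles per pixel: long waves
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        f = f + amp * np.cos(2 * np.pi * (fu * lines + fv * samples) + phase)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


@dataclass
class SimulatedScene:
    """One synthetic acquisition: raw/white/dark cubes plus ground truth."""

    raw: Hypercube
    white: Hypercube
    dark: Hypercube
    labels: np.ndarray          # 0 = background, i+1 = truths[i]
    mask_truth: Mask
    reference: pd.DataFrame
    reflectance_truth: np.ndarray  # noiseless construction input


def simulate_cube(
    truths: list[SliceTruth],
    geometry: list[EllipseGeometry] | None = None,
    config: SpectralModelConfig | None = None,
    seed: int = 0,
) -> SimulatedScene:
    """Render slices into raw/white/dark cubes that calibration inverts.

    ``raw = dark + reflectance * (white - dark)`` per pixel; background
    pixels carry near-zero reflectance so a 590 nm / 0.1 threshold
    recovers the generating footprint. The returned reference table holds
    slice-level averages of the per-pixel truth fields (BI and L*/b*
    recomputed from the averaged L, a, b).
    """
    config = config or SpectralModelConfig()
    if geometry is None:
        geometry, frame = grid_geometry(len(truths))
    else:
        frame = (
            int(np.ceil(max(g.center_line + g.radius_line for g in geometry))) + 1,
            int(np.ceil(max(g.center_sample + g.radius_sample for g in geometry))) + 1,
        )
    if len(geometry) != len(truths):
        raise ValueError("one geometry entry required per truth")

    rng = np.random.default_rng(seed)
    wl = np.asarray(config.wavelength_grid, dtype=float)
    n_bands = wl.size
    labels = np.zeros(frame, dtype=int)
    refl = np.full(frame + (n_bands,), config.background_reflectance, dtype=float)

    lines = np.arange(frame[0])[:, None]
    samples = np.arange(frame[1])[None, :]
    rows = []
    for k, (truth, geom) in enumerate(zip(truths, geometry)):
        if (
            geom.center_line - geom.radius_line < 0
            or geom.center_line + geom.radius_line > frame[0]
            or geom.center_sample - geom.radius_sample < 0
            or geom.center_sample + geom.radius_sample > frame[1]
        ):
            raise ValueError(f"slice {truth.slice_id} footprint exceeds frame")
        inside = (
            ((lines - geom.center_line) / geom.radius_line) ** 2
            + ((samples - geom.center_sample) / geom.radius_sample) ** 2
        ) <= 1.0
        if np.any(labels[inside]):
            raise ValueError(f"slice {truth.slice_id} overlaps a previous slice")
        labels[inside] = k + 1

        browning_field = _cosine_field(frame, rng)[inside]
        water_field = _cosine_field(frame, rng)[inside]
        local_browning = np.clip(
            truth.browning_level + config.pixel_field_scale * browning_field, 0.0, 1.0
        )
        local_water = np.clip(
            truth.water_content_true
            + 0.1 * config.pixel_field_scale * water_field,
            *WC_RANGE,
        )
        refl[inside] = _pixel_spectra(local_browning, local_water, config, rng)

        L_px, a_px, b_px = color_from_browning(local_browning)
        rows.append(
            {
                "slice_id": truth.slice_id,
                "group_h": truth.placement_group,
                "L": L_px.mean(),
                "a": a_px.mean(),
                "b": b_px.mean(),
                "WC": local_water.mean(),
            }
        )

    if config.noise_sd > 0:  # background noise too
        bg = labels == 0
        refl[bg] = np.clip(
            refl[bg] + rng.normal(0.0, config.noise_sd, refl[bg].shape),
            1e-6,
            1.0 - 1e-6,
        )

    # white/dark references with a smooth spectral gain; raw inverts Eq-style
    dark_counts = np.full(frame + (n_bands,), 100.0, dtype=float)
    gain = 900.0 * (0.6 + 0.4 * np.exp(-0.5 * ((wl - 700.0) / 300.0) ** 2))
    white_counts = dark_counts + gain[None, None, :]
    raw_counts = dark_counts + refl * (white_counts - dark_counts)

    table = build_reference_table(
        [r["slice_id"] for r in rows],
        [r["group_h"] for r in rows],
        [r["L"] for r in rows],
        [r["a"] for r in rows],
        [r["b"] for r in rows],
        [r["WC"] for r in rows],
    )
    return SimulatedScene(
        raw=Hypercube(raw_counts, wl, "raw"),
        white=Hypercube(white_counts, wl, "raw"),
        dark=Hypercube(dark_counts, wl, "raw"),
        labels=labels,
        mask_truth=Mask(labels > 0),
        reference=table,
        reflectance_truth=refl,
    )


def simulate_dataset(
    n_slices: int = 240,
    noise_sd: float = 0.005,
    seed: int = 0,
    slices_per_scene: int = 30,
    config: SpectralModelConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[SimulatedScene]]:
    """Simulate a full study: several scenes, calibrated mean ROI spectra.

    Returns (reference table, mean-spectra matrix on the full grid,
    wavelength grid, scenes). Mean spectra are computed from the
    calibrated cubes through the package's own mask/extract path.
    """
    from dataclasses import replace

    from .image_io import CalibrationPair, calibrate, extract_spectra

    base_config = replace(config or SpectralModelConfig(), noise_sd=noise_sd)
    truths = sample_slice_truths(n_slices, seed=seed)
    tables, spectra, scenes = [], [], []
    for start in range(0, n_slices, slices_per_scene):
        chunk = truths[start : start + slices_per_scene]
        scene = simulate_cube(chunk, config=base_config, seed=seed + 1000 + start)
        refl = calibrate(scene.raw, CalibrationPair(scene.white, scene.dark))
        for k in range(len(chunk)):
            slice_mask = Mask(scene.labels == k + 1)
            _, mean_spec = extract_spectra(refl, slice_mask)
            spectra.append(mean_spec)
        tables.append(scene.reference)
        scenes.append(scene)
    table = pd.concat(tables, ignore_index=True)
    return table, np.array(spectra), np.asarray(base_config.wavelength_grid), scenes
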