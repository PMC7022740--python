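import numpy as np
import pytest

from tuberspec.image_io import CalibrationPair, Mask, calibrate
from tuberspec.pipeline import PipelineConfig, prepare_spectra
from tuberspec.synthetic import (
    SpectralModelConfig,
    sample_slice_truths,
    simulate_cube,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def noise_free_scene():
    """Four slices rendered without noise: calibration must invert exactly."""
    truths = sample_slice_truths(4, seed=2)
    scene = simulate_cube(truths, config=SpectralModelConfig(noise_sd=0.0), seed=3)
    return truths, scene


@pytest.fixture(scope="session")
def reflectance_cube(noise_free_scene):
    _, scene = noise_free_scene
    return calibrate(scene.raw, CalibrationPair(scene.white, scene.dark))


@pytest.fixture(scope="session")
def study_dataset():
    """The full study conditions: 240 slices, reflectance noise sd 0.005."""
    table, spectra, wavelengths, scenes = simulate_dataset(
        n_slices=240, noise_sd=0.005, seed=101
    )
    return table, spectra, wavelengths, scenes


@pytest.fixture(scope="session")
def prepared_study(study_dataset):
    """Trimmed + preprocessed mean spectra of the study dataset."""
    table, spectra, wavelengths, _ = study_dataset
    matrix = prepare_spectra(spectra, wavelengths, PipelineConfig())
    return table, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
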