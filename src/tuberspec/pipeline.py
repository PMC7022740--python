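"""End-to-end pipeline: simulate -> calibrate -> extract -> preprocess ->
split -> select -> train -> evaluate -> visualize.

A single :class:`PipelineConfig` drives the whole grid of
(target x band set x model) runs. One master seed fans out to per-stage
seeds through a CRC-keyed seed sequence, so every stage is independently
reproducible and no two stages share a random stream.

Reference values of the prediction set are never passed to the selection
or training stages; they re-enter only at evaluation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import evaluation, reference, selection
from .image_io import SpectraMatrix, trim_bands
from .preprocess import PreprocessSpec, preprocess_matrix
from .regression import ModelProvenance, fit_lssvm, fit_pls
from .synthetic import simulate_dataset

logger = logging.getLogger("tuberspec")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    entropy = [int(master_seed), zlib.crc32(stage.encode())]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    out_dir: str = "tuberspec_run"
    n_slices: int = 240
    noise_sd: float = 0.005
    seed: int = 7
    targets: tuple[str, ...] = reference.TARGETS
    band_sets: tuple[str, ...] = ("full", "spa", "cars")
    models: tuple[str, ...] = ("pls", "lssvm")
    trim_low_nm: float = 477.0
    trim_high_nm: float = 947.0
    outlier_k: float = 3.0
    folds: int = 10
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    spa_n_min: int = 5
    spa_n_max: int = 30
    cars_n_runs: int = 50
    max_pls_components: int = 20
    render_maps: bool = False
    spectral_config: object | None = None  # SpectralModelConfig override

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["preprocess"] = asdict(self.preprocess)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def prepare_spectra(
    spectra: np.ndarray, wavelengths: np.ndarray, config: PipelineConfig
) -> SpectraMatrix:
    """Trim mean spectra to the analysis window and preprocess them."""
    matrix = SpectraMatrix(spectra, wavelengths)
    matrix = trim_bands(matrix, config.trim_low_nm, config.trim_high_nm)
    return preprocess_matrix(matrix, config.preprocess)


def select_bands(
    method: str,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> list[int] | None:
    """Band subset for a band-set name; None means the full spectrum."""
    if method == "full":
        return None
    if method == "spa":
        result = selection.spa_select(
            X_cal, y_cal, n_min=config.spa_n_min, n_max=config.spa_n_max,
            folds=config.folds, seed=seed,
        )
    elif method == "cars":
        result = selection.cars_select(
            X_cal, y_cal, n_runs=config.cars_n_runs, folds=config.folds, seed=seed,
        )
    else:
        raise ValueError(f"unknown band set {method!r}")
    return result.selected_band_indices


def train_model(
    model_name: str,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: PipelineConfig,
    seed: int,
    provenance: ModelProvenance,
):
    if model_name == "pls":
        return fit_pls(
            X_cal, y_cal, max_components=config.max_pls_components,
            folds=config.folds, seed=seed, provenance=provenance,
        )
    if model_name == "lssvm":
        return fit_lssvm(
            X_cal, y_cal, folds=config.folds, seed=seed, provenance=provenance
        )
    raise ValueError(f"unknown model {model_name!r}")


def run_pipeline(config: PipelineConfig, dataset=None) -> pd.DataFrame:
    """Run the full grid and write reports/models/logs to the run directory.

    Returns the evaluation report (also written as ``report.csv``).
    Deterministic given the config: rerunning with the same config and
    seed reproduces every output. ``dataset`` may supply a precomputed
    ``(reference table, mean spectra, wavelengths)`` triple to skip the
    simulation stage (e.g. for measured data loaded from disk).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    run_stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    t0 = time.time()

    if dataset is None:
        table, spectra, wavelengths, _scenes = simulate_dataset(
            n_slices=config.n_slices,
            noise_sd=config.noise_sd,
            seed=stage_seed(config.seed, "simulate"),
            config=config.spectral_config,
        )
    else:
        table, spectra, wavelengths = dataset
    table.to_csv(os.path.join(config.out_dir, "reference.csv"), index=False)
    logger.info("simulate: %d slices in %.1fs", len(table), time.time() - t0)

    matrix = prepare_spectra(spectra, wavelengths, config)
    rows = []
    selections = {}
    for target in config.targets:
        labels = reference.assign_sets(table, target, outlier_k=config.outlier_k)
        cal = (labels == "calibration").to_numpy()
        pred = (labels == "prediction").to_numpy()
        y = table[target].to_numpy(dtype=float)
        X_cal, y_cal = matrix.data[cal], y[cal]
        X_pred, y_pred = matrix.data[pred], y[pred]
        for band_set in config.band_sets:
            t_sel = time.time()
            subset = select_bands(
                band_set, X_cal, y_cal, config,
                seed=stage_seed(config.seed, f"select-{band_set}-{target}"),
            )
            cols = slice(None) if subset is None else subset
            n_vars = matrix.data.shape[1] if subset is None else len(subset)
            selections[f"{target}-{band_set}"] = {
                "indices": None if subset is None else list(map(int, subset)),
                "n_variables": n_vars,
                "reduction_percent": selection.reduction_percent(
                    n_vars, matrix.data.shape[1]
                ),
            }
            logger.info(
                "select %s/%s: %d vars in %.1fs",
                target, band_set, n_vars, time.time() - t_sel,
            )
            for model_name in config.models:
                t_fit = time.time()
                prov = ModelProvenance(
                    n_bands=n_vars,
                    band_indices=None if subset is None else list(map(int, subset)),
                    preprocess=dict(matrix.preprocess_spec),
                )
                model, cv = train_model(
                    model_name, X_cal[:, cols], y_cal, config,
                    seed=stage_seed(config.seed, f"train-{model_name}-{band_set}-{target}"),
                    provenance=prov,
                )
                rows.append(
                    evaluation.evaluate_model(
                        target, model_name, band_set, n_vars,
                        y_cal, model.predict(X_cal[:, cols]),
                        y_cal, cv.predictions,
                        y_pred, model.predict(X_pred[:, cols]),
                    )
                )
                logger.info(
                    "train %s/%s/%s in %.1fs",
                    target, band_set, model_name, time.time() - t_fit,
                )

    report = evaluation.build_report(rows)
    report.to_csv(os.path.join(config.out_dir, "report.csv"), index=False)
    with open(os.path.join(config.out_dir, "selections.json"), "w") as fh:
        json.dump({**run_stamp, "selections": selections}, fh, indent=1)
    with open(os.path.join(config.out_dir, "run.json"), "w") as fh:
        json.dump({**run_stamp, "elapsed_s": round(time.time() - t0, 2),
                   "n_rows": len(report)}, fh, indent=1)
    return report


# ---------------------------------------------------------------------------
# Model serialization (JSON; arrays inline)
# ---------------------------------------------------------------------------

def save_model(model, path: str | os.PathLike) -> None:
    """Serialize a fitted model to JSON.

    PLS prediction is affine, so the regression vector and intercept
    suffice; LS-SVM stores its support values and scaled training spectra.
    """
    from .regression import LSSVMModel, PLSModel

    prov = asdict(model.provenance)
    if isinstance(model, PLSModel):
        payload = {
            "type": "pls",
            "n_components": model.n_components,
            "coef": model.coef_.tolist(),
            "intercept": model.intercept_,
            "provenance": prov,
        }
    elif isinstance(model, LSSVMModel):
        payload = {
            "type": "lssvm",
            "gamma": model.gamma,
            "sigma2": model.sigma2,
            "alpha": model.alpha.tolist(),
            "bias": model.bias,
            "x_train": model.x_train.tolist(),
            "x_mean": model.x_mean.tolist(),
            "x_scale": model.x_scale.tolist(),
            "provenance": prov,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


@dataclass
class AffineModel:
    """Reloaded PLS model: prediction is X @ coef + intercept."""

    coef: np.ndarray
    intercept: float
    provenance: ModelProvenance

    def predict(self, X) -> np.ndarray:
        arr = self.provenance.check(X)
        return arr @ self.coef + self.intercept


def load_model(path: str | os.PathLike):
    from .regression import LSSVMModel

    with open(path) as fh:
        payload = json.load(fh)
    prov = ModelProvenance(**payload["provenance"])
    if payload["type"] == "pls":
        return AffineModel(np.asarray(payload["coef"]), payload["intercept"], prov)
    if payload["type"] == "lssvm":
        return LSSVMModel(
            gamma=payload["gamma"],
            sigma2=payload["sigma2"],
            alpha=np.asarray(payload["alpha"]),
            bias=payload["bias"],
            x_train=np.asarray(payload["x_train"]),
            x_mean=np.asarray(payload["x_mean"]),
            x_scale=np.asarray(payload["x_scale"]),
            provenance=prov,
        )
    raise ValueError(f"unknown model type {payload['type']!r}")
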