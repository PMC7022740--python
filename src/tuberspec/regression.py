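"""PLS and LS-SVM regression with ten-fold cross-validation.

PLS is delegated to scikit-learn's ``PLSRegression`` (latent-variable
count chosen by cross-validated RMSE). The least-squares support vector
machine is solved directly from its dual KKT system

    [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]

with an RBF kernel K(u, v) = exp(-||u - v||^2 / sigma^2). Hyperparameters
(gamma, sigma^2) are optimized by a budgeted two-stage log-grid search
scored by ten-fold RMSECV. Band columns are autoscaled with statistics
from the training rows of each fold only, so cross-validation scores are
leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .image_io import ProvenanceError, SpectraMatrix


def make_folds(n: int, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded fold assignment: sizes differ by at most one, disjoint cover."""
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, folds)):
        fold_ids[chunk] = f
    return fold_ids


def _resolve_folds(folds, n: int, seed: int) -> np.ndarray:
    """Accept either a fold count or an explicit per-sample assignment."""
    if np.ndim(folds) == 1:
        fold_ids = np.asarray(folds, dtype=int)
        if fold_ids.size != n:
            raise ValueError("fold assignment length must equal n samples")
        return fold_ids
    return make_folds(n, folds=min(int(folds), n), seed=seed)


@dataclass
class CVResult:
    fold_ids: np.ndarray
    predictions: np.ndarray  # out-of-fold prediction for every sample
    rmsecv: float
    r2_cv: float


@dataclass
class ModelProvenance:
    """What a model expects of its input spectra."""

    n_bands: int
    band_indices: list[int] | None = None  # subset of a parent grid, if any
    preprocess: dict = field(default_factory=dict)

    def check(self, X) -> np.ndarray:
        if isinstance(X, SpectraMatrix):
            if self.preprocess and not X.preprocessed:
                raise ProvenanceError("model expects preprocessed spectra")
            arr = X.data
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[1] != self.n_bands:
            raise ProvenanceError(
                f"model expects {self.n_bands} bands, got {arr.shape[1]}"
            )
        return arr


@dataclass
class PLSModel:
    n_components: int
    estimator: PLSRegression
    provenance: ModelProvenance

    @property
    def coef_(self) -> np.ndarray:
        return self.estimator.coef_.ravel()

    @property
    def intercept_(self) -> float:
        # effective intercept of the affine map X @ coef_ + b: the
        # estimator centers X internally, so evaluate at the origin
        origin = np.zeros((1, self.provenance.n_bands))
        return float(self.estimator.predict(origin).ravel()[0])

    def predict(self, X) -> np.ndarray:
        arr = self.provenance.check(X)
        return self.estimator.predict(arr).ravel()


@dataclass
class LSSVMModel:
    gamma: float
    sigma2: float
    alpha: np.ndarray
    bias: float
    x_train: np.ndarray      # autoscaled training spectra
    x_mean: np.ndarray
    x_scale: np.ndarray
    provenance: ModelProvenance

    def predict(self, X) -> np.ndarray:
        arr = self.provenance.check(X)
        z = (arr - self.x_mean) / self.x_scale
        k = _rbf_kernel(z, self.x_train, self.sigma2)
        return k @ self.alpha + self.bias


def predict(model, X) -> np.ndarray:
    """Predict with provenance checking (band count, preprocessing state)."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

def fit_pls(
    X,
    y: np.ndarray,
    max_components: int = 20,
    folds: int = 10,
    seed: int = 0,
    provenance: ModelProvenance | None = None,
) -> tuple[PLSModel, CVResult]:
    """PLS regression; latent-variable count minimizes ten-fold RMSECV."""
    arr = X.data if isinstance(X, SpectraMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = arr.shape
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to regress")
    fold_ids = _resolve_folds(folds, n, seed)
    max_train = min((fold_ids != f).sum() for f in np.unique(fold_ids))
    cmax = int(min(max_components, max_train - 1, p))
    best = None
    for c in range(1, cmax + 1):
        pred = np.empty(n)
        for f in np.unique(fold_ids):
            val = fold_ids == f
            m = PLSRegression(n_components=c, scale=True)
            m.fit(arr[~val], y[~val])
            pred[val] = m.predict(arr[val]).ravel()
        rmsecv = float(np.sqrt(np.mean((pred - y) ** 2)))
        if best is None or rmsecv < best[0]:
            best = (rmsecv, c, pred.copy())
    rmsecv, n_comp, cv_pred = best
    estimator = PLSRegression(n_components=n_comp, scale=True)
    estimator.fit(arr, y)
    prov = provenance or ModelProvenance(n_bands=p)
    ss_res = np.sum((cv_pred - y) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    cv = CVResult(fold_ids, cv_pred, rmsecv, 1.0 - ss_res / ss_tot)
    return PLSModel(n_comp, estimator, prov), cv


# ---------------------------------------------------------------------------
# LS-SVM
# ---------------------------------------------------------------------------

def _rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-np.maximum(d2, 0.0) / sigma2)


def solve_lssvm_system(K: np.ndarray, y: np.ndarray, gamma: float) -> tuple[np.ndarray, float]:
    """Solve the LS-SVM dual KKT system; returns (alpha, bias).

    The system is [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]; the
    first row enforces sum(alpha) = 0.
    """
    n = len(y)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    sol = np.linalg.solve(A, rhs)
    return sol[1:], float(sol[0])


@dataclass(frozen=True)
class SearchSpec:
    """Two-stage log-grid hyperparameter search (budget <= 1000 evaluations).

    Coarse: ``grid x grid`` points over gamma in [gamma_lo, gamma_hi] and
    sigma2 in [s2_lo_factor, s2_hi_factor] x median squared pairwise
    distance; refine: same-size grid spanning one coarse step around the
    incumbent.
    """

    grid: int = 10
    gamma_lo: float = 1e-2
    gamma_hi: float = 1e6
    s2_lo_factor: float = 1e-2
    s2_hi_factor: float = 1e3

    def __post_init__(self) -> None:
        if 2 * self.grid**2 > 1000:
            raise ValueError("search budget exceeds 1000 evaluations")


def fit_lssvm(
    X,
    y: np.ndarray,
    search: SearchSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    provenance: ModelProvenance | None = None,
) -> tuple[LSSVMModel, CVResult]:
    """LS-SVM (RBF) regression with cross-validated hyperparameter search."""
    arr = X.data if isinstance(X, SpectraMatrix) else np.asarray(X, dtype=float)
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = arr.shape
    search = search or SearchSpec()
    if np.ndim(folds) == 0 and n < 2 * folds:
        folds = max(2, n // 2)
    fold_ids = _resolve_folds(folds, n, seed)

    # Per-fold squared-distance matrices under that fold's training scaling.
    # Centering cancels in pairwise differences, so only the scale matters.
    diffs2 = (arr[:, None, :] - arr[None, :, :]) ** 2  # (n, n, p)
    fold_scale = {}
    for f in np.unique(fold_ids):
        tr = fold_ids != f
        s = arr[tr].std(axis=0, ddof=1)
        s[s == 0] = 1.0
        fold_scale[f] = s
    d2_fold = {f: diffs2 @ (1.0 / fold_scale[f] ** 2) for f in fold_scale}

    s_all = arr.std(axis=0, ddof=1)
    s_all[s_all == 0] = 1.0
    d2_all = diffs2 @ (1.0 / s_all**2)
    d2_med = float(np.median(d2_all[np.triu_indices(n, k=1)]))
    d2_med = d2_med if d2_med > 0 else 1.0

    def cv_rmse(gamma: float, sigma2: float) -> tuple[float, np.ndarray]:
        pred = np.empty(n)
        for f in np.unique(fold_ids):
            val = fold_ids == f
            tr = ~val
            K = np.exp(-d2_fold[f][np.ix_(tr, tr)] / sigma2)
            alpha, b = solve_lssvm_system(K, y[tr], gamma)
            K_val = np.exp(-d2_fold[f][np.ix_(val, tr)] / sigma2)
            pred[val] = K_val @ alpha + b
        return float(np.sqrt(np.mean((pred - y) ** 2))), pred

    def grid_around(g_lo, g_hi, s_lo, s_hi):
        gammas = np.logspace(np.log10(g_lo), np.log10(g_hi), search.grid)
        sigmas = np.logspace(np.log10(s_lo), np.log10(s_hi), search.grid)
        best = None
        for g in gammas:
            for s2 in sigmas:
                rmse, pred = cv_rmse(g, s2)
                if best is None or rmse < best[0]:
                    best = (rmse, g, s2, pred)
        return best, gammas, sigmas

    best, gammas, sigmas = grid_around(
        search.gamma_lo,
        search.gamma_hi,
        search.s2_lo_factor * d2_med,
        search.s2_hi_factor * d2_med,
    )
    g_step = gammas[1] / gammas[0]
    s_step = sigmas[1] / sigmas[0]
    _, g_best, s_best, _ = best
    refined, _, _ = grid_around(
        g_best / g_step, g_best * g_step, s_best / s_step, s_best * s_step
    )
    if refined[0] < best[0]:
        best = refined
    rmsecv, gamma, sigma2, cv_pred = best

    z = (arr - arr.mean(axis=0)) / s_all
    K = np.exp(-d2_all / sigma2)
    alpha, bias = solve_lssvm_system(K, y, gamma)
    prov = provenance or ModelProvenance(n_bands=p)
    ss_res = np.sum((cv_pred - y) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    cv = CVResult(fold_ids, cv_pred, rmsecv, 1.0 - ss_res / ss_tot)
    model = LSSVMModel(
        gamma=float(gamma),
        sigma2=float(sigma2),
        alpha=alpha,
        bias=bias,
        x_train=z,
        x_mean=arr.mean(axis=0),
        x_scale=s_all,
        provenance=prov,
    )
    return model, cv
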