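"""Characteristic-wavelength selection: successive projections (SPA) and
competitive adaptive reweighted sampling (CARS).

Both selectors operate on the calibration spectra only and return a
:class:`SelectionResult` carrying the chosen band indices, the matching
wavelengths, the validation-error trace and method diagnostics, so a
model refit downstream can prove it used no bands outside the selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .regression import make_folds

logger = logging.getLogger("tuberspec")


@dataclass
class SelectionResult:
    method: str                       # "SPA" | "CARS"
    selected_band_indices: list[int]  # sorted, unique
    selected_nm: list[float]
    score_trace: list[float]          # per-candidate-subset validation error
    diagnostics: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected_band_indices)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def reduction_percent(n_selected: int, n_total: int) -> float:
    """Percentage of input variables removed by selection, to one decimal.

    E.g. 23 of 370 bands retained -> 93.8 % reduction.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must lie in [0, n_total]")
    return round(100.0 * (1.0 - n_selected / n_total), 1)


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_chain(X: np.ndarray, start_index: int, k: int) -> list[int]:
    """Successive-projection chain of ``k`` band indices from ``start_index``.

    Starting from the given column, repeatedly appends the band whose
    column has the largest norm after projection onto the orthogonal
    complement of the span of the already-selected columns — the band
    least collinear with the current subset. Deterministic; zero
    (fully collinear) columns are logged and never selected.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start_index < p:
        raise ValueError("start_index out of range")
    if k > min(n, p):
        raise ValueError(f"cannot select {k} bands from {n}x{p} matrix")
    residual = X.copy()
    selected = [start_index]
    for _ in range(k - 1):
        xj = residual[:, selected[-1]].copy()
        nrm2 = xj @ xj
        if nrm2 <= 1e-300:
            logger.warning("spa_chain: zero pivot column %d", selected[-1])
            break
        residual -= np.outer(xj, xj @ residual) / nrm2
        norms = np.einsum("ij,ij->j", residual, residual)
        norms[selected] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-24:
            logger.warning("spa_chain: all remaining columns collinear")
            break
        selected.append(nxt)
    return selected


def _ols_cv_rmse(X: np.ndarray, y: np.ndarray, fold_ids: np.ndarray) -> float:
    """10-fold (or given-fold) RMSE of ordinary least squares with intercept."""
    n = len(y)
    pred = np.empty(n)
    ones = np.ones((n, 1))
    A = np.hstack([ones, X])
    for f in np.unique(fold_ids):
        val = fold_ids == f
        coef, *_ = np.linalg.lstsq(A[~val], y[~val], rcond=None)
        pred[val] = A[val] @ coef
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    n_min: int = 5,
    n_max: int = 30,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """SPA wavelength selection with a cross-validated least-squares scorer.

    For every start band and every subset size in [n_min, n_max], builds
    the projection chain and scores an ordinary-least-squares fit on the
    selected bands by cross-validated RMSE; returns the minimizing subset.
    Ties prefer the smaller subset, then the lower start index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_min > n_max:
        raise ValueError("n_min must not exceed n_max")
    if n <= n_max:
        raise ValueError(f"need more than n_max={n_max} calibration samples")
    fold_ids = make_folds(n, folds=folds, seed=seed)
    best = None  # (rmse, k, start, subset)
    trace = []
    chains = {}
    for start in range(p):
        chain = spa_chain(X, start, min(n_max, n - 1, p))
        chains[start] = chain
        for k in range(n_min, n_max + 1):
            if k > len(chain):
                break
            subset = chain[:k]
            rmse = _ols_cv_rmse(X[:, subset], y, fold_ids)
            trace.append(rmse)
            key = (rmse, k, start)
            if best is None or key < best[0]:
                best = (key, subset)
    (rmse, k, start), subset = best
    return SelectionResult(
        method="SPA",
        selected_band_indices=sorted(int(i) for i in subset),
        selected_nm=[],
        score_trace=trace,
        diagnostics={"best_start": start, "best_k": k, "best_rmse": rmse,
                     "chains": {str(s): list(map(int, c)) for s, c in chains.items()}},
        params={"n_min": n_min, "n_max": n_max, "folds": folds, "seed": seed},
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def edf_counts(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retained-band counts: run 1 keeps all ``p``
    bands, the final run keeps 2.

    r_i = a e^{-k i} with a e^{-k} = 1 and a e^{-k n_runs} = 2/p.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)
    i = np.arange(1, n_runs + 1)
    counts = np.round(a * np.exp(-k * i) * p).astype(int)
    counts[0] = p
    counts[-1] = 2
    return np.maximum(counts, 2)


def _pls_weights(X, y, rng, max_components, inner_folds=5):
    """|regression coefficient| on autoscaled bands, components by inner CV."""
    n, p = X.shape
    cmax = int(min(max_components, n - int(np.ceil(n / inner_folds)) - 1, p))
    cmax = max(cmax, 1)
    fold_ids = make_folds(n, folds=min(inner_folds, n), seed=int(rng.integers(2**31)))
    best_c, best_rmse = 1, np.inf
    for c in range(1, cmax + 1):
        pred = np.empty(n)
        ok = True
        for f in np.unique(fold_ids):
            val = fold_ids == f
            if (~val).sum() <= c:
                ok = False
                break
            m = PLSRegression(n_components=c, scale=True)
            m.fit(X[~val], y[~val])
            pred[val] = m.predict(X[val]).ravel()
        if not ok:
            break
        rmse = np.sqrt(np.mean((pred - y) ** 2))
        if rmse < best_rmse:
            best_c, best_rmse = c, rmse
    model = PLSRegression(n_components=best_c, scale=True)
    model.fit(X, y)
    sx = X.std(axis=0, ddof=1)
    weights = np.abs(model.coef_.ravel() * sx)  # coefficient on standardized X
    return weights, best_c, best_rmse


def _pls_cv_rmse(X, y, n_components, folds, seed):
    n = len(y)
    fold_ids = make_folds(n, folds=min(folds, n), seed=seed)
    pred = np.empty(n)
    for f in np.unique(fold_ids):
        val = fold_ids == f
        c = int(min(n_components, (~val).sum() - 1, X.shape[1]))
        m = PLSRegression(n_components=max(c, 1), scale=True)
        m.fit(X[~val], y[~val])
        pred[val] = m.predict(X[val]).ravel()
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    folds: int = 10,
    seed: int = 0,
    row_fraction: float = 0.8,
    max_components: int = 10,
) -> SelectionResult:
    """CARS wavelength selection.

    Each run draws a Monte-Carlo subset of calibration rows, fits PLS on
    the surviving bands, ranks bands by absolute standardized regression
    coefficient, keeps the count dictated by the exponentially decreasing
    function (EDF), and competes the survivors by adaptive reweighted
    sampling (weighted draws with replacement, deduplicated, topped up by
    coefficient rank so the retained count follows the EDF exactly).
    The run whose subset has the smallest 10-fold RMSECV wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.any(X.std(axis=0) == 0):
        raise ValueError("all bands must have positive dispersion")
    rng = np.random.default_rng(seed)
    counts = edf_counts(p, n_runs)
    survivors = np.arange(p)
    run_subsets, run_sizes, run_rmsecv = [], [], []
    n_rows = max(int(round(row_fraction * n)), 2)
    for i in range(n_runs):
        rows = rng.choice(n, size=n_rows, replace=False)
        weights, n_comp, _ = _pls_weights(
            X[np.ix_(rows, survivors)], y[rows], rng, max_components
        )
        target_count = int(min(counts[i], survivors.size))
        order = np.argsort(weights)[::-1]
        forced = survivors[order[:target_count]]
        # adaptive reweighted sampling among current survivors
        w = weights / weights.sum() if weights.sum() > 0 else None
        draws = rng.choice(survivors, size=target_count, replace=True, p=w)
        picked = np.unique(draws)
        if picked.size < target_count:  # top up by coefficient rank
            ranked = survivors[order]
            extra = ranked[~np.isin(ranked, picked)][: target_count - picked.size]
            picked = np.concatenate([picked, extra])
        survivors = np.sort(picked)
        rmsecv = _pls_cv_rmse(
            X[:, survivors], y, max_components, folds, seed=int(rng.integers(2**31))
        )
        run_subsets.append(survivors.copy())
        run_sizes.append(int(survivors.size))
        run_rmsecv.append(rmsecv)
    best_run = int(np.argmin(run_rmsecv))
    best = run_subsets[best_run]
    return SelectionResult(
        method="CARS",
        selected_band_indices=[int(i) for i in best],
        selected_nm=[],
        score_trace=[float(r) for r in run_rmsecv],
        diagnostics={
            "best_run": best_run,
            "edf_counts": [int(c) for c in counts],
            "run_sizes": run_sizes,
        },
        params={
            "n_runs": n_runs,
            "folds": folds,
            "seed": seed,
            "row_fraction": row_fraction,
            "max_components": max_components,
        },
    )


def attach_wavelengths(result: SelectionResult, wavelengths: np.ndarray) -> SelectionResult:
    """Fill ``selected_nm`` from a wavelength grid (indices must fit)."""
    wl = np.asarray(wavelengths, dtype=float)
    if result.selected_band_indices and max(result.selected_band_indices) >= wl.size:
        raise ValueError("selected indices exceed wavelength grid")
    result.selected_nm = [float(wl[i]) for i in result.selected_band_indices]
    return result
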