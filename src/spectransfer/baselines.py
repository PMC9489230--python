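"""Conventional chemometric regressors: PLS and RBF-kernel SVR.

Both models are tuned by 5-fold cross-validation on the calibration set:
PLS by scanning the latent-variable count, SVR by an exhaustive base-10
grid over the regularization parameter ``c`` (decades −7..7) and kernel
width ``g`` (decades −9..1), the customary search box for spectra.  Folds
are contiguous blocks after a seeded shuffle, so fold assignment is a pure
function of ``(n, folds, seed)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR

from .dataset import SpectraSet
from .evaluation import MetricsReport, metrics

__all__ = ["GridSpec", "PLSModel", "SVRModel", "fit_pls", "fit_svr", "cv_folds"]


@dataclass(frozen=True)
class GridSpec:
    """Base-10 exponent grid for the SVR (c, g) search."""

    c_exponents: tuple[int, ...] = tuple(range(-7, 8))
    g_exponents: tuple[int, ...] = tuple(range(-9, 2))
    base: float = 10.0
    folds: int = 5

    def __post_init__(self) -> None:
        if not self.c_exponents or not self.g_exponents:
            raise ValueError("exponent ranges must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def points(self) -> list[tuple[float, float]]:
        """(c, g) pairs in ascending (c, g) order — the tie-break order."""
        return [(self.base ** ce, self.base ** ge)
                for ce in sorted(self.c_exponents)
                for ge in sorted(self.g_exponents)]


def cv_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous fold blocks of a seeded permutation of ``range(n)``."""
    if n <= folds:
        raise ValueError(f"need more samples ({n}) than folds ({folds})")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def _rmsecv(make_model, x: np.ndarray, y: np.ndarray,
            fold_idx: list[np.ndarray]) -> float:
    """RMSE of out-of-fold predictions, pooled over folds."""
    pred = np.empty_like(y, dtype=float)
    for test in fold_idx:
        train = np.setdiff1d(np.arange(y.size), test)
        model = make_model()
        model.fit(x[train], y[train])
        pred[test] = np.asarray(model.predict(x[test])).ravel()
    return float(np.sqrt(np.mean((pred - y) ** 2)))


class _Fitted:
    kind = ""

    def __init__(self, estimator, input_width: int,
                 cv_report: MetricsReport | None = None):
        self._estimator = estimator
        self.input_width = input_width
        self.cv_report = cv_report

    def predict(self, data: SpectraSet | np.ndarray) -> np.ndarray:
        x = data.reflectance if isinstance(data, SpectraSet) else np.asarray(data)
        x = np.atleast_2d(x)
        if x.shape[0] == 0:
            return np.empty(0)
        if x.shape[1] != self.input_width:
            raise ValueError(
                f"input width {x.shape[1]} != training width {self.input_width}"
            )
        return np.asarray(self._estimator.predict(x)).ravel()


class PLSModel(_Fitted):
    kind = "pls"

    def __init__(self, estimator, input_width, n_components: int,
                 rmsecv_curve: dict[int, float], cv_report=None):
        super().__init__(estimator, input_width, cv_report)
        self.n_components = n_components
        self.rmsecv_curve = rmsecv_curve


class SVRModel(_Fitted):
    kind = "svr"

    def __init__(self, estimator, input_width, c: float, g: float,
                 rmsecv_grid: dict[tuple[float, float], float], cv_report=None):
        super().__init__(estimator, input_width, cv_report)
        self.c = c
        self.g = g
        self.rmsecv_grid = rmsecv_grid


def fit_pls(train: SpectraSet, max_components: int = 20, folds: int = 5,
            seed: int = 0) -> PLSModel:
    """PLS with the latent-variable count minimizing 5-fold RMSECV."""
    if max_components <= 0:
        raise ValueError("max_components must be positive")
    x = train.reflectance
    y = train.reference_value
    limit = min(max_components, x.shape[0] - 1 - x.shape[0] // folds,
                x.shape[1])
    fold_idx = cv_folds(y.size, folds, seed)
    curve: dict[int, float] = {}
    with warnings.catch_warnings():
        # noiseless fixtures exhaust the y residual before max_components
        warnings.filterwarnings("ignore", message="y residual is constant")
        for k in range(1, max(limit, 1) + 1):
            curve[k] = _rmsecv(
                lambda k=k: PLSRegression(n_components=k, scale=False),
                x, y, fold_idx)
        best_k = min(curve, key=lambda k: (curve[k], k))
        final = PLSRegression(n_components=best_k, scale=False).fit(x, y)
        # R²_CV from pooled out-of-fold predictions at the chosen complexity
        pred = np.empty_like(y)
        for test in fold_idx:
            tr = np.setdiff1d(np.arange(y.size), test)
            m = PLSRegression(n_components=best_k, scale=False).fit(x[tr], y[tr])
            pred[test] = np.asarray(m.predict(x[test])).ravel()
    cv_rep = metrics(pred, y, split_name="cross_validation")
    return PLSModel(final, x.shape[1], best_k, curve, cv_rep)


def fit_svr(train: SpectraSet, grid: GridSpec | None = None, seed: int = 0,
            epsilon: float = 0.1) -> SVRModel:
    """RBF SVR with (c, g) selected by exhaustive 5-fold grid search.

    Ties in RMSECV are broken toward the smallest ``c`` then smallest
    ``g`` — the least complex model.
    """
    grid = grid or GridSpec()
    x = train.reflectance
    y = train.reference_value
    fold_idx = cv_folds(y.size, grid.folds, seed)
    scores: dict[tuple[float, float], float] = {}
    best: tuple[float, float] | None = None
    with warnings.catch_warnings():
        # extreme-C grid corners legitimately hit the iteration cap
        warnings.simplefilter("ignore", ConvergenceWarning)
        for c, g in grid.points():
            score = _rmsecv(
                lambda c=c, g=g: SVR(kernel="rbf", C=c, gamma=g,
                                     epsilon=epsilon, cache_size=200,
                                     max_iter=500_000),
                x, y, fold_idx)
            scores[(c, g)] = score
            if best is None or score < scores[best]:
                best = (c, g)
        c, g = best
        final = SVR(kernel="rbf", C=c, gamma=g, epsilon=epsilon,
                    cache_size=200, max_iter=500_000).fit(x, y)
        pred = np.empty_like(y)
        for test in fold_idx:
            tr = np.setdiff1d(np.arange(y.size), test)
            m = SVR(kernel="rbf", C=c, gamma=g, epsilon=epsilon,
                    max_iter=500_000).fit(x[tr], y[tr])
            pred[test] = np.asarray(m.predict(x[test])).ravel()
    cv_rep = metrics(pred, y, split_name="cross_validation")
    return SVRModel(final, x.shape[1], c, g, scores, cv_rep)
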