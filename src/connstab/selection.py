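"""Two-stage feature selection: t-test screen, then CV-LASSO stability selection.

Stage 1 keeps the edges whose two-sided pooled-variance t-test p-value on
the training subjects falls below a threshold ``p0``.  Stage 2 splits the
training subjects into ``k_inner`` groups; leaving out each group in turn,
a LASSO (squared-error loss on the 0/1 labels, i.e. a linear-probability
fit) is tuned by an internal cross-validated MSE curve with the one-
standard-error rule and refit, yielding ``k_inner`` sparse feature sets.
Edges appearing in at least ``n_occurrence`` of those sets survive.

Features are standardized (mean 0, SD 1) on the fitting subjects inside
every LASSO fit; the penalty grid is 100 log-spaced values from
``lambda_max`` down to ``1e-3 * lambda_max``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "LassoFit",
    "SelectionState",
    "ttest_screen",
    "two_sample_t",
    "fit_lasso",
    "lambda_grid",
    "one_se_lambda",
    "lasso_cv_fit",
    "cv_lasso_select",
    "select_by_occurrence",
]


@dataclass
class PipelineParams:
    """Tunables of the discriminative-edge pipeline.

    The grid-searched triple is (``p0``, ``n_occurrence``, ``svm_cost``);
    the remaining fields fix the cross-validation layout and the internal
    LASSO path.
    """

    p0: float = 0.05
    n_occurrence: int = 5
    svm_cost: float = 1.0
    k_outer: int = 10
    k_inner: int = 10
    repeats: int = 100
    n_permutations: int = 1000
    seed: int = 0
    # internal LASSO-path settings (the study text leaves these open)
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    k_lambda: int = 5
    stratified: bool = True
    fisher_z: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must lie in (0, 1]")
        if not 1 <= self.n_occurrence <= self.k_inner:
            raise ValueError("n_occurrence must lie in 1..k_inner")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")
        for name in ("k_outer", "k_inner", "k_lambda"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.repeats < 1 or self.n_permutations < 1:
            raise ValueError("repeats and n_permutations must be >= 1")
        if self.n_lambdas < 2 or not 0 < self.lambda_min_ratio < 1:
            raise ValueError("invalid lambda grid settings")


@dataclass
class LassoFit:
    """One tuned LASSO fit: the penalty path, its CV curve and the 1SE choice."""

    lambda_grid: np.ndarray  # descending
    coef_path: np.ndarray  # (n_features, n_lambdas), full-fitting-set path
    cv_mse: np.ndarray
    cv_mse_se: np.ndarray
    lambda_1se: float
    coef: np.ndarray  # coefficients at lambda_1se

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.coef != 0.0)


@dataclass
class SelectionState:
    """Audit record of one training fold's two-stage selection."""

    screened_edges: np.ndarray
    inner_sets: list[np.ndarray] = field(default_factory=list)
    inner_occurrence: np.ndarray | None = None
    lasso_features: np.ndarray | None = None


# ---------------------------------------------------------------------------
# stage 1: univariate screen


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sided t statistics and p-values, columnwise.

    Zero pooled variance yields ``t = 0, p = 1`` with a logged warning
    rather than NaN.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    n0, n1 = a.shape[0], b.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 observations per group")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    df = n0 + n1 - 2
    pooled = ((n0 - 1) * va + (n1 - 1) * vb) / df
    degenerate = pooled == 0
    if np.any(degenerate):
        logger.warning(
            "%d feature(s) with zero pooled variance: p set to 1", degenerate.sum()
        )
    se = np.sqrt(np.where(degenerate, 1.0, pooled) * (1.0 / n0 + 1.0 / n1))
    t = np.where(degenerate, 0.0, (a.mean(axis=0) - b.mean(axis=0)) / se)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p


def ttest_screen(
    X: np.ndarray, y: np.ndarray, p0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edges with two-sided pooled t-test p < ``p0`` between the groups.

    ``t`` is signed as group0 − group1 (controls minus patients).  Returns
    (passing indices, t, p).
    """
    y = np.asarray(y, int)
    t, p = two_sample_t(X[y == 0], X[y == 1])
    return np.flatnonzero(p < p0), t, p


# ---------------------------------------------------------------------------
# stage 2: CV-LASSO


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, min_ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced penalty grid from ``lambda_max``.

    ``lambda_max = max |X_std' (y - ybar)| / n`` is the smallest penalty at
    which every coefficient is zero.
    """
    Xs, _, _ = _standardize(np.asarray(X, float))
    yc = np.asarray(y, float) - np.mean(y)
    lmax = float(np.max(np.abs(Xs.T @ yc)) / len(yc)) if len(yc) else 0.0
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def fit_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, standardize: bool = True
) -> tuple[np.ndarray, float]:
    """Minimize ``(1/2n) Σ(y − Xβ − β0)² + λ Σ|β|`` (intercept unpenalized).

    Features are standardized internally by default; the returned ``β``
    applies to the standardized predictors and the prediction is
    ``β0 + X_std β``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xs = _standardize(X)[0] if standardize else X
    if lam == 0:
        design = np.column_stack([np.ones(len(y)), Xs])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return beta[1:], float(beta[0])
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=500_000, tol=1e-12)
    model.fit(Xs, y)
    return model.coef_.copy(), float(model.intercept_)


def one_se_lambda(
    grid: np.ndarray, cv_mse: np.ndarray, cv_mse_se: np.ndarray
) -> float:
    """Largest penalty whose CV-MSE is within one SE of the minimum.

    ``grid`` must be descending; ties at the minimum resolve to the largest
    penalty (maximal sparsity).
    """
    grid = np.asarray(grid, float)
    cv_mse = np.asarray(cv_mse, float)
    cv_mse_se = np.asarray(cv_mse_se, float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if not (grid.shape == cv_mse.shape == cv_mse_se.shape):
        raise ValueError("grid and CV arrays must be aligned")
    if grid.size > 1 and np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly descending")
    best = int(np.argmin(cv_mse))  # first minimum = largest lambda among ties
    threshold = cv_mse[best] + cv_mse_se[best]
    qualifying = np.flatnonzero(cv_mse <= threshold)
    return float(grid[qualifying[0]])


def _path_coefs(X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Coordinate-descent coefficient path on pre-standardized data."""
    with warnings.catch_warnings():
        # residual duality gaps of ~1e-5 at the smallest penalties are far
        # below anything that changes a support decision
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(X, y, alphas=grid, max_iter=10_000, tol=1e-7)
    return coefs  # (n_features, n_lambdas), aligned with descending grid


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.asarray(f, int)) for f in folds]


def lasso_cv_fit(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    k: int = 5,
) -> LassoFit:
    """Tune one LASSO by an internal k-fold CV-MSE curve and the 1SE rule.

    The curve averages held-out squared error across ``k`` internal folds,
    each standardized on its own training part; the final coefficients come
    from the full-data path at ``lambda_1se``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    grid = lambda_grid(X, y, n_lambdas, lambda_min_ratio)
    folds = _kfold_indices(n, min(k, n), rng)
    errs = np.empty((len(folds), grid.size))
    for f, val in enumerate(folds):
        tr = np.setdiff1d(np.arange(n), val)
        Xs, mu, sd = _standardize(X[tr])
        ybar = y[tr].mean()
        coefs = _path_coefs(Xs, y[tr] - ybar, grid)
        pred = ybar + ((X[val] - mu) / sd) @ coefs
        errs[f] = ((pred - y[val, None]) ** 2).mean(axis=0)
    cv_mse = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(len(folds))
    lam = one_se_lambda(grid, cv_mse, cv_se)
    Xs_full, _, _ = _standardize(X)
    coefs_full = _path_coefs(Xs_full, y - y.mean(), grid)
    j = int(np.argmin(np.abs(grid - lam)))
    return LassoFit(grid, coefs_full, cv_mse, cv_se, lam, coefs_full[:, j].copy())


def cv_lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    k_inner: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    k_lambda: int = 5,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Leave-one-group-out LASSO selection over ``k_inner`` inner groups.

    For each held-out group a tuned LASSO is fit on the remaining subjects
    (:func:`lasso_cv_fit`); its nonzero support is that repetition's
    feature set.  Returns the ``k_inner`` sets (column indices into ``X``)
    and the per-column occurrence count in ``0..k_inner``.

    If a fitting set would miss a class entirely, the split falls back to a
    stratified one with a logged warning.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < k_inner:
        raise ValueError(f"need at least k_inner={k_inner} subjects, got {n}")
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k_inner, rng)
    classes = np.unique(y)
    for held in folds:
        fit_mask = np.ones(n, bool)
        fit_mask[held] = False
        if len(np.unique(y[fit_mask])) < len(classes):
            logger.warning("inner split left a class absent; using stratified folds")
            folds = _stratified_folds(y, k_inner, rng)
            break
    inner_sets: list[np.ndarray] = []
    occurrence = np.zeros(p, dtype=int)
    for held in folds:
        fit_mask = np.ones(n, bool)
        fit_mask[held] = False
        fit = lasso_cv_fit(
            X[fit_mask],
            y[fit_mask],
            rng,
            n_lambdas=n_lambdas,
            lambda_min_ratio=lambda_min_ratio,
            k=k_lambda,
        )
        inner_sets.append(fit.support)
        occurrence[fit.support] += 1
    return inner_sets, occurrence


def select_by_occurrence(occurrence: np.ndarray, n_required: int) -> np.ndarray:
    """Columns selected in at least ``n_required`` inner sets, canonical order."""
    occurrence = np.asarray(occurrence, int)
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    return np.flatnonzero(occurrence >= n_required)
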