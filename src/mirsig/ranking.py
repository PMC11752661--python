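"""Ridge-discriminant marker ranking.

The disease discriminant is L2-penalized least squares of the 0/1 disease
label on standardized miRNA expression (a ridge linear-discriminant
direction, not logistic regression; a config flag switches the loss). The
penalty lambda is chosen by stratified k-fold cross-validation over a
descending log-spaced grid; by default the most-regularized lambda within
one standard error of the minimum mean squared validation error is used
(``lambda_rule="min"`` selects the minimizer instead — on block-correlated
designs the CV curve is flat near its minimum and the 1-SE choice gives a
far more stable coefficient ranking). Coefficients are refit on all data at
the chosen lambda, and
the markers with the largest absolute standardized coefficients are
selected. Fold assignment is a function of the seed and the (label,
sample-id)-sorted order only, so permuting the input sample order changes
nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .dataio import DataError


@dataclass
class RidgeConfig:
    n_folds: int = 10
    lambda_grid: np.ndarray = field(default=None)  # descending; None = data-driven
    n_lambdas: int = 100
    seed: int = 0
    k_select: int = 16
    loss: str = "squared"  # or "logistic"
    lambda_rule: str = "1se"  # or "min"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0:
                raise ValueError("lambda_grid must be non-empty")
            if (grid <= 0).any() or not (np.diff(grid) < 0).all():
                raise ValueError("lambda_grid must be positive and sorted descending")
            self.lambda_grid = grid
        if self.loss not in ("squared", "logistic"):
            raise ValueError("loss must be 'squared' or 'logistic'")
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")


@dataclass
class RidgeRanking:
    coefficients: pd.Series  # standardized-predictor scale
    best_lambda: float
    selected: list  # ordered by |coefficient| descending


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise DataError("constant predictor column; cannot standardize")
    return (X - mu) / sd, mu, sd


def _ridge_path(Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Coefficients (p x n_lambda) of min ||yc - Xs b||^2 + lambda ||b||^2
    via SVD of the standardized design."""
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ yc
    shrink = s[:, None] / (s[:, None] ** 2 + lambdas[None, :])
    return Vt.T @ (shrink * uty[:, None])


def _sorted_fold_indices(y: pd.Series, n_folds: int, seed: int):
    """Stratified folds computed on samples sorted by (label, id)."""
    order = np.lexsort((y.index.to_numpy(), y.to_numpy()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(np.zeros(len(y)), y.to_numpy()[order]):
        yield order[tr], order[te]


def ridge_coefficients(X: pd.DataFrame, y: pd.Series, config: RidgeConfig) -> RidgeRanking:
    """Cross-validated ridge discriminant on sample x miRNA expression.

    ``X``: samples in rows, candidate miRNAs in columns; ``y``: 0/1 disease
    score aligned with the rows.
    """
    y = y.loc[X.index]
    if y.nunique() < 2:
        raise DataError("both classes must be present")
    if len(X) < config.n_folds:
        raise DataError("fewer samples than folds")
    A = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)

    if config.loss == "logistic":
        return _logistic_ranking(X, y, config)

    Xs_all, _, _ = _standardize(A)
    if config.lambda_grid is None:
        s1 = np.linalg.svd(Xs_all, compute_uv=False)[0]
        lambdas = np.geomspace(10.0 * s1**2, 1e-4 * s1**2, config.n_lambdas)
    else:
        lambdas = config.lambda_grid

    errs = np.zeros((config.n_folds, lambdas.size))
    for f, (tr, te) in enumerate(_sorted_fold_indices(y, config.n_folds, config.seed)):
        if len(np.unique(yv[tr])) < 2 or len(np.unique(yv[te])) < 2:
            raise DataError("a stratified fold lost a class; reduce n_folds")
        Xtr, mu, sd = _standardize(A[tr])
        ybar = yv[tr].mean()
        B = _ridge_path(Xtr, yv[tr] - ybar, lambdas)
        pred = ((A[te] - mu) / sd) @ B + ybar
        errs[f] = ((pred - yv[te][:, None]) ** 2).mean(axis=0)
    mean_err = errs.mean(axis=0)
    best = int(np.argmin(mean_err))  # argmin takes the first (largest) lambda on ties
    if config.lambda_rule == "1se":
        # most-regularized lambda within one standard error of the minimum:
        # the stable choice for coefficient ranking on correlated designs
        se = errs.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        within = np.flatnonzero(mean_err <= mean_err[best] + se[best])
        best = int(within[0])  # grid is descending, so first = largest lambda
    best_lambda = float(lambdas[best])

    beta = _ridge_path(Xs_all, yv - yv.mean(), np.array([best_lambda]))[:, 0]
    coefficients = pd.Series(beta, index=X.columns, name="coefficient")
    selected = select_top_k(coefficients, config.k_select)
    return RidgeRanking(coefficients=coefficients, best_lambda=best_lambda, selected=selected)


def _logistic_ranking(X: pd.DataFrame, y: pd.Series, config: RidgeConfig) -> RidgeRanking:
    """L2-penalized logistic alternative, CV over the same style of grid."""
    A, _, _ = _standardize(X.to_numpy(dtype=float))
    yv = y.to_numpy(dtype=int)
    lambdas = config.lambda_grid if config.lambda_grid is not None else np.geomspace(1e3, 1e-3, config.n_lambdas)
    accs = np.zeros((config.n_folds, len(lambdas)))
    for f, (tr, te) in enumerate(_sorted_fold_indices(y, config.n_folds, config.seed)):
        for j, lam in enumerate(lambdas):
            clf = LogisticRegression(C=1.0 / lam, max_iter=2000)
            clf.fit(A[tr], yv[tr])
            accs[f, j] = (clf.predict(A[te]) == yv[te]).mean()
    best = int(np.argmax(accs.mean(axis=0)))
    best_lambda = float(lambdas[best])
    clf = LogisticRegression(C=1.0 / best_lambda, max_iter=2000)
    clf.fit(A, yv)
    coefficients = pd.Series(clf.coef_[0], index=X.columns, name="coefficient")
    return RidgeRanking(coefficients, best_lambda, select_top_k(coefficients, config.k_select))


def select_top_k(coefficients: pd.Series, k: int) -> list:
    """The k miRNAs with largest |coefficient|; exact ties break
    lexicographically by miRNA id."""
    if coefficients.empty:
        raise DataError("empty coefficient ranking")
    if k > len(coefficients):
        warnings.warn("k exceeds the number of candidates; returning all", stacklevel=2)
        k = len(coefficients)
    order = sorted(coefficients.index, key=lambda m: (-abs(coefficients[m]), m))
    return order[:k]
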