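"""Hyperparameter tuning by k-fold cross-validation on ensemble MSE.

Defaults follow the method's published protocol: 20 folds with 200 trees
per fit.  The grid brackets the hyperparameters a regional-health analysis
of this kind ends up with (minimum node size a few dozen, a handful of
split features, alpha a few percent); ties in CV MSE break toward the
simpler model (larger alpha, then larger m, then smaller j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import StandardizedDataset
from .forest import Hyperparams, build_forest, predict_ensemble

__all__ = ["CVResult", "kfold_split", "cv_mse", "tune", "default_grid"]


def default_grid(p: int) -> list[tuple[int, int, float]]:
    ms = [25, 35, 45, 60]
    js = sorted({j for j in (2, 4, 8, p) if 1 <= j <= p})
    alphas = [0.005, 0.01, 0.02, 0.05, 0.1]
    return [(m, j, a) for m in ms for j in js for a in alphas]


@dataclass
class CVResult:
    grid: list[tuple[int, int, float]]
    cv_mse: np.ndarray
    best: tuple[int, int, float]
    folds: int
    trees_per_fit: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid, columns=["m", "j", "alpha"])
        df["cv_mse"] = self.cv_mse
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def kfold_split(n: int, k: int, rng) -> list[np.ndarray]:
    """Shuffled partition into k folds whose sizes differ by at most 1."""
    if k > n:
        raise ValueError(f"k={k} folds cannot exceed n={n} samples")
    if k < 2:
        raise ValueError("need at least 2 folds")
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, StandardizedDataset):
        return data.X, data.y
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def cv_mse(
    data,
    hyperparams: Hyperparams,
    k: int = 20,
    trees: int = 200,
    seed: int = 0,
    n_jobs: int = 1,
) -> float:
    """Mean over folds of the held-out MSE of the ensemble prediction."""
    X, y = _as_xy(data)
    n = X.shape[0]
    folds = kfold_split(n, k, np.random.default_rng(seed))
    hp = Hyperparams(
        m=hyperparams.m,
        j=hyperparams.j,
        alpha=hyperparams.alpha,
        T=trees,
        weighted_split_mse=hyperparams.weighted_split_mse,
    )
    for fold in folds:
        if n - fold.size < 2 * hp.m:
            raise ValueError(
                f"training fold of size {n - fold.size} is too small for m={hp.m}; "
                "reduce m or the number of folds"
            )
    fold_mse = []
    for fi, fold in enumerate(folds):
        train = np.setdiff1d(np.arange(n), fold)
        forest = build_forest((X[train], y[train]), hp, seed=seed * 100003 + fi, n_jobs=n_jobs)
        pred = predict_ensemble(forest, X[fold])
        fold_mse.append(float(np.mean((y[fold] - pred) ** 2)))
    return float(np.mean(fold_mse))


def tune(
    data,
    grid: list[tuple[int, int, float]] | None = None,
    k: int = 20,
    trees: int = 200,
    seed: int = 0,
    n_jobs: int = 1,
) -> CVResult:
    """Evaluate cv_mse on every (m, j, alpha) triple with a common seed."""
    X, _ = _as_xy(data)
    if grid is None:
        grid = default_grid(X.shape[1])
    if not grid:
        raise ValueError("empty hyperparameter grid")
    scores = np.empty(len(grid))
    for i, (m, j, alpha) in enumerate(grid):
        try:
            scores[i] = cv_mse(data, Hyperparams(m=m, j=j, alpha=alpha), k, trees, seed, n_jobs)
        except ValueError as exc:
            warnings.warn(f"grid point (m={m}, j={j}, alpha={alpha}) failed: {exc}")
            scores[i] = np.inf
    if not np.isfinite(scores).any():
        raise ValueError("every grid point failed cross-validation")
    best_score = scores.min()
    # ties toward simpler models: larger alpha, larger m, smaller j
    tied = [grid[i] for i in np.nonzero(scores <= best_score)[0]]
    best = max(tied, key=lambda t: (t[2], t[0], -t[1]))
    return CVResult(grid=list(grid), cv_mse=scores, best=best, folds=k, trees_per_fit=trees)
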