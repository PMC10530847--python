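"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: child
MSEs come from pseudoinverse fits on materialized subsets, and the split
search is a plain double loop over evaluate-style refits, so agreement
with the package's prefix-Gram sweep is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sylvanreg.data_io import StandardizedDataset

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def pinv_fit(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Independent least-squares: coefficients via pseudoinverse, MSE = RSS/n."""
    coef = np.linalg.pinv(design) @ y
    rss = float(np.sum((y - design @ coef) ** 2))
    return coef, rss / design.shape[0]


def exhaustive_best_split(X, y, features, m, alpha, root_mse, parent_mse=None):
    """Plain double-loop split search with the stated tie-break.

    Iterates features ascending and thresholds ascending, refitting both
    children from scratch for every candidate; a later candidate replaces
    the incumbent only when its child-MSE sum is smaller by more than 1e-12.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    D = np.hstack([np.ones((n, 1)), X])
    if parent_mse is None:
        _, parent_mse = pinv_fit(D, y)
    best = None
    best_sum = np.inf
    for f in sorted(set(int(v) for v in features)):
        u = np.unique(X[:, f])
        for t in (u[:-1] + u[1:]) / 2.0:
            mask = X[:, f] <= t
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < m or nr < m:
                continue
            Dl, Dr = D[mask], D[~mask]
            if np.linalg.matrix_rank(Dl) < p + 1 or np.linalg.matrix_rank(Dr) < p + 1:
                continue
            _, ml = pinv_fit(Dl, y[mask])
            _, mr = pinv_fit(Dr, y[~mask])
            s = ml + mr
            if parent_mse - s > alpha * root_mse and s < best_sum - 1e-12:
                best_sum = s
                best = (f, float(t))
    return best


def make_standardized(X: np.ndarray, y: np.ndarray, names=None) -> StandardizedDataset:
    """Z-score arrays into a StandardizedDataset without touching data_io."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    mx, sx = X.mean(axis=0), X.std(axis=0, ddof=1)
    my, sy = y.mean(), y.std(ddof=1)
    return StandardizedDataset(
        X=(X - mx) / sx,
        y=(y - my) / sy,
        means=np.concatenate([[my], mx]),
        sds=np.concatenate([[sy], sx]),
        outcome_name="y",
        predictor_names=names,
        region_ids=[f"R{i:04d}" for i in range(X.shape[0])],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def linear_dataset(rng) -> StandardizedDataset:
    """n=120, p=3, exactly standardized, moderate noise, fixed seed."""
    X = rng.standard_normal((120, 3))
    y = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.25 * rng.standard_normal(120)
    return make_standardized(X, y)
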