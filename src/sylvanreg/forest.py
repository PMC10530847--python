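"""The bagged ensemble of linear-model trees.

Each of the T trees is grown on its own bootstrap sample (size n, drawn
with replacement) with an rng stream derived deterministically from
(seed, tree index), so parallel and sequential builds agree bit-for-bit.
After growth, every original sample — in-bag and out-of-bag alike — is
routed down every tree; its ensemble coefficient vector is the plain mean
of the coefficient vectors of the T leaves it lands in.  Those per-sample
coefficients, plotted against a moderator axis, are the method's window
into coefficient heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data_io import StandardizedDataset
from .tree_builder import SylvanTree, TreeNode, build_tree

__all__ = [
    "Hyperparams",
    "SylvanForest",
    "PerSampleCoefficients",
    "bootstrap_indices",
    "build_forest",
    "assign_leaf",
    "ensemble_coefficients",
    "predict_ensemble",
]


@dataclass(frozen=True)
class Hyperparams:
    """m: minimum node size; j: features tried per split; alpha: required
    fractional MSE reduction (vs the root MSE E_r); T: number of trees.

    ``weighted_split_mse`` switches the split criterion from the plain sum
    of the two child MSEs (the default) to the size-weighted mean."""

    m: int = 45
    j: int = 4
    alpha: float = 0.02
    T: int = 5000
    weighted_split_mse: bool = False

    def validate(self, p: int) -> None:
        if self.m < p + 2:
            raise ValueError(f"m={self.m} must be ≥ p+2={p + 2} so leaf OLS is overdetermined")
        if not (1 <= self.j <= p):
            raise ValueError(f"j={self.j} must be in [1, {p}]")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.T < 1:
            raise ValueError("T must be positive")


@dataclass
class SylvanForest:
    trees: list[SylvanTree]
    bootstrap_indices: list[np.ndarray]
    hyperparams: Hyperparams
    seed: int
    predictor_names: list[str] | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "hyperparams": {
                "m": self.hyperparams.m,
                "j": self.hyperparams.j,
                "alpha": self.hyperparams.alpha,
                "T": self.hyperparams.T,
                "weighted_split_mse": self.hyperparams.weighted_split_mse,
            },
            "predictor_names": self.predictor_names,
            "bootstrap_indices": [idx.tolist() for idx in self.bootstrap_indices],
            "trees": [t.to_dict() for t in self.trees],
        }


@dataclass
class PerSampleCoefficients:
    """n × (p+1) matrix of tree-averaged leaf coefficients, intercept first."""

    beta: np.ndarray
    term_names: list[str]
    region_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.term_names)
        if self.region_ids is not None:
            df.insert(0, "region", self.region_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bootstrap_indices(n: int, rng) -> np.ndarray:
    """n i.i.d. uniform draws from [0, n) — sampling with replacement."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return rng.integers(0, n, size=n)


def _grow_one(X: np.ndarray, y: np.ndarray, hp: Hyperparams, seed: int, t: int):
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(t,)))
    idx = bootstrap_indices(X.shape[0], rng)
    tree = build_tree(X[idx], y[idx], hp.m, hp.j, hp.alpha, rng, weighted=hp.weighted_split_mse)
    return idx, tree


def build_forest(
    data: StandardizedDataset | tuple[np.ndarray, np.ndarray],
    hyperparams: Hyperparams,
    seed: int,
    n_jobs: int = 1,
    predictor_names: list[str] | None = None,
) -> SylvanForest:
    """Grow T trees, each on its own bootstrap sample.

    ``data`` is either a :class:`StandardizedDataset` or a plain ``(X, y)``
    pair.  Results are identical for any ``n_jobs`` because every tree's
    randomness comes only from (seed, tree index).
    """
    if isinstance(data, StandardizedDataset):
        X, y = data.X, data.y
        predictor_names = predictor_names or data.predictor_names
    else:
        X, y = data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    hyperparams.validate(X.shape[1])

    if n_jobs == 1:
        grown = [_grow_one(X, y, hyperparams, seed, t) for t in range(hyperparams.T)]
    else:
        grown = Parallel(n_jobs=n_jobs)(
            delayed(_grow_one)(X, y, hyperparams, seed, t) for t in range(hyperparams.T)
        )
    return SylvanForest(
        trees=[g[1] for g in grown],
        bootstrap_indices=[g[0] for g in grown],
        hyperparams=hyperparams,
        seed=seed,
        predictor_names=predictor_names,
    )


def assign_leaf(tree: SylvanTree, x: np.ndarray) -> TreeNode:
    """Follow split rules from the root (value ≤ threshold goes left)."""
    node = tree.root
    while not node.is_leaf:
        node = node.left if x[node.split.feature] <= node.split.threshold else node.right
    return node


def _leaf_coef_matrix(tree: SylvanTree, X: np.ndarray) -> np.ndarray:
    """Leaf coefficient vector for every row of X, vectorized descent."""
    n = X.shape[0]
    out = np.empty((n, tree.root.fit.coefficients.size))
    stack = [(tree.root, np.arange(n))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            out[idx] = node.fit.coefficients
        else:
            mask = X[idx, node.split.feature] <= node.split.threshold
            stack.append((node.right, idx[~mask]))
            stack.append((node.left, idx[mask]))
    return out


def ensemble_coefficients(
    forest: SylvanForest,
    data: StandardizedDataset | np.ndarray,
    oob_only: bool = False,
) -> PerSampleCoefficients:
    """Route every sample through every tree and average leaf coefficients.

    With ``oob_only`` a sample averages only over trees whose bootstrap
    sample did not contain it (rows in every bag fall back to all trees).
    """
    if isinstance(data, StandardizedDataset):
        X = data.X
        names = data.predictor_names
        ids = data.region_ids
    else:
        X = np.asarray(data, dtype=float)
        names = forest.predictor_names or [f"x{i}" for i in range(X.shape[1])]
        ids = None
    n = X.shape[0]
    k = X.shape[1] + 1

    total = np.zeros((n, k))
    count = np.zeros(n) if oob_only else None
    for tree, bag in zip(forest.trees, forest.bootstrap_indices):
        coefs = _leaf_coef_matrix(tree, X)
        if oob_only:
            in_bag = np.zeros(n, dtype=bool)
            seen = bag[bag < n]
            in_bag[seen] = True
            coefs = np.where(in_bag[:, None], 0.0, coefs)
            count += ~in_bag
            total += coefs
        else:
            total += coefs
    if oob_only:
        never_oob = count == 0
        if never_oob.any():
            # fall back to the all-trees average for rows in every bag
            full = ensemble_coefficients(forest, X, oob_only=False).beta
            count = np.where(never_oob, 1.0, count)
            total[never_oob] = full[never_oob]
        beta = total / count[:, None]
    else:
        beta = total / forest.n_trees

    term_names = ["const."] + list(names)
    return PerSampleCoefficients(beta=beta, term_names=term_names, region_ids=ids)


def predict_ensemble(forest: SylvanForest, X: np.ndarray) -> np.ndarray:
    """Per sample, the mean over trees of the landed leaf's linear prediction."""
    X = np.asarray(X, dtype=float)
    if isinstance(X, np.ndarray) and X.ndim != 2:
        raise ValueError("X must be 2-D")
    total = np.zeros(X.shape[0])
    for tree in forest.trees:
        coefs = _leaf_coef_matrix(tree, X)
        total += coefs[:, 0] + np.einsum("ij,ij->i", coefs[:, 1:], X)
    return total / forest.n_trees
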