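"""Growing one linear-model tree on a bootstrap sample.

Recursive binary splitting where *every node carries a full multiple
linear regression on all p explanatory variables*, regardless of which
features were candidates for splitting.  A candidate split (feature,
threshold) is accepted only when

1. it minimizes the (unweighted) sum of the two child-node regression
   MSEs among all candidates,
2. the error reduction ``parent_mse − (left_mse + right_mse)`` strictly
   exceeds ``alpha`` times the MSE of the tree's own root fit (E_r), and
3. neither child falls below the minimum node size ``m`` (bootstrap
   multiplicity counts).

Growth is iterative and stack-based (depth-first); candidate features are
redrawn at every node.  Split thresholds are midpoints of consecutive
distinct in-node feature values; ties in the child-MSE sum (within 1e-12)
break toward the lowest feature index, then the lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linmodel import LinearFit, add_intercept, fit_ols

__all__ = [
    "SplitRule",
    "TreeNode",
    "SylvanTree",
    "candidate_thresholds",
    "evaluate_split",
    "best_split",
    "build_tree",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SplitRule:
    """Binary split: feature value ≤ threshold goes left, > goes right."""

    feature: int
    threshold: float


@dataclass
class TreeNode:
    fit: LinearFit
    sample_indices: np.ndarray  # positions into the bootstrap arrays
    split: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class SylvanTree:
    root: TreeNode
    root_mse: float  # E_r, reference scale for the alpha condition
    n_features: int

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.append(node.right)
                stack.append(node.left)
        return out

    def to_dict(self) -> dict:
        """JSON-serializable audit document (split rules, coefficients, sizes)."""

        def rec(node: TreeNode) -> dict:
            d = {
                "n": int(node.fit.n_fit),
                "mse": node.fit.mse,
                "coefficients": node.fit.coefficients.tolist(),
            }
            if not node.is_leaf:
                d["split"] = {
                    "feature": node.split.feature,
                    "threshold": node.split.threshold,
                }
                d["left"] = rec(node.left)
                d["right"] = rec(node.right)
            return d

        return {"root_mse": self.root_mse, "n_features": self.n_features, "tree": rec(self.root)}


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct sorted values (CART convention)."""
    u = np.unique(np.asarray(values, dtype=float))
    if u.size < 2:
        return np.empty(0)
    return (u[:-1] + u[1:]) / 2.0


@dataclass(frozen=True)
class SplitEvaluation:
    left_mse: float
    right_mse: float
    feasible: bool


def evaluate_split(node_X: np.ndarray, node_y: np.ndarray, rule: SplitRule, m: int) -> SplitEvaluation:
    """Fit full-variable OLS in each child of ``rule`` and report the MSEs.

    ``feasible`` is False when a child is smaller than ``m`` or a child fit
    is degenerate (rank-deficient design); infeasible splits are flagged,
    never raised.
    """
    node_X = np.asarray(node_X, dtype=float)
    node_y = np.asarray(node_y, dtype=float)
    mask = node_X[:, rule.feature] <= rule.threshold
    nl = int(mask.sum())
    nr = node_X.shape[0] - nl
    if nl == 0 or nr == 0:
        raise ValueError("rule does not partition the node into two non-empty groups")
    left = fit_ols(add_intercept(node_X[mask]), node_y[mask])
    right = fit_ols(add_intercept(node_X[~mask]), node_y[~mask])
    feasible = nl >= m and nr >= m and not left.degenerate and not right.degenerate
    return SplitEvaluation(left.mse, right.mse, feasible)


def _sweep_feature(D: np.ndarray, y: np.ndarray, feature: int, m: int):
    """Child MSEs for every candidate threshold of one feature, by prefix Grams.

    Returns (thresholds, left_mse, right_mse) restricted to size-feasible
    cuts; rank-deficient child Grams are dropped (degenerate ⇒ infeasible).
    Cumulative X'X / X'y sums make the full threshold scan O(n·k²) plus one
    batched normal-equation solve, instead of 2(n−1) independent refits.
    """
    n, k = D.shape
    v = D[:, feature + 1]  # column 0 is the intercept
    order = np.argsort(v, kind="stable")
    Ds, ys, vs = D[order], y[order], v[order]

    cuts = np.nonzero(np.diff(vs) > 0)[0]  # left block = sorted[: cut+1]
    if cuts.size == 0:
        return (np.empty(0),) * 5
    nl = cuts + 1
    nr = n - nl
    ok = (nl >= m) & (nr >= m)
    cuts, nl, nr = cuts[ok], nl[ok], nr[ok]
    if cuts.size == 0:
        return (np.empty(0),) * 5
    thresholds = (vs[cuts] + vs[cuts + 1]) / 2.0

    G = np.cumsum(Ds[:, :, None] * Ds[:, None, :], axis=0)
    a = np.cumsum(Ds * ys[:, None], axis=0)
    cy = np.cumsum(ys * ys)

    GL, aL, cyL = G[cuts], a[cuts], cy[cuts]
    GR, aR, cyR = G[-1] - GL, a[-1] - aL, cy[-1] - cyL

    def solve_rss(Gm, am, cym, sizes):
        try:
            beta = np.linalg.solve(Gm, am[:, :, None])[:, :, 0]
            rss = cym - np.einsum("ij,ij->i", beta, am)
            bad = ~np.isfinite(rss)
        except np.linalg.LinAlgError:
            beta = np.full_like(am, np.nan)
            rss = np.empty(len(am))
            bad = np.zeros(len(am), dtype=bool)
            for i in range(len(am)):
                try:
                    b = np.linalg.solve(Gm[i], am[i])
                    rss[i] = cym[i] - b @ am[i]
                except np.linalg.LinAlgError:
                    rss[i] = np.nan
                    bad[i] = True
            bad |= ~np.isfinite(rss)
        return np.where(bad, np.nan, rss / sizes)

    scale = max(cy[-1] / n, 1e-300)
    with np.errstate(invalid="ignore"):
        mse_l = solve_rss(GL, aL, cyL, nl)
        mse_r = solve_rss(GR, aR, cyR, nr)
        valid = np.isfinite(mse_l) & np.isfinite(mse_r)
        # an extremely ill-conditioned Gram can solve without raising; treat a
        # grossly negative RSS as degenerate rather than report a free lunch
        valid &= (mse_l > -1e-6 * scale) & (mse_r > -1e-6 * scale)
    # what remains negative is roundoff from the cy − β·a form
    return (
        thresholds[valid],
        np.maximum(mse_l[valid], 0.0),
        np.maximum(mse_r[valid], 0.0),
        nl[valid],
        nr[valid],
    )


def best_split(
    node_X: np.ndarray,
    node_y: np.ndarray,
    candidate_features,
    m: int,
    alpha: float,
    root_mse: float,
    parent_mse: float | None = None,
    weighted: bool = False,
) -> SplitRule | None:
    """Exhaustive search over candidate (feature, threshold) pairs.

    Returns the feasible pair minimizing ``left_mse + right_mse`` subject to
    the error-reduction condition, or None when no pair qualifies.  With
    ``weighted`` the aggregate is the size-weighted child MSE
    ``(n_l·left_mse + n_r·right_mse)/n`` instead of the plain sum — a less
    demanding criterion that also splits on mild heterogeneity.
    """
    node_X = np.asarray(node_X, dtype=float)
    node_y = np.asarray(node_y, dtype=float)
    D = add_intercept(node_X)
    if parent_mse is None:
        parent_mse = fit_ols(D, node_y).mse

    best_rule = None
    best_sum = np.inf
    n = node_X.shape[0]
    for f in sorted(int(f) for f in set(candidate_features)):
        thr, mse_l, mse_r, nl, nr = _sweep_feature(D, node_y, f, m)
        if thr.size == 0:
            continue
        sums = (nl * mse_l + nr * mse_r) / n if weighted else mse_l + mse_r
        qualifies = parent_mse - sums > alpha * root_mse
        if not qualifies.any():
            continue
        idx = np.nonzero(qualifies)[0]
        # thresholds ascend within a feature: lowest threshold wins a tie
        smin = sums[idx].min()
        local = idx[np.nonzero(sums[idx] <= smin + _TIE_TOL)[0][0]]
        if smin < best_sum - _TIE_TOL:
            best_sum = smin
            best_rule = SplitRule(f, float(thr[local]))
    return best_rule


def build_tree(
    X_boot: np.ndarray,
    y_boot: np.ndarray,
    m: int,
    j: int,
    alpha: float,
    rng,
    weighted: bool = False,
) -> SylvanTree:
    """Grow one tree on a bootstrap sample, stack-based depth-first.

    At each popped node of size ≥ 2m, ``j`` candidate features are drawn
    uniformly without replacement from all p via ``rng``; if ``best_split``
    returns a rule the children are created (each refit by full-variable
    OLS) and pushed, otherwise the node becomes a leaf.
    """
    X_boot = np.asarray(X_boot, dtype=float)
    y_boot = np.asarray(y_boot, dtype=float)
    n, p = X_boot.shape
    if n < m:
        raise ValueError("bootstrap sample smaller than minimum node size")
    if not (1 <= j <= p):
        raise ValueError("j must be in [1, p]")

    root_fit = fit_ols(add_intercept(X_boot), y_boot)
    root = TreeNode(fit=root_fit, sample_indices=np.arange(n))
    tree = SylvanTree(root=root, root_mse=root_fit.mse, n_features=p)

    stack = [root]
    while stack:
        node = stack.pop()
        idx = node.sample_indices
        if idx.size < 2 * m or node.fit.degenerate:
            continue
        feats = rng.choice(p, size=j, replace=False)
        rule = best_split(
            X_boot[idx], y_boot[idx], feats, m, alpha, tree.root_mse,
            parent_mse=node.fit.mse, weighted=weighted,
        )
        if rule is None:
            continue
        mask = X_boot[idx, rule.feature] <= rule.threshold
        li, ri = idx[mask], idx[~mask]
        node.split = rule
        node.left = TreeNode(fit=fit_ols(add_intercept(X_boot[li]), y_boot[li]), sample_indices=li)
        node.right = TreeNode(fit=fit_ols(add_intercept(X_boot[ri]), y_boot[ri]), sample_indices=ri)
        stack.append(node.right)
        stack.append(node.left)
    return tree
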