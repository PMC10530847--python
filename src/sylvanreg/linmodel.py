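"""Ordinary-least-squares core.

Every tree node carries a multiple linear regression fitted by
:func:`fit_ols`; the final reported models additionally need classical
inference (:func:`ols_inference`).  The node-level mean-squared error
deliberately uses the *node sample count* ``n`` as denominator, not the
unbiased ``n - k``: the split criterion compares MSEs across nodes of
different sizes and treats "mean-squared error" literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["LinearFit", "RegressionReport", "add_intercept", "fit_ols", "ols_inference"]


def add_intercept(X: np.ndarray) -> np.ndarray:
    """Prepend a column of ones to a predictor matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    return np.hstack([np.ones((X.shape[0], 1)), X])


@dataclass(frozen=True)
class LinearFit:
    """A fitted linear model at one tree node.

    Attributes
    ----------
    coefficients:
        Length-k vector, intercept first.
    mse:
        Residual sum of squares divided by the node sample count.
    n_fit:
        Number of samples (with bootstrap multiplicity) the fit used.
    degenerate:
        True when the design was rank-deficient and the coefficients are
        the minimum-norm least-squares solution.  Callers refuse to split
        on degenerate children.
    """

    coefficients: np.ndarray
    mse: float
    n_fit: int
    degenerate: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear prediction for a predictor matrix without intercept column."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.coefficients[0] + X @ self.coefficients[1:]


def fit_ols(design: np.ndarray, y: np.ndarray) -> LinearFit:
    """Least-squares fit of ``y`` on an explicit design matrix.

    ``design`` must already contain its intercept column.  A rank-deficient
    design is solved by minimum-norm least squares and flagged degenerate
    rather than raised, keeping the split search total.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = design.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    if n < k:
        # underdetermined: still solvable by min-norm, always degenerate
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        return LinearFit(coef, rss / n, n, degenerate=True)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    return LinearFit(coef, rss / n, n, degenerate=rank < k)


@dataclass
class RegressionReport:
    """Term-wise inference table: standardized β, SE, p, 95% CI, adjusted R²."""

    terms: list[str]
    std_beta: np.ndarray
    std_error: np.ndarray
    p_value: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    adjusted_r2: float
    r2: float
    n: int
    footnotes: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.terms,
                "std_beta": self.std_beta,
                "std_error": self.std_error,
                "p_value": self.p_value,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_csv(self, path) -> None:
        """Write the table; adjusted R² and notes go in '#' footer comments."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            self.to_frame().to_csv(fh, index=False)
            fh.write(f"# adjusted_r2 = {self.adjusted_r2!r}\n")
            for note in self.footnotes:
                fh.write(f"# {note}\n")

    def beta_of(self, term: str) -> float:
        return float(self.std_beta[self.terms.index(term)])


def ols_inference(design: np.ndarray, y: np.ndarray, term_labels: list[str]) -> RegressionReport:
    """Classical OLS inference on an explicit design matrix.

    Standard errors use the unbiased residual variance RSS/(n−k); p-values
    are two-sided t-tests and the 95% CIs are t-based with n−k degrees of
    freedom.  Adjusted R² = 1 − (1−R²)(n−1)/(n−k).
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = design.shape
    if len(term_labels) != k:
        raise ValueError("one label per design column required")
    if n <= k:
        raise ValueError("saturated model: need n > number of terms")

    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k:
        raise ValueError("design is rank-deficient; drop collinear terms")
    resid = y - design @ coef
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tcrit = stats.t.ppf(0.975, df)

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df

    return RegressionReport(
        terms=list(term_labels),
        std_beta=coef,
        std_error=se,
        p_value=pvals,
        ci_low=coef - tcrit * se,
        ci_high=coef + tcrit * se,
        adjusted_r2=adj_r2,
        r2=r2,
        n=n,
    )
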