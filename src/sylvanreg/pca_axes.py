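"""First principal component of the standardized predictors.

PC1 — the direction of largest variance of the predictor cloud — serves
as the moderator axis against which per-sample coefficients are plotted
and on which the piecewise interaction terms act.  In regional health
data it typically captures an urbanization gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import StandardizedDataset

__all__ = ["PCAResult", "pc1"]


@dataclass
class PCAResult:
    loadings: np.ndarray  # correlation-scaled: eigenvector × sqrt(eigenvalue)
    eigenvector: np.ndarray  # unit-norm leading eigenvector
    scores: np.ndarray  # per-sample PC1 score
    explained_variance_ratio: float
    variable_names: list[str]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.variable_names, "loading": self.loadings})

    def scores_frame(self, region_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"pc1": self.scores})
        if region_ids is not None:
            df.insert(0, "region", list(region_ids))
        return df


def pc1(data: StandardizedDataset | np.ndarray, names=None, sign_anchor: str | None = None) -> PCAResult:
    """Leading eigenpair of the predictor correlation matrix.

    Scores are the projection of the (standardized) predictors on the unit
    eigenvector; loadings are eigenvector × sqrt(leading eigenvalue), i.e.
    the Pearson correlation between each variable and the score.  The sign
    is fixed so the variable with the largest absolute loading loads
    positively, unless ``sign_anchor`` names a variable that must load
    positively instead.
    """
    if isinstance(data, StandardizedDataset):
        X = data.X
        names = names or data.predictor_names
    else:
        X = np.asarray(data, dtype=float)
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")

    corr = (X.T @ X) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = float(eigvals[-1])
    vec = eigvecs[:, -1]

    if sign_anchor is not None:
        if sign_anchor not in names:
            raise ValueError(f"sign anchor {sign_anchor!r} is not a predictor")
        anchor = names.index(sign_anchor)
    else:
        anchor = int(np.argmax(np.abs(vec)))
    if vec[anchor] < 0:
        vec = -vec

    scores = X @ vec
    loadings = vec * np.sqrt(max(lead, 0.0))
    evr = lead / float(eigvals.sum())
    return PCAResult(
        loadings=loadings,
        eigenvector=vec,
        scores=scores,
        explained_variance_ratio=evr,
        variable_names=list(names),
    )
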