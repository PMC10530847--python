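"""Final reported regressions and coefficient-vs-moderator profiles.

Two models are fit on the standardized data: the base model (outcome on
all predictors, no interactions) and the interaction model, which adds
user-chosen centered piecewise interaction columns.  Because every
interaction column vanishes at moderator 0, each variable's overall
coefficient as a function of the moderator — its :class:`BetaProfile` —
equals the base coefficient at 0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import StandardizedDataset
from .linmodel import RegressionReport, add_intercept, ols_inference
from .piecewise import InteractionTerm, build_interaction_columns

__all__ = ["BetaProfile", "fit_base_model", "fit_interaction_model", "beta_profile"]

_PVALUE_CAUTION = (
    "p-values: interaction shapes were chosen exploratorily; nominal p-values "
    "should be interpreted with caution"
)


def _term_labels(data: StandardizedDataset) -> list[str]:
    return ["const."] + list(data.predictor_names)


def fit_base_model(data: StandardizedDataset) -> RegressionReport:
    """OLS of standardized y on intercept + all standardized predictors."""
    return ols_inference(add_intercept(data.X), data.y, _term_labels(data))


def fit_interaction_model(
    data: StandardizedDataset,
    pc1_scores: np.ndarray,
    terms: list[InteractionTerm],
) -> RegressionReport:
    """Base design augmented with the centered interaction columns.

    The moderator never enters as a main effect on its own; it acts only
    through the g(·) shapes (the intercept's modifier is a ``const. ×``
    term the user supplies explicitly).
    """
    if not terms:
        return fit_base_model(data)
    inter = build_interaction_columns(data, pc1_scores, terms)
    design = np.hstack([add_intercept(data.X), inter.to_numpy()])
    labels = _term_labels(data) + list(inter.columns)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        offending = _collinear_labels(design, labels)
        raise ValueError(f"interaction columns collinear with the design: {offending}")
    report = ols_inference(design, data.y, labels)
    report.footnotes.append(_PVALUE_CAUTION)
    return report


def _collinear_labels(design: np.ndarray, labels: list[str]) -> list[str]:
    """Greedy scan for the columns that first break full rank."""
    bad = []
    kept = design[:, :1]
    for jcol in range(1, design.shape[1]):
        cand = np.hstack([kept, design[:, jcol : jcol + 1]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept = cand
        else:
            bad.append(labels[jcol])
    return bad


@dataclass
class BetaProfile:
    """A variable's overall coefficient as a function of the moderator."""

    variable: str
    base_beta: float
    terms: list[InteractionTerm]
    term_betas: list[float]

    def value(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.full(z.shape, self.base_beta)
        for term, beta in zip(self.terms, self.term_betas):
            out = out + beta * term.spec(z)
        return out

    def frame(self, z_grid) -> pd.DataFrame:
        z = np.asarray(z_grid, dtype=float)
        return pd.DataFrame({"variable": self.variable, "z": z, "beta": self.value(z)})


def beta_profile(report: RegressionReport, variable: str, terms: list[InteractionTerm]) -> BetaProfile:
    """base β plus the variable's interaction βs times their shapes."""
    if variable not in report.terms:
        raise ValueError(f"{variable!r} not in the report")
    own = [t for t in terms if t.base == variable]
    return BetaProfile(
        variable=variable,
        base_beta=report.beta_of(variable),
        terms=own,
        term_betas=[report.beta_of(t.label) for t in own],
    )
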