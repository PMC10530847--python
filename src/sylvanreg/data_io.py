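"""Reading region-level tables and z-scoring all variables.

The modelling pipeline works entirely on the standardized scale: the
outcome and every predictor are z-scored (sample sd, denominator n−1), so
all reported coefficients are standardized partial regression coefficients
comparable across variables.  Means and sds are retained so results can be
mapped back to the raw scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RawDataset", "StandardizedDataset", "read_table", "standardize", "unstandardize"]


@dataclass
class RawDataset:
    region_ids: list[str]
    outcome_name: str
    predictor_names: list[str]
    values: np.ndarray  # n × (p+1), outcome first

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return len(self.predictor_names)

    @property
    def y(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def X(self) -> np.ndarray:
        return self.values[:, 1:]


@dataclass
class StandardizedDataset:
    X: np.ndarray  # n × p, each column mean 0 / sd 1
    y: np.ndarray  # n, mean 0 / sd 1
    means: np.ndarray  # p+1, outcome first
    sds: np.ndarray  # p+1, outcome first
    outcome_name: str
    predictor_names: list[str]
    region_ids: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def read_table(
    path,
    outcome_column: str,
    id_column: str,
    predictors: list[str] | None = None,
    log_columns: list[str] | None = None,
) -> RawDataset:
    """Read a CSV of regions × variables.

    All numeric columns other than the id and outcome become predictors
    unless an explicit ``predictors`` list is given.  Rows with any missing
    value are dropped (count logged).  ``log_columns`` applies a natural log
    before anything else, for variables defined as ln-transformed.
    """
    df = pd.read_csv(path)
    for col in (id_column, outcome_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    ids = df[id_column].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate region ids in {path}: {sorted(set(dup))}")

    if predictors is None:
        predictors = [c for c in df.columns if c not in (id_column, outcome_column)]
    missing = [c for c in predictors if c not in df.columns]
    if missing:
        raise ValueError(f"predictor columns not found: {missing}")

    cols = [outcome_column] + list(predictors)
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna() & df[cols].notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {int(r)} column {cols[int(c)]!r} in {path}"
        )

    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with missing values", n_dropped)
    sub = sub.loc[keep]
    ids = ids.loc[keep]

    values = sub.to_numpy(dtype=float)
    if log_columns:
        for col in log_columns:
            if col not in cols:
                raise ValueError(f"log_columns entry {col!r} is not a data column")
            j = cols.index(col)
            if np.any(values[:, j] <= 0):
                raise ValueError(f"column {col!r} has non-positive values; cannot ln-transform")
            values[:, j] = np.log(values[:, j])

    if values.shape[0] < 2:
        raise ValueError("need at least 2 complete rows")
    return RawDataset(
        region_ids=list(ids),
        outcome_name=outcome_column,
        predictor_names=list(predictors),
        values=values,
    )


def standardize(raw: RawDataset) -> StandardizedDataset:
    """Z-score outcome and predictors (sample sd, n−1 denominator)."""
    means = raw.values.mean(axis=0)
    sds = raw.values.std(axis=0, ddof=1)
    zero = np.where(sds == 0)[0]
    if len(zero):
        names = [raw.outcome_name] + raw.predictor_names
        raise ValueError(f"constant column(s): {[names[i] for i in zero]}")
    z = (raw.values - means) / sds
    return StandardizedDataset(
        X=z[:, 1:],
        y=z[:, 0],
        means=means,
        sds=sds,
        outcome_name=raw.outcome_name,
        predictor_names=list(raw.predictor_names),
        region_ids=list(raw.region_ids),
    )


def unstandardize(data: StandardizedDataset) -> RawDataset:
    """Inverse of :func:`standardize`."""
    z = np.column_stack([data.y, data.X])
    values = z * data.sds + data.means
    return RawDataset(
        region_ids=list(data.region_ids),
        outcome_name=data.outcome_name,
        predictor_names=list(data.predictor_names),
        values=values,
    )
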