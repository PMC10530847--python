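"""Centered piecewise-linear moderator functions and interaction columns.

Three shapes of a moderator z — an ascending ramp ``lins``, a descending
ramp ``linz``, and a trapezoid ``trpz`` — each clamped to [0, 1] and then
centered by subtracting the value at z = 0 (or at a user-chosen
``center_at``).  An interaction term is the product of a base variable
(or the constant term) and the centered shape; the centering makes every
interaction column vanish at the moderator's mean, so base coefficients
keep their at-the-mean interpretation.

    lins(z; a, b) = f(z) − f(0),  f(z) = clamp((z − a)/(b − a), 0, 1)
    linz(z; a, b) = f(z) − f(0),  f(z) = clamp((b − z)/(b − a), 0, 1)
    trpz(z; a, b, c, d) = f(z) − f(0),
        f(z) = max(min((z − a)/(b − a), 1, (d − z)/(d − c)), 0)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import StandardizedDataset

__all__ = [
    "PiecewiseSpec",
    "InteractionTerm",
    "lins",
    "linz",
    "trpz",
    "build_interaction_columns",
    "parse_term",
]

KINDS = ("lins", "linz", "trpz")


def _lins_raw(z, a, b):
    return np.clip((np.asarray(z, dtype=float) - a) / (b - a), 0.0, 1.0)


def _linz_raw(z, a, b):
    return np.clip((b - np.asarray(z, dtype=float)) / (b - a), 0.0, 1.0)


def _trpz_raw(z, a, b, c, d):
    z = np.asarray(z, dtype=float)
    return np.maximum(np.minimum(np.minimum((z - a) / (b - a), 1.0), (d - z) / (d - c)), 0.0)


def _check_ramp(a, b):
    if not a < b:
        raise ValueError(f"require a < b, got a={a}, b={b}")


def lins(z, a, b, center_at: float = 0.0):
    """Centered ascending ramp: 0 below a, 1 above b, linear between."""
    _check_ramp(a, b)
    return _lins_raw(z, a, b) - _lins_raw(center_at, a, b)


def linz(z, a, b, center_at: float = 0.0):
    """Centered descending ramp: 1 below a, 0 above b."""
    _check_ramp(a, b)
    return _linz_raw(z, a, b) - _linz_raw(center_at, a, b)


def trpz(z, a, b, c, d, center_at: float = 0.0):
    """Centered trapezoid: rises on [a, b], plateau on [b, c], falls on [c, d].

    b = c is allowed (triangle); a < b and c < d are strict so neither ramp
    divides by zero.
    """
    if not (a < b <= c < d):
        raise ValueError(f"require a < b ≤ c < d, got ({a}, {b}, {c}, {d})")
    return _trpz_raw(z, a, b, c, d) - _trpz_raw(center_at, a, b, c, d)


@dataclass(frozen=True)
class PiecewiseSpec:
    kind: str
    params: tuple[float, ...]
    center_at: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        need = 4 if self.kind == "trpz" else 2
        if len(self.params) != need:
            raise ValueError(f"{self.kind} takes {need} parameters, got {len(self.params)}")
        self(0.0)  # validates parameter ordering

    def __call__(self, z):
        fn = {"lins": lins, "linz": linz, "trpz": trpz}[self.kind]
        return fn(z, *self.params, center_at=self.center_at)

    def param_str(self) -> str:
        return ", ".join(f"{v:g}" for v in self.params)


@dataclass(frozen=True)
class InteractionTerm:
    """base × g(moderator); base "const." means g(moderator) itself."""

    base: str
    spec: PiecewiseSpec
    moderator: str = "PC1"

    @property
    def label(self) -> str:
        return f"{self.base} × {self.spec.kind} ({self.moderator}; {self.spec.param_str()})"


def parse_term(token: str) -> InteractionTerm:
    """Parse ``BASE:kind:p1,p2[,p3,p4][@MODERATOR]``, e.g. ``UE:trpz:-3,-2,1,3``."""
    moderator = "PC1"
    if "@" in token:
        token, moderator = token.rsplit("@", 1)
    parts = token.split(":")
    if len(parts) != 3:
        raise ValueError(f"bad interaction term {token!r}: expected BASE:kind:params")
    base, kind, params_s = parts
    try:
        params = tuple(float(v) for v in params_s.split(","))
    except ValueError as exc:
        raise ValueError(f"bad parameters in {token!r}: {exc}") from None
    return InteractionTerm(base=base, spec=PiecewiseSpec(kind=kind, params=params), moderator=moderator)


def build_interaction_columns(
    data: StandardizedDataset,
    pc1_scores: np.ndarray,
    terms: list[InteractionTerm],
) -> pd.DataFrame:
    """One column per term: base value × centered g(moderator score)."""
    pc1_scores = np.asarray(pc1_scores, dtype=float)
    if pc1_scores.shape[0] != data.n:
        raise ValueError("moderator scores and data disagree on n")
    labels = [t.label for t in terms]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate interaction terms")
    cols = {}
    for term in terms:
        g = term.spec(pc1_scores)
        if term.base == "const.":
            base = np.ones(data.n)
        elif term.base in data.predictor_names:
            base = data.X[:, data.predictor_names.index(term.base)]
        else:
            raise ValueError(f"unknown base variable {term.base!r}")
        cols[term.label] = base * g
    return pd.DataFrame(cols)
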