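"""Coefficient-heterogeneity scatter plots.

One panel per predictor: per-sample ensemble coefficients (Y) against the
moderator score (X), with three overlays — a red dotted line at β = 0, an
orange dashed line at the base-model constant β, and a violet solid line
tracing the interaction model's β-profile.  Every figure gets a CSV
sidecar with the exact numbers plotted; the figures are derived
artifacts, the sidecars are the contract.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .final_model import BetaProfile
from .forest import PerSampleCoefficients
from .linmodel import RegressionReport

__all__ = ["plot_coefficients"]


def plot_coefficients(
    per_sample: PerSampleCoefficients,
    pc1_scores: np.ndarray,
    base_report: RegressionReport | None,
    profiles: dict[str, BetaProfile] | None,
    out_dir,
    grid: bool = False,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Write one panel (or one grid figure) per predictor plus CSV sidecars."""
    pc1_scores = np.asarray(pc1_scores, dtype=float)
    n = per_sample.beta.shape[0]
    if pc1_scores.shape[0] != n:
        raise ValueError("pc1_scores and per-sample coefficients disagree on n")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = profiles or {}

    variables = per_sample.term_names[1:]
    z_grid = np.linspace(pc1_scores.min(), pc1_scores.max(), 200)
    written: list[Path] = []

    def draw(ax, var, col):
        ax.scatter(pc1_scores, per_sample.beta[:, col], s=8, alpha=0.6, color="0.3")
        ax.axhline(0.0, color="red", linestyle=":", linewidth=1)
        if base_report is not None and var in base_report.terms:
            ax.axhline(base_report.beta_of(var), color="orange", linestyle="--", linewidth=1.2)
        if var in profiles:
            ax.plot(z_grid, profiles[var].value(z_grid), color="darkviolet", linewidth=1.5)
        ax.set_xlabel("PC1")
        ax.set_ylabel("std. β")
        ax.set_title(var)

    def sidecar(var, col) -> Path:
        df = pd.DataFrame({"pc1": pc1_scores, "beta": per_sample.beta[:, col]})
        if base_report is not None and var in base_report.terms:
            df["base_beta"] = base_report.beta_of(var)
        if var in profiles:
            prof = profiles[var].value(pc1_scores)
            df["profile_beta"] = prof
        path = out_dir / f"coef_{var}.csv"
        df.to_csv(path, index=False)
        return path

    if grid:
        ncol = int(np.ceil(np.sqrt(len(variables))))
        nrow = int(np.ceil(len(variables) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow), squeeze=False)
        for i, var in enumerate(variables):
            draw(axes[i // ncol][i % ncol], var, i + 1)
            written.append(sidecar(var, i + 1))
        for ax in axes.flat[len(variables) :]:
            ax.set_visible(False)
        fig.tight_layout()
        for fmt in formats:
            path = out_dir / f"coefficients.{fmt}"
            fig.savefig(path)
            written.append(path)
        plt.close(fig)
    else:
        for i, var in enumerate(variables):
            fig, ax = plt.subplots(figsize=(4, 3.2))
            draw(ax, var, i + 1)
            fig.tight_layout()
            for fmt in formats:
                path = out_dir / f"coef_{var}.{fmt}"
                fig.savefig(path)
                written.append(path)
            plt.close(fig)
            written.append(sidecar(var, i + 1))
    return written
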