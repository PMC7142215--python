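"""Emission of model and validation results as plain data tables.

Figures are deliberately emitted as delimited text (scree table, mode-curve
bands, boxplot summaries) rather than rendered images, so downstream checks
can assert on numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import KineticPCA
from .trials import CHANNELS
from .validation import ValidationReport

__all__ = ["scree_table", "mode_curve_table", "write_model_report", "write_validation_report"]


def scree_table(model: KineticPCA) -> pd.DataFrame:
    """Per-component eigenvalue, variance share, and cumulative variance."""
    ratio = model.explained_variance_ratio_
    return pd.DataFrame(
        {
            "component": np.arange(1, model.n_components_ + 1),
            "eigenvalue": model.explained_variance_,
            "variance_pct": 100 * ratio,
            "cumulative_pct": 100 * np.cumsum(ratio),
        }
    )


def mode_curve_table(model: KineticPCA, k: int, n_sd: float = 2.0) -> pd.DataFrame:
    """Long-format mean and +/- band waveforms of mode ``k``."""
    mean, plus, minus = model.mode_curves(k, n_sd)
    n_channels, n_instants = mean.shape
    names = CHANNELS if n_channels == len(CHANNELS) else [f"ch{c}" for c in range(n_channels)]
    rows = []
    for c in range(n_channels):
        for t in range(n_instants):
            rows.append(
                {"mode": k, "channel": names[c], "progress_pct": 100.0 * t / (n_instants - 1),
                 "mean": mean[c, t], "plus": plus[c, t], "minus": minus[c, t]}
            )
    return pd.DataFrame(rows)


def write_model_report(model: KineticPCA, directory: str | Path, n_mode_curves: int = 3) -> None:
    """Write the model file, scree table, and leading mode-curve bands."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.save(directory / "model.json")
    scree_table(model).to_csv(directory / "scree.csv", index=False)
    k_max = min(n_mode_curves, model.n_components_)
    if k_max >= 1:
        curves = pd.concat([mode_curve_table(model, k) for k in range(1, k_max + 1)])
        curves.to_csv(directory / "mode_curves.csv", index=False)


def write_validation_report(report: ValidationReport, directory: str | Path) -> None:
    """Write every validation table plus a machine-readable summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.accuracy.to_csv(directory / "accuracy.csv", index=False)
    report.compactness.to_csv(directory / "compactness.csv", index=False)
    report.generalization.to_csv(directory / "generalization.csv", index=False)
    report.specificity.to_csv(directory / "specificity.csv", index=False)
    report.permutation.to_csv(directory / "permutation.csv", index=False)
    (directory / "summary.json").write_text(
        json.dumps(report.summary(), indent=2), encoding="utf-8"
    )
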