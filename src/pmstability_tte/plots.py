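"""Prediction- and classification-instability plots.

Prediction instability: each individual's true risk (x) against their
risk-scale uncertainty interval (y, drawn as a vertical segment), with the
identity line and two LOWESS curves fitted separately through the upper
and lower bounds to show a 'typical' interval at each risk.

Classification instability: true risk (x) against the probability that the
uncertainty distribution falls on the wrong side of the clinical threshold
(y), peaking at 0.5 where the true risk sits on the threshold.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["prediction_instability_plot", "classification_instability_plot"]

_MIN_SMOOTH = 10


def prediction_instability_plot(
    records: pd.DataFrame,
    path: str | Path,
    span: float = 0.3,
    title: str | None = None,
) -> Path:
    """Save a prediction-instability plot; returns the file path.

    Needs ``risk_true``, ``lower`` and ``upper`` columns.  With fewer than
    10 records the smoother curves are skipped with a warning.
    """
    risk = records["risk_true"].to_numpy(float)
    lower = records["lower"].to_numpy(float)
    upper = records["upper"].to_numpy(float)

    fig, ax = plt.subplots(figsize=(5.2, 5.0))
    ax.vlines(risk, lower, upper, color="0.6", lw=0.6, alpha=0.5, zorder=1)
    ax.plot([0, 1], [0, 1], color="black", lw=1.0, zorder=2)
    if len(records) >= _MIN_SMOOTH:
        for bound, colour in ((lower, "tab:blue"), (upper, "tab:red")):
            sm = lowess(bound, risk, frac=span, return_sorted=True)
            ax.plot(sm[:, 0], np.clip(sm[:, 1], 0, 1), color=colour, lw=1.6, zorder=3)
    else:
        warnings.warn("fewer than 10 records: smoother curves omitted", stacklevel=2)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("true event risk")
    ax.set_ylabel("95% uncertainty interval for risk")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def classification_instability_plot(
    records: pd.DataFrame,
    threshold: float,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Save a classification-instability plot (misclassification
    probability against true risk, vertical line at the threshold)."""
    fig, ax = plt.subplots(figsize=(5.2, 4.2))
    ax.scatter(
        records["risk_true"],
        records["misclassification"],
        s=8,
        color="tab:blue",
        alpha=0.6,
    )
    ax.axvline(threshold, color="black", lw=1.0, ls="--")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 0.55)
    ax.set_xlabel("true event risk")
    ax.set_ylabel("misclassification probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
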