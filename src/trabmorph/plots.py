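"""Cohort plots: parameter and ratio box plots by age category, PCA biplots."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import PCAReport, RATIO_PAIRS, ratio_table
from .synthetic import CATEGORIES, PARAMS, REGIONS

_LABELS = {"bvtv": "BV/TV", "da": "DA", "tb_th": "Tb.Th (mm)",
           "tb_sp": "Tb.Sp (mm)", "tb_n": "Tb.N (1/mm)"}


def _box_by_category(ax, df: pd.DataFrame, col: str) -> None:
    data, ticks = [], []
    for cat in CATEGORIES:
        v = df.loc[df["age_category"] == cat, col].dropna().to_numpy()
        if v.size:
            data.append(v)
            ticks.append(cat)
    if data:
        ax.boxplot(data, tick_labels=ticks)
        ax.tick_params(axis="x", rotation=45, labelsize=7)


def parameter_boxplots(cohort: pd.DataFrame, path: str) -> str:
    """Box-and-whisker plots of the five parameters per region and age
    category (raw values)."""
    fig, axes = plt.subplots(len(PARAMS), len(REGIONS),
                             figsize=(3 * len(REGIONS), 2.2 * len(PARAMS)),
                             squeeze=False)
    for i, p in enumerate(PARAMS):
        for j, r in enumerate(REGIONS):
            ax = axes[i][j]
            _box_by_category(ax, cohort, f"{p}_{r}")
            if i == 0:
                ax.set_title(r, fontsize=9)
            if j == 0:
                ax.set_ylabel(_LABELS[p], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def ratio_boxplots(cohort: pd.DataFrame, path: str,
                   parameter: str = "bvtv") -> str:
    """Inter-region ratio box plots across age categories."""
    ratios = ratio_table(cohort)
    fig, axes = plt.subplots(1, len(RATIO_PAIRS),
                             figsize=(3 * len(RATIO_PAIRS), 2.8),
                             squeeze=False)
    for j, pair in enumerate(RATIO_PAIRS):
        ax = axes[0][j]
        _box_by_category(ax, ratios, f"{parameter}_{pair}")
        ax.axhline(1.0, lw=0.5, color="grey")
        ax.set_title(pair.replace("_", " / "), fontsize=9)
    axes[0][0].set_ylabel(f"{_LABELS[parameter]} ratio", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def pca_biplot(report: PCAReport, cohort: pd.DataFrame, path: str) -> str:
    """Score scatter (coloured by age category) with loading arrows."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    scores = report.scores
    cats = cohort.loc[scores.index, "age_category"]
    cmap = plt.get_cmap("viridis", len(CATEGORIES))
    for i, cat in enumerate(CATEGORIES):
        sel = cats == cat
        if sel.any():
            ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"],
                       s=18, color=cmap(i), label=cat)
    scale = float(np.abs(scores[["PC1", "PC2"]].to_numpy()).max()) * 0.8
    for var in report.loadings.index:
        lx, ly = report.loadings.loc[var, ["PC1", "PC2"]]
        ax.annotate("", xy=(lx * scale, ly * scale), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="0.4", lw=0.8))
        ax.text(lx * scale * 1.07, ly * scale * 1.07, var, fontsize=6,
                color="0.3")
    ax.set_xlabel(f"PC1 ({report.proportion[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({report.proportion[1] * 100:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
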