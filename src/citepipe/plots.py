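"""Diagnostic plots (never a correctness surface): ridgelines, dot plots,
importance profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def ridgeline(
    clr: pd.DataFrame,
    marker: str,
    groups: pd.Series,
    threshold: float | None = None,
    path: str | Path | None = None,
):
    """Stacked per-group density sketches of one marker's CLR values."""
    fig, ax = plt.subplots(figsize=(6, 0.8 * groups.nunique() + 1))
    levels = list(pd.unique(groups.dropna()))
    lo, hi = clr[marker].min(), clr[marker].max()
    xs = np.linspace(lo, hi, 200)
    for i, g in enumerate(levels):
        vals = clr.loc[groups == g, marker].to_numpy()
        if len(vals) < 2:
            continue
        hist, edges = np.histogram(vals, bins=40, range=(lo, hi), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.interp(xs, centers, hist)
        dens = dens / (dens.max() or 1.0) * 0.9
        ax.fill_between(xs, i, i + dens, alpha=0.7)
    if threshold is not None:
        ax.axvline(threshold, color="k", ls="--", lw=1)
    ax.set_yticks(range(len(levels)), levels)
    ax.set_xlabel(f"{marker} (log2 CLR)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def de_dotplot(de_table: pd.DataFrame, path: str | Path | None = None):
    """Dot plot of significant DE rows; dot size log(pct.1/pct.2)."""
    sig = de_table[de_table["significant"]].copy()
    fig, ax = plt.subplots(figsize=(8, max(2, 0.25 * sig["gene"].nunique())))
    if len(sig):
        genes = {g: i for i, g in enumerate(sorted(sig["gene"].unique()))}
        contrasts = {c: i for i, c in enumerate(sorted(sig["contrast"].unique()))}
        size = np.log(np.clip(sig["pct_1"] / np.clip(sig["pct_2"], 1e-3, None), 1e-3, None)) + 1.5
        ax.scatter(
            [contrasts[c] for c in sig["contrast"]],
            [genes[g] for g in sig["gene"]],
            s=40 * np.clip(size, 0.2, None),
            c=sig["avg_log2FC"], cmap="coolwarm",
        )
        ax.set_xticks(list(contrasts.values()), list(contrasts), rotation=45, ha="right")
        ax.set_yticks(list(genes.values()), list(genes))
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def importance_profile(importance: pd.DataFrame, top: int = 50, path: str | Path | None = None):
    """Line-with-dots profile of the top-ranked genes' mean importances."""
    sub = importance.nsmallest(top, "rank")
    fig, ax = plt.subplots(figsize=(6, max(2, 0.2 * len(sub))))
    ax.plot(sub["mean_importance"], range(len(sub)), "-o", ms=4)
    ax.set_yticks(range(len(sub)), sub.index)
    ax.invert_yaxis()
    ax.set_xlabel("mean scaled importance (0-100)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
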