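"""Wilcoxon rank-sum differential expression with fraction/effect statistics.

Tests are run cluster-vs-rest within a major type or group-vs-group within a
cell population, on normalized expression, with Bonferroni correction over
the genes tested per contrast and the significance filter
``adj_p < 0.05 and pct.1 > 0.2``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["wilcoxon_test", "effect_stats", "de_screen"]

ADJ_P_CUTOFF = 0.05
PCT1_CUTOFF = 0.2
_EXACT_MAX_N = 29  # exact enumeration below 30 per side (and no ties)


def wilcoxon_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both sides have < 30 observations and there are no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction. Returns (U statistic of the first sample, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all observations identical: no evidence either way
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(a), len(b)) <= _EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def effect_stats(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """(avg_log2FC, pct.1, pct.2) on normalized expression.

    avg_log2FC = log2(mean(A)+1) - log2(mean(B)+1); pct.i is the fraction of
    cells in group i with a nonzero value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    lfc = float(np.log2(a.mean() + 1.0) - np.log2(b.mean() + 1.0))
    return lfc, float((a > 0).mean()), float((b > 0).mean())


def _one_contrast(
    values: pd.DataFrame, mask_a: np.ndarray, mask_b: np.ndarray, contrast: str
) -> pd.DataFrame:
    x = values.to_numpy()
    rows = []
    m = values.shape[1]
    for j, gene in enumerate(values.columns):
        a, b = x[mask_a, j], x[mask_b, j]
        _, p = wilcoxon_test(a, b)
        lfc, pct1, pct2 = effect_stats(a, b)
        rows.append((gene, contrast, lfc, pct1, pct2, p))
    out = pd.DataFrame(
        rows, columns=["gene", "contrast", "avg_log2FC", "pct_1", "pct_2", "p"]
    )
    out["adj_p"] = np.minimum(out["p"] * m, 1.0)  # Bonferroni over genes per contrast
    out["significant"] = (out["adj_p"] < ADJ_P_CUTOFF) & (out["pct_1"] > PCT1_CUTOFF)
    return out


def de_screen(
    values: pd.DataFrame,
    grouping: pd.Series,
    mode: str = "one_vs_rest",
    group_order: list[str] | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Differential-expression screen over all genes.

    ``one_vs_rest``: each grouping label against all other cells.
    ``pairwise_groups``: consecutive pairs of ``group_order`` (first vs
    second, second vs third, ...), the disease-contrast layout.
    Contrasts with a side below ``min_cells`` cells are skipped with a
    warning. Bonferroni is applied per contrast over the genes tested.
    """
    grouping = grouping.reindex(values.index)
    if grouping.isna().any():
        raise ValueError("grouping labels missing for some cells")
    labels = grouping.to_numpy()
    if mode == "one_vs_rest":
        contrasts = [
            (str(g), labels == g, labels != g, f"{g}_vs_rest")
            for g in pd.unique(labels)
        ]
    elif mode == "pairwise_groups":
        order = group_order or list(pd.unique(labels))
        contrasts = [
            (a, labels == a, labels == b, f"{a}_vs_{b}")
            for a, b in zip(order[:-1], order[1:])
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pieces = []
    for name, mask_a, mask_b, cname in contrasts:
        if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
            logger.warning("contrast %s skipped: a side has < %d cells", cname, min_cells)
            continue
        pieces.append(_one_contrast(values, mask_a, mask_b, cname))
    if not pieces:
        return pd.DataFrame(
            columns=["gene", "contrast", "avg_log2FC", "pct_1", "pct_2", "p", "adj_p", "significant"]
        )
    return pd.concat(pieces, ignore_index=True)
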