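"""Cross-modality association analyses.

Two screens: (1) a filtered Spearman correlation of each antibody with its
corresponding gene(s), per cell type, where cells below the antibody
threshold or with zero gene counts are discarded, pairs surviving on 10 or
fewer cells are deemed insignificant, non-significant coefficients are
reported as zero, and records with |rho| >= 0.25 are selected; (2) an
iterated random-forest importance ranking of genes that discriminate
disease conditions, trained on balanced resamples and rescaled to 0-100 per
iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)

__all__ = ["correlation_screen", "rf_importance"]

MIN_SURVIVING_CELLS = 11  # pairs with 10 cells or fewer are insignificant
P_CUTOFF = 0.05
RHO_SELECT = 0.25


def correlation_screen(
    adt_thresholded: pd.DataFrame,
    rna: pd.DataFrame,
    antibody_gene_map: dict[str, list[str] | str],
    cell_types: pd.Series | None = None,
    min_cells: int = MIN_SURVIVING_CELLS,
) -> pd.DataFrame:
    """Filtered Spearman screen of antibody-gene pairs, per cell type.

    For each (antibody, gene, cell type): keep cells with a positive
    (above-threshold) antibody value and a nonzero gene count; with fewer
    than ``min_cells`` survivors the record is insignificant and its
    reported coefficient is zero; otherwise Spearman rho with its p-value,
    zeroed when p > 0.05. ``selected`` marks |reported_rho| >= 0.25.
    """
    if cell_types is None:
        cell_types = pd.Series("all", index=adt_thresholded.index)
    cell_types = cell_types.reindex(adt_thresholded.index)
    records = []
    for antibody, genes in antibody_gene_map.items():
        if antibody not in adt_thresholded.columns:
            logger.warning("antibody %s not in ADT matrix; skipped", antibody)
            continue
        if isinstance(genes, str):
            genes = [genes]
        for gene in genes:
            if gene not in rna.columns:
                logger.warning("gene %s (antibody %s) not in RNA matrix; skipped", gene, antibody)
                continue
            for ct in pd.unique(cell_types.dropna()):
                in_type = (cell_types == ct).to_numpy()
                a = adt_thresholded[antibody].to_numpy()[in_type]
                g = rna[gene].reindex(adt_thresholded.index).to_numpy()[in_type]
                mask = (a > 0) & (g > 0) & ~np.isnan(g)
                n = int(mask.sum())
                if n < min_cells:
                    records.append((antibody, gene, ct, np.nan, np.nan, n, 0.0, False))
                    continue
                rho, p = stats.spearmanr(a[mask], g[mask])
                reported = float(rho) if p <= P_CUTOFF else 0.0
                records.append(
                    (antibody, gene, ct, float(rho), float(p), n, reported,
                     abs(reported) >= RHO_SELECT)
                )
    return pd.DataFrame(
        records,
        columns=["antibody", "gene", "cell_type", "rho", "p", "n_cells",
                 "reported_rho", "selected"],
    )


def rf_importance(
    rna: pd.DataFrame,
    conditions: pd.Series,
    cells_per_condition: int = 1000,
    iterations: int = 15,
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "impurity",
) -> pd.DataFrame:
    """Iterated random-forest gene importance for discriminating conditions.

    Each iteration trains a seeded random-forest classifier (``n_trees``
    trees) on ``cells_per_condition`` cells resampled from each condition
    (with replacement when a condition is smaller, logged), computes per-gene
    importances (``impurity`` mean decrease or ``permutation`` on the
    training resample) and rescales them so the iteration maximum is 100.
    Returns one row per gene with per-iteration scores, their mean, and the
    rank by mean (1 = most important).
    """
    conditions = conditions.reindex(rna.index).dropna()
    levels = pd.unique(conditions)
    if len(levels) < 2:
        raise ValueError("need >= 2 conditions")
    if importance not in ("impurity", "permutation"):
        raise ValueError(f"importance must be 'impurity' or 'permutation', got {importance!r}")
    x_all = rna.loc[conditions.index]
    rng = np.random.default_rng(seed)
    scores = np.zeros((iterations, rna.shape[1]))
    for it in range(iterations):
        idx = []
        for lvl in levels:
            members = np.flatnonzero((conditions == lvl).to_numpy())
            replace = len(members) < cells_per_condition
            if replace:
                logger.info(
                    "condition %s has %d < %d cells; sampling with replacement",
                    lvl, len(members), cells_per_condition,
                )
            idx.append(rng.choice(members, size=cells_per_condition, replace=replace))
        idx = np.concatenate(idx)
        x = x_all.to_numpy()[idx]
        y = conditions.to_numpy()[idx]
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(x, y)
        if importance == "impurity":
            imp = clf.feature_importances_
        else:
            imp = permutation_importance(
                clf, x, y, n_repeats=3, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
            ).importances_mean
        imp = np.clip(imp, 0.0, None)
        if imp.max() > 0:
            imp = 100.0 * imp / imp.max()
        scores[it] = imp
    table = pd.DataFrame(
        scores.T,
        index=rna.columns,
        columns=[f"iter_{i + 1}" for i in range(iterations)],
    )
    table.index.name = "gene"
    table["mean_importance"] = scores.mean(axis=0)
    table["rank"] = (
        table["mean_importance"].rank(ascending=False, method="first").astype(int)
    )
    return table.sort_values("rank")
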