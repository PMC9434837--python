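"""QC: sample-tag demultiplexing, doublet removal, antibody floor, normalization.

The filtering order is fixed: tag doublets first, then expression doublets,
then the minimum-antibody-molecule floor (128 molecules by default), after
which ADT counts are CLR-normalized on a log2 scale and RNA counts are
normalized per cell to a fixed total (1000 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from citepipe.matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "demux_tags",
    "tag_thresholds_from_mixture",
    "flag_expression_doublets",
    "filter_antibody_floor",
    "clr_normalize",
    "normalize_rna",
    "run_qc",
    "QCResult",
]

DEFAULT_ANTIBODY_FLOOR = 128
DEFAULT_DOUBLET_RATE = 0.075


def demux_tags(tags: CountMatrix, thresholds: dict[str, float]) -> pd.DataFrame:
    """Call each cell singlet/doublet/undetermined from its sample-tag counts.

    A tag is positive iff its count >= its threshold. Exactly one positive
    tag -> singlet carrying that tag; two or more -> doublet; none ->
    undetermined (excluded downstream).
    """
    for t in tags.features:
        if t not in thresholds:
            raise KeyError(f"no demux threshold for tag {t!r}")
    thr = np.array([thresholds[t] for t in tags.features], dtype=float)
    positive = tags.counts >= thr
    n_pos = positive.sum(axis=1)
    call = np.where(n_pos == 1, "singlet", np.where(n_pos >= 2, "doublet", "undetermined"))
    tag = np.full(tags.n_cells, "", dtype=object)
    singlet = n_pos == 1
    tag[singlet] = tags.features.to_numpy()[np.argmax(positive[singlet], axis=1)]
    return pd.DataFrame({"tag_call": call, "tag": tag}, index=tags.cells)


def tag_thresholds_from_mixture(tags: CountMatrix, seed: int = 0) -> dict[str, float]:
    """Per-tag positivity thresholds from a 2-component mixture on log1p counts.

    Reuses the antibody thresholding machinery; the threshold is mapped back
    to the count scale.
    """
    from citepipe.thresholding import fit_mixture_1d, gaussian_intersection

    out: dict[str, float] = {}
    for j, t in enumerate(tags.features):
        logc = np.log1p(tags.counts[:, j].astype(float))
        fit = fit_mixture_1d(logc, seed=seed)
        if fit.converged:
            cut = gaussian_intersection(fit)
        else:  # degenerate tag column: fall back to midpoint of the range
            cut = 0.5 * (logc.min() + logc.max())
            logger.warning("tag %s: mixture did not converge, midpoint fallback", t)
        out[t] = float(np.expm1(cut))
    return out


def flag_expression_doublets(
    adt: CountMatrix,
    rna: CountMatrix,
    expected_rate: float = DEFAULT_DOUBLET_RATE,
    k: int = 25,
    n_components: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Flag likely expression doublets with an artificial-doublet kNN score.

    Artificial doublets are sums of random real-cell pairs. Real and
    artificial cells are embedded together by PCA on normalized ADT+RNA
    features; each real cell is scored by the fraction of artificial
    neighbours among its k nearest, and the top ``expected_rate`` fraction of
    real cells (quota ``floor(n * expected_rate)``, ties broken by cell-id
    order) is flagged.
    """
    if not (0 < expected_rate < 0.5):
        raise ValueError(f"expected_rate must be in (0, 0.5), got {expected_rate}")
    if adt.n_cells < 100:
        raise ValueError(f"need >= 100 cells, got {adt.n_cells}")
    if not adt.cells.equals(rna.cells):
        raise ValueError("ADT and RNA matrices must cover the same cells")
    n = adt.n_cells
    rng = np.random.default_rng(seed)
    pairs = rng.integers(0, n, size=(n, 2))
    art_adt = adt.counts[pairs[:, 0]] + adt.counts[pairs[:, 1]]
    art_rna = rna.counts[pairs[:, 0]] + rna.counts[pairs[:, 1]]

    def _features(a: np.ndarray, r: np.ndarray) -> np.ndarray:
        a = np.log1p(a.astype(float))
        a -= a.mean(axis=1, keepdims=True)
        tot = r.sum(axis=1, keepdims=True).astype(float)
        tot[tot == 0] = 1.0
        r = np.log1p(1000.0 * r / tot)
        return np.hstack([a, r])

    x = np.vstack(
        [_features(adt.counts, rna.counts), _features(art_adt, art_rna)]
    )
    n_comp = min(n_components, x.shape[1], x.shape[0] - 1)
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    idx = idx[:, 1:]  # drop self
    score = (idx >= n).mean(axis=1)

    quota = int(np.floor(n * expected_rate))
    flags = np.zeros(n, dtype=bool)
    if quota > 0:
        order = np.lexsort((np.arange(n), -score))
        flags[order[:quota]] = True
    return pd.Series(flags, index=adt.cells, name="expression_doublet")


def filter_antibody_floor(adt: CountMatrix, floor: int = DEFAULT_ANTIBODY_FLOOR) -> pd.Index:
    """Cells kept iff total antibody molecules >= floor (strictly fewer removed)."""
    totals = adt.counts.sum(axis=1)
    return adt.cells[totals >= floor]


def clr_normalize(adt: CountMatrix) -> pd.DataFrame:
    """Centered log-ratio per marker across cells, on a log2 scale.

    y = (ln(x+1) - mean_cells ln(x+1)) / ln 2. Output is finite everywhere;
    a marker with all-zero counts maps to all zeros (warned).
    """
    logx = np.log1p(adt.counts.astype(float))
    zero_markers = adt.features[(adt.counts == 0).all(axis=0)]
    for m in zero_markers:
        logger.warning("marker %s has all-zero counts; CLR output is constant 0", m)
    clr = (logx - logx.mean(axis=0, keepdims=True)) / np.log(2.0)
    return pd.DataFrame(clr, index=adt.cells, columns=adt.features)


def normalize_rna(rna: CountMatrix, scale: float = 1000.0) -> pd.DataFrame:
    """Scale each cell to a fixed total; zero-total cells are excluded (warned)."""
    totals = rna.counts.sum(axis=1).astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("excluding %d cells with zero total RNA counts", int(zero.sum()))
    counts = rna.counts[~zero]
    out = counts * (scale / totals[~zero][:, None])
    return pd.DataFrame(out, index=rna.cells[~zero], columns=rna.features)


@dataclass
class QCResult:
    cell_table: pd.DataFrame  # tag_call, tag, expression_doublet, total_adt, qc_pass
    adt_clr: pd.DataFrame  # CLR values for qc-passing cells
    rna_norm: pd.DataFrame  # normalized RNA for qc-passing cells
    stage_counts: dict[str, int]  # cells surviving after each stage


def run_qc(
    adt: CountMatrix,
    rna: CountMatrix,
    tags: CountMatrix,
    cell_table: pd.DataFrame,
    tag_thresholds: dict[str, float] | None = None,
    doublet_rate: float = DEFAULT_DOUBLET_RATE,
    floor: int = DEFAULT_ANTIBODY_FLOOR,
    seed: int = 0,
) -> QCResult:
    """Full QC waterfall in the fixed order: tag doublets -> expression
    doublets -> antibody floor; then normalization of the surviving cells."""
    if tag_thresholds is None:
        tag_thresholds = tag_thresholds_from_mixture(tags, seed=seed)
    table = cell_table.copy()
    demux = demux_tags(tags, tag_thresholds)
    table = table.join(demux)
    table["total_adt"] = adt.row_totals()

    singlets = table.index[table["tag_call"] == "singlet"]
    stage_counts = {"input": adt.n_cells, "tag_singlet": len(singlets)}

    expr_flags = flag_expression_doublets(
        adt.subset_cells(singlets),
        rna.subset_cells(singlets),
        expected_rate=doublet_rate,
        seed=seed,
    )
    table["expression_doublet"] = expr_flags.reindex(table.index, fill_value=False)
    not_expr_dbl = singlets[~expr_flags.loc[singlets].to_numpy()]
    stage_counts["expression_singlet"] = len(not_expr_dbl)

    kept_floor = filter_antibody_floor(adt.subset_cells(not_expr_dbl), floor=floor)
    stage_counts["antibody_floor"] = len(kept_floor)

    table["qc_pass"] = table.index.isin(kept_floor)
    adt_clr = clr_normalize(adt.subset_cells(kept_floor))
    rna_norm = normalize_rna(rna.subset_cells(kept_floor))
    if len(rna_norm) < len(kept_floor):
        dropped = kept_floor.difference(rna_norm.index)
        table.loc[dropped, "qc_pass"] = False
        adt_clr = adt_clr.loc[rna_norm.index]
    stage_counts["final"] = int(table["qc_pass"].sum())
    return QCResult(table, adt_clr, rna_norm, stage_counts)
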