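"""End-to-end pipeline driver.

Stage order is fixed: demux -> expression doublets -> antibody floor ->
normalize -> threshold -> gate -> cluster -> statistics. Every stage emits a
provenance record (input/output cells, parameters, seed) and every output
table carries the config hash and seed in ``DataFrame.attrs``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from citepipe import association, clustering, diffexpr, gating, proportions, qc, thresholding
from citepipe.matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineParams:
    floor: int = qc.DEFAULT_ANTIBODY_FLOOR
    doublet_rate: float = qc.DEFAULT_DOUBLET_RATE
    exclude_markers: list[str] = field(default_factory=list)
    resolutions: dict[str, float] = field(default_factory=lambda: dict(clustering.DEFAULT_RESOLUTIONS))
    default_resolution: float = 0.8
    knn: int = 20
    group_order: list[str] | None = None
    antibody_gene_map: dict[str, list[str]] | None = None
    rf_cells_per_condition: int = 1000
    rf_iterations: int = 15
    rf_trees: int = 500
    min_cells_per_type: int = 30
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in vars(self).items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    cell_table: pd.DataFrame
    thresholds: pd.DataFrame
    assignment: pd.DataFrame
    de_clusters: pd.DataFrame
    de_groups: pd.DataFrame
    proportion_table: pd.DataFrame
    proportion_tests: list
    correlations: pd.DataFrame
    importance: dict[str, pd.DataFrame]
    provenance: list[dict[str, Any]]
    adt_thresholded: pd.DataFrame
    rna_norm: pd.DataFrame


def _record(provenance: list, stage: str, n_in: int, n_out: int, **params) -> None:
    provenance.append(
        {"stage": stage, "cells_in": n_in, "cells_out": n_out, **params}
    )
    logger.info("stage %s: %d -> %d cells", stage, n_in, n_out)


def _stamp(frame: pd.DataFrame, cfg_hash: str, seed: int) -> pd.DataFrame:
    frame.attrs["config_hash"] = cfg_hash
    frame.attrs["seed"] = seed
    return frame


def run_pipeline(
    adt: CountMatrix,
    rna: CountMatrix,
    tags: CountMatrix,
    cell_table: pd.DataFrame,
    params: PipelineParams | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    cfg_hash = params.config_hash()
    prov: list[dict[str, Any]] = []

    # --- QC waterfall ---------------------------------------------------
    qc_res = qc.run_qc(
        adt, rna, tags, cell_table,
        doublet_rate=params.doublet_rate, floor=params.floor, seed=params.seed,
    )
    sc = qc_res.stage_counts
    _record(prov, "demux_tags", sc["input"], sc["tag_singlet"])
    _record(prov, "expression_doublets", sc["tag_singlet"], sc["expression_singlet"],
            rate=params.doublet_rate)
    _record(prov, "antibody_floor", sc["expression_singlet"], sc["antibody_floor"],
            floor=params.floor)
    table = qc_res.cell_table

    # --- thresholding ---------------------------------------------------
    clr = qc_res.adt_clr
    marker_set = thresholding.exclude_marker(list(clr.columns), params.exclude_markers)
    clr = clr[marker_set]
    fitted = thresholding.fit_thresholds(clr, seed=params.seed)
    thr_table = thresholding.thresholds_to_frame(fitted)
    adt_thr = thresholding.apply_thresholds(clr, fitted)
    _record(prov, "thresholding", len(clr), len(adt_thr),
            markers=len(marker_set), excluded=list(params.exclude_markers))

    # --- gating ---------------------------------------------------------
    gates = gating.default_gates()
    major = gating.assign_major_types(adt_thr, gates)
    table = table.join(major.rename("major_type"))
    n_assigned = int((major != gating.UNASSIGNED).sum())
    _record(prov, "gating", len(adt_thr), n_assigned)

    # --- clustering per major type --------------------------------------
    pieces = []
    for mt in sorted(major[major != gating.UNASSIGNED].unique()):
        cells = major.index[major == mt]
        if len(cells) < params.min_cells_per_type:
            logger.warning("type %s has only %d cells; not clustered", mt, len(cells))
            continue
        res = params.resolutions.get(mt, params.default_resolution)
        assigned = clustering.cluster_major_type(
            adt_thr.loc[cells], resolution=res, k=params.knn, seed=params.seed,
        )
        assigned.insert(0, "major_type", mt)
        pieces.append(assigned)
    assignment = (
        pd.concat(pieces) if pieces
        else pd.DataFrame(columns=["major_type", "cluster", "resolution", "split_from", "split_rule"])
    )
    _record(prov, "clustering", n_assigned, len(assignment), k=params.knn)

    # --- differential expression ----------------------------------------
    rna_norm = qc_res.rna_norm
    de_cluster_pieces, de_group_pieces = [], []
    group_order = params.group_order or list(pd.unique(table["group"].dropna())) \
        if "group" in table.columns else None
    for mt in pd.unique(assignment["major_type"]) if len(assignment) else []:
        cells = assignment.index[assignment["major_type"] == mt]
        values = rna_norm.loc[cells]
        de_c = diffexpr.de_screen(
            values, assignment.loc[cells, "cluster"], mode="one_vs_rest"
        )
        de_c.insert(0, "major_type", mt)
        de_cluster_pieces.append(de_c)
        if group_order:
            de_g = diffexpr.de_screen(
                values, table.loc[cells, "group"], mode="pairwise_groups",
                group_order=group_order,
            )
            de_g.insert(0, "major_type", mt)
            de_group_pieces.append(de_g)
    de_clusters = pd.concat(de_cluster_pieces, ignore_index=True) if de_cluster_pieces else pd.DataFrame()
    de_groups = pd.concat(de_group_pieces, ignore_index=True) if de_group_pieces else pd.DataFrame()
    _record(prov, "diffexpr", len(assignment), len(assignment),
            n_cluster_rows=len(de_clusters), n_group_rows=len(de_groups))

    # --- proportions ----------------------------------------------------
    prop_table = proportions.proportions_per_participant(assignment, table)
    prop_tests = proportions.run_proportion_tests(prop_table) if "group" in prop_table.columns else []
    _record(prov, "proportions", len(assignment), len(prop_table))

    # --- associations ---------------------------------------------------
    ab_map = params.antibody_gene_map or {
        m: [m] for m in adt_thr.columns if m in rna_norm.columns
    }
    correlations = association.correlation_screen(
        adt_thr.loc[assignment.index] if len(assignment) else adt_thr,
        rna_norm,
        ab_map,
        cell_types=assignment["major_type"] if len(assignment) else None,
    )
    importance: dict[str, pd.DataFrame] = {}
    if group_order:
        for a, b in zip(group_order[:-1], group_order[1:]):
            mask = table["group"].isin([a, b]) & table["qc_pass"]
            cells = table.index[mask].intersection(rna_norm.index)
            importance[f"{a}_vs_{b}"] = association.rf_importance(
                rna_norm.loc[cells], table.loc[cells, "group"],
                cells_per_condition=params.rf_cells_per_condition,
                iterations=params.rf_iterations,
                n_trees=params.rf_trees,
                seed=params.seed,
            )
    _record(prov, "association", len(rna_norm), len(rna_norm),
            n_correlation_rows=len(correlations), n_rf_contrasts=len(importance))

    for frame in (table, thr_table, assignment, de_clusters, de_groups,
                  prop_table, correlations, *importance.values()):
        _stamp(frame, cfg_hash, params.seed)
    for rec in prov:
        rec["config_hash"] = cfg_hash
        rec["seed"] = params.seed

    return PipelineResult(
        cell_table=table,
        thresholds=thr_table,
        assignment=assignment,
        de_clusters=de_clusters,
        de_groups=de_groups,
        proportion_table=prop_table,
        proportion_tests=prop_tests,
        correlations=correlations,
        importance=importance,
        provenance=prov,
        adt_thresholded=adt_thr,
        rna_norm=rna_norm,
    )
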