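"""Readers/writers for count matrices, cohorts and pipeline configuration."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from citepipe.matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "save_cohort", "load_cohort",
           "load_config", "save_config"]


def read_matrix(path: str | Path, feature_class: str) -> CountMatrix:
    """Load a CountMatrix from matrix-market triplet (+ ``<stem>.features.txt``
    and ``<stem>.barcodes.txt`` sidecars) or a dense CSV (cells x features,
    header row of feature ids, first column of cell ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        mat = scipy_io.mmread(path)
        stem = path.with_suffix("")
        features = _read_lines(Path(f"{stem}.features.txt"))
        barcodes = _read_lines(Path(f"{stem}.barcodes.txt"))
        counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        return CountMatrix(pd.Index(barcodes), pd.Index(features), counts, feature_class)
    if path.suffix == ".csv":
        frame = pd.read_csv(path, index_col=0)
        return CountMatrix(frame.index, frame.columns, frame.to_numpy(), feature_class)
    raise ValueError(f"unsupported matrix format: {path.suffix!r} (use .mtx or .csv)")


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar file: {path}")
    return path.read_text().splitlines()


def write_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write matrix-market (.mtx with feature/barcode sidecars) or dense CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".mtx":
        scipy_io.mmwrite(path, sparse.coo_matrix(matrix.counts))
        stem = path.with_suffix("")
        Path(f"{stem}.features.txt").write_text("\n".join(map(str, matrix.features)) + "\n")
        Path(f"{stem}.barcodes.txt").write_text("\n".join(map(str, matrix.cells)) + "\n")
    elif path.suffix == ".csv":
        matrix.to_frame().to_csv(path)
    else:
        raise ValueError(f"unsupported matrix format: {path.suffix!r} (use .mtx or .csv)")


def save_cohort(outdir: str | Path, adt: CountMatrix, rna: CountMatrix,
                tags: CountMatrix, cell_table: pd.DataFrame,
                truth=None, config=None) -> None:
    """Write one cohort: per-class MTX + sidecars, cell table CSV, truth CSV,
    and (when given) the generating config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(adt, outdir / "adt.mtx")
    write_matrix(rna, outdir / "rna.mtx")
    write_matrix(tags, outdir / "tags.mtx")
    cell_table.to_csv(outdir / "cells.csv")
    if config is not None:
        save_config(config.to_dict() if hasattr(config, "to_dict") else config,
                    outdir / "config.yaml")
    if truth is not None:
        truth.cells.to_csv(outdir / "truth_cells.csv")
        from citepipe.synthetic import truth_report

        truth_report(truth).to_csv(outdir / "truth_planted.csv", index=False)


def load_cohort(indir: str | Path):
    indir = Path(indir)
    adt = read_matrix(indir / "adt.mtx", "ADT")
    rna = read_matrix(indir / "rna.mtx", "RNA")
    tags = read_matrix(indir / "tags.mtx", "TAG")
    cell_table = pd.read_csv(indir / "cells.csv", index_col=0)
    return adt, rna, tags, cell_table


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
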