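"""Count-matrix container shared by all feature classes (ADT, RNA, sample tags)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("ADT", "RNA", "TAG")


@dataclass
class CountMatrix:
    """Cells x features matrix of non-negative integer counts.

    Parameters
    ----------
    cells
        Unique cell identifiers (rows).
    features
        Unique feature identifiers (columns).
    counts
        Dense ``(n_cells, n_features)`` array of non-negative integers.
    feature_class
        One of ``"ADT"``, ``"RNA"``, ``"TAG"``.
    """

    cells: pd.Index
    features: pd.Index
    counts: np.ndarray
    feature_class: str = "ADT"

    def __post_init__(self) -> None:
        self.cells = pd.Index(self.cells)
        self.features = pd.Index(self.features)
        self.counts = np.asarray(self.counts)
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}"
            )
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x features)")
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if self.counts.size == 0:
            raise ValueError("empty count matrix")
        if not self.cells.is_unique:
            dup = self.cells[self.cells.duplicated()][0]
            raise ValueError(f"duplicate cell id: {dup!r}")
        if not self.features.is_unique:
            dup = self.features[self.features.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            bad = ~np.isclose(self.counts, rounded)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-integer count at cell {self.cells[i]!r}, "
                    f"feature {self.features[j]!r}: {self.counts[i, j]}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at cell {self.cells[i]!r}, "
                f"feature {self.features[j]!r}: {self.counts[i, j]}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cells, columns=self.features)

    def row_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.cells, name="total")

    def subset_cells(self, keep: pd.Index | list) -> "CountMatrix":
        """Return a new matrix restricted to ``keep`` (order preserved)."""
        keep = pd.Index(keep)
        pos = self.cells.get_indexer(keep)
        if (pos < 0).any():
            missing = keep[pos < 0][0]
            raise KeyError(f"unknown cell id: {missing!r}")
        return CountMatrix(keep, self.features, self.counts[pos], self.feature_class)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, feature_class: str) -> "CountMatrix":
        return cls(frame.index, frame.columns, frame.to_numpy(), feature_class)
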