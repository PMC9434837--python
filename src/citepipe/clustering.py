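"""Antibody-only subclustering of each major cell type.

Cells of one major type are clustered on the thresholded CLR values of the
markers that are non-negative (expressed) in that type: shared-nearest-
neighbour graph from Euclidean kNN, then modularity community detection
(Leiden, RBConfiguration) at a per-type resolution. Transcript features must
never reach the graph builder. Marker-based post-hoc splits refine
individual clusters with recorded provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RESOLUTIONS",
    "SplitRule",
    "build_neighbor_graph",
    "modularity_cluster",
    "cluster_major_type",
    "split_cluster",
    "embed_2d",
    "nonnegative_markers",
]

# per-type community-detection resolutions
DEFAULT_RESOLUTIONS = {
    "B": 0.8,
    "CD4 T": 1.0,
    "CD8 T": 1.3,
    "CM": 0.5,
    "INT": 0.4,
    "NCM": 0.4,
    "NK": 0.3,
}

RNA_FEATURE_CLASSES = {"RNA"}


def build_neighbor_graph(
    features: pd.DataFrame, k: int = 20, feature_class: str = "ADT"
) -> ig.Graph:
    """Shared-nearest-neighbour graph from Euclidean kNN.

    Edge weight between kNN pairs is the Jaccard overlap of their neighbour
    sets (self included, as is conventional). Raises if RNA features are
    passed: clustering consumes antibody features only.
    """
    if feature_class in RNA_FEATURE_CLASSES:
        raise ValueError("clustering must not consume RNA features")
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 cells to build a graph, got {n}")
    if n < k + 1:
        logger.warning("only %d cells; reducing k from %d to %d", n, k, n - 1)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    idx = nn.kneighbors(x, return_distance=False)  # includes self in column 0
    rows = np.repeat(np.arange(n), k + 1)
    adj = sparse.csr_matrix(
        (np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (adj @ adj.T).tocoo()  # |N(i) & N(j)| with self-inclusive sets
    mask = np.asarray(adj[shared.row, shared.col]).ravel() > 0
    src, dst, s = shared.row[mask], shared.col[mask], shared.data[mask]
    keep = src < dst
    src, dst, s = src[keep], dst[keep], s[keep]
    jaccard = s / (2 * (k + 1) - s)
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = jaccard.tolist()
    g.vs["name"] = [str(c) for c in features.index]
    n_comp = len(g.connected_components())
    logger.info("kNN graph: %d cells, %d edges, %d components", n, g.ecount(), n_comp)
    return g


def modularity_cluster(graph: ig.Graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Modularity-based (Leiden RBConfiguration) communities at the given
    resolution; deterministic given seed; labels 1..C by decreasing size."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    order = np.argsort(-np.bincount(raw), kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(1, len(order) + 1)
    return relabel[raw]


def nonnegative_markers(
    thresholded: pd.DataFrame, min_positive_fraction: float = 0.05
) -> list[str]:
    """Markers expressed (positive after thresholding) in at least
    ``min_positive_fraction`` of the cells at hand."""
    frac = (thresholded > 0).mean(axis=0)
    return [m for m in thresholded.columns if frac[m] >= min_positive_fraction]


def cluster_major_type(
    thresholded: pd.DataFrame,
    resolution: float,
    k: int = 20,
    seed: int = 0,
    min_positive_fraction: float = 0.05,
    batch_correct=None,
) -> pd.DataFrame:
    """Cluster one major type's cells on its non-negative markers.

    Features are z-scaled per marker; ``batch_correct`` is an optional hook
    ``f(matrix) -> matrix`` applied before graph building (identity when
    None). Returns a frame with cluster labels and the resolution used.
    """
    markers = nonnegative_markers(thresholded, min_positive_fraction)
    if not markers:
        raise ValueError("no non-negative markers to cluster on")
    x = thresholded[markers].to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    if batch_correct is not None:
        x = np.asarray(batch_correct(x))
    graph = build_neighbor_graph(pd.DataFrame(x, index=thresholded.index), k=k)
    labels = modularity_cluster(graph, resolution, seed=seed)
    return pd.DataFrame(
        {
            "cluster": labels.astype(str),
            "resolution": resolution,
            "split_from": "",
            "split_rule": "",
        },
        index=thresholded.index,
    )


@dataclass(frozen=True)
class SplitRule:
    """Post-hoc split of one cluster on marker positivity patterns.

    ``reference="threshold"`` splits on thresholded positivity (> 0);
    ``reference="median"`` splits at the cluster median of each marker.
    """

    cluster: str
    markers: tuple[str, ...]
    reference: str = "threshold"

    def __post_init__(self) -> None:
        if self.reference not in ("threshold", "median"):
            raise ValueError(f"reference must be 'threshold' or 'median', got {self.reference!r}")


def split_cluster(
    assignment: pd.DataFrame, thresholded: pd.DataFrame, rule: SplitRule
) -> pd.DataFrame:
    """Partition one cluster by the rule's marker hi/lo pattern.

    Sublabels are ``<cluster>.<i>`` ordered by decreasing size; a split that
    does not yield at least two non-empty subclusters is rejected (assignment
    returned unchanged, with a warning). Provenance (original cluster, rule)
    is recorded for the moved cells.
    """
    if rule.cluster not in set(assignment["cluster"]):
        raise KeyError(f"cluster {rule.cluster!r} not present in assignment")
    cells = assignment.index[assignment["cluster"] == rule.cluster]
    sub = thresholded.loc[cells, list(rule.markers)]
    if rule.reference == "threshold":
        hi = sub.to_numpy() > 0
    else:
        hi = sub.to_numpy() > sub.median(axis=0).to_numpy()
    patterns = pd.Series(["".join("hi" if h else "lo" for h in row) for row in hi], index=cells)
    counts = patterns.value_counts()
    if len(counts) < 2:
        logger.warning(
            "split of cluster %s on %s rejected: only one non-empty side",
            rule.cluster, "/".join(rule.markers),
        )
        return assignment
    out = assignment.copy()
    rule_str = f"{'/'.join(rule.markers)}({rule.reference})"
    for i, pattern in enumerate(counts.index, start=1):
        members = patterns.index[patterns == pattern]
        out.loc[members, "cluster"] = f"{rule.cluster}.{i}"
        out.loc[members, "split_from"] = rule.cluster
        out.loc[members, "split_rule"] = rule_str
    return out


def embed_2d(features: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """2-D manifold embedding for diagnostics only (never for statistics)."""
    import umap  # imported lazily: slow import, plotting-only dependency

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return reducer.fit_transform(np.asarray(features, dtype=float))
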