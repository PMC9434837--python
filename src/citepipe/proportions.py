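"""Cluster-abundance testing across participant groups.

Per participant, each cluster's share of its parent major type is
transformed to log-odds (with a continuity correction so zero counts stay
finite) and compared across groups by one-way ANOVA followed by Tukey's
multiple comparison test on all group pairs. Group summaries are reported on
the percentage scale for readability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "proportions_per_participant",
    "logodds",
    "logodds_from_counts",
    "anova_tukey",
    "run_proportion_tests",
    "ProportionTestResult",
]


def proportions_per_participant(
    assignment: pd.DataFrame, cell_table: pd.DataFrame
) -> pd.DataFrame:
    """Per (participant, cluster): cluster cells / parent-type cells.

    ``assignment`` needs columns ``major_type`` and ``cluster``;
    ``cell_table`` needs ``participant`` (and ``group`` if present it is
    carried through). Participants with zero parent cells are excluded with
    a warning (they contribute no proportion).
    """
    joined = assignment.join(cell_table[["participant"]], how="inner")
    if "group" in cell_table.columns:
        joined = joined.join(cell_table[["group"]])
    parent = (
        joined.groupby(["participant", "major_type"], observed=True)
        .size()
        .rename("n_parent")
    )
    rows = (
        joined.groupby(["participant", "major_type", "cluster"], observed=True)
        .size()
        .rename("n_cluster")
        .reset_index()
    )
    # every participant x cluster combination within a type, zeros included
    full = []
    for mt, sub in rows.groupby("major_type", observed=True):
        clusters = sorted(sub["cluster"].unique())
        participants = joined["participant"].unique()
        grid = pd.MultiIndex.from_product(
            [participants, [mt], clusters], names=["participant", "major_type", "cluster"]
        )
        full.append(
            sub.set_index(["participant", "major_type", "cluster"])
            .reindex(grid, fill_value=0)
            .reset_index()
        )
    table = pd.concat(full, ignore_index=True)
    table = table.join(
        parent, on=["participant", "major_type"]
    )
    missing = table["n_parent"].isna() | (table["n_parent"] == 0)
    if missing.any():
        dropped = table.loc[missing, "participant"].unique()
        logger.warning(
            "excluding %d participant/type combinations with zero parent cells (%s...)",
            int(missing.sum()), ", ".join(map(str, dropped[:3])),
        )
        table = table[~missing]
    table["n_parent"] = table["n_parent"].astype(int)
    table["proportion"] = table["n_cluster"] / table["n_parent"]
    table["logodds"] = logodds_from_counts(
        table["n_cluster"].to_numpy(), table["n_parent"].to_numpy()
    )
    if "group" in joined.columns:
        group_of = joined.drop_duplicates("participant").set_index("participant")["group"]
        table["group"] = group_of.loc[table["participant"]].to_numpy()
    return table


def logodds_from_counts(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """ln(p'/(1-p')) with continuity-corrected p' = (k + 0.5)/(n + 1).

    Finite for k = 0 and k = n; n = 0 must be excluded upstream.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("parent count n must be > 0")
    p = (k + 0.5) / (n + 1.0)
    return np.log(p / (1.0 - p))


def logodds(p: float, n: int) -> float:
    """Continuity-corrected log-odds of proportion ``p`` out of ``n`` parent cells."""
    return float(logodds_from_counts(np.array([p * n]), np.array([n]))[0])


@dataclass
class ProportionTestResult:
    cluster: str
    group_means: dict[str, float]  # percentage scale
    group_sems: dict[str, float]
    anova_f: float
    anova_p: float
    tukey_p: dict[tuple[str, str], float]
    n_per_group: dict[str, int] = field(default_factory=dict)


def anova_tukey(
    transformed: np.ndarray,
    groups: np.ndarray,
    display_values: np.ndarray | None = None,
    cluster: str = "",
    min_per_group: int = 2,
    compute_tukey: bool = True,
) -> ProportionTestResult:
    """One-way ANOVA + Tukey HSD on transformed (log-odds) values.

    Groups with fewer than ``min_per_group`` observations are dropped with a
    warning. ``display_values`` (e.g., proportions) feed the reported group
    means/SEMs; they default to the transformed values.
    ``compute_tukey=False`` skips the post-hoc test (it dominates runtime in
    large simulation studies that only use the ANOVA p-value).
    """
    transformed = np.asarray(transformed, dtype=float)
    groups = np.asarray(groups)
    if display_values is None:
        display_values = transformed
    display_values = np.asarray(display_values, dtype=float)
    keep_labels = []
    for g in pd.unique(groups):
        if (groups == g).sum() >= min_per_group:
            keep_labels.append(g)
        else:
            logger.warning("group %s dropped: fewer than %d participants", g, min_per_group)
    if len(keep_labels) < 2:
        raise ValueError("need >= 2 groups with enough participants")
    samples = [transformed[groups == g] for g in keep_labels]
    disp = [display_values[groups == g] for g in keep_labels]
    if np.ptp(np.concatenate(samples)) == 0:  # all values identical
        f_stat, p = 0.0, 1.0
        tukey = {
            (a, b): 1.0 for a, b in combinations(keep_labels, 2)
        }
    else:
        f_stat, p = stats.f_oneway(*samples)
        if compute_tukey:
            res = stats.tukey_hsd(*samples)
            tukey = {
                (keep_labels[i], keep_labels[j]): float(res.pvalue[i, j])
                for i, j in combinations(range(len(keep_labels)), 2)
            }
        else:
            tukey = {}
    return ProportionTestResult(
        cluster=cluster,
        group_means={g: 100.0 * float(np.mean(d)) for g, d in zip(keep_labels, disp)},
        group_sems={
            g: 100.0 * float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
            for g, d in zip(keep_labels, disp)
        },
        anova_f=float(f_stat),
        anova_p=float(p),
        tukey_p=tukey,
        n_per_group={g: int((groups == g).sum()) for g in keep_labels},
    )


def run_proportion_tests(prop_table: pd.DataFrame) -> list[ProportionTestResult]:
    """Run the ANOVA/Tukey test for every (major type, cluster) in a
    proportion table produced by :func:`proportions_per_participant`."""
    if "group" not in prop_table.columns:
        raise ValueError("proportion table lacks a 'group' column")
    results = []
    for (mt, cl), sub in prop_table.groupby(["major_type", "cluster"], observed=True):
        try:
            results.append(
                anova_tukey(
                    sub["logodds"].to_numpy(),
                    sub["group"].to_numpy(),
                    display_values=sub["proportion"].to_numpy(),
                    cluster=f"{mt}/{cl}",
                )
            )
        except ValueError as err:
            logger.warning("cluster %s/%s skipped: %s", mt, cl, err)
    return results
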