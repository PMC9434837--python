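"""Boolean immunophenotype gating over thresholded antibody values.

A gate is a named conjunction of (marker, +/-) predicates with an optional
parent gate; after thresholding, "+" means a strictly positive value and "-"
means exactly zero. The default gate set reproduces the 8-type PBMC scheme:
B cells, a T parent split into CD4+/CD8+ T cells, a monocyte parent split
into classical/intermediate/nonclassical monocytes, and NK cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GateDefinition",
    "default_gates",
    "gates_from_config",
    "evaluate_gate",
    "assign_major_types",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GateDefinition:
    name: str
    predicates: tuple[tuple[str, str], ...]  # (marker, "+" | "-")
    parent: str | None = None
    terminal: bool = True
    priority: int = 0

    def __post_init__(self) -> None:
        for marker, sign in self.predicates:
            if sign not in ("+", "-"):
                raise ValueError(f"gate {self.name!r}: sign must be '+' or '-', got {sign!r}")


def default_gates() -> list[GateDefinition]:
    """The printed 8-type scheme: terminal gates B, CD4 T, CD8 T, CM, INT,
    NCM, NK plus the non-terminal T and monocyte parents."""
    return [
        GateDefinition("B", (("CD19", "+"), ("CD3", "-"))),
        GateDefinition("T", (("CD19", "-"), ("CD3", "+")), terminal=False),
        GateDefinition("CD4 T", (("CD4", "+"), ("CD8", "-")), parent="T"),
        GateDefinition("CD8 T", (("CD8", "+"), ("CD4", "-")), parent="T"),
        GateDefinition(
            "Monocyte", (("CD19", "-"), ("CD3", "-"), ("CD56", "-")), terminal=False
        ),
        GateDefinition("CM", (("CD14", "+"), ("CD16", "-")), parent="Monocyte"),
        GateDefinition("INT", (("CD14", "+"), ("CD16", "+")), parent="Monocyte"),
        GateDefinition(
            "NCM", (("CD14", "-"), ("CD16", "+"), ("CD56", "-")), parent="Monocyte"
        ),
        # CD20/CD206 negativity kept exactly as printed even where redundant
        GateDefinition(
            "NK",
            (
                ("CD4", "-"), ("CD56", "+"), ("CD14", "-"),
                ("CD20", "-"), ("CD123", "-"), ("CD206", "-"),
            ),
        ),
    ]


def gates_from_config(entries: list[dict]) -> list[GateDefinition]:
    """Build a gate set from config entries, e.g.
    ``{"name": "B", "predicates": ["CD19+", "CD3-"], "parent": null}``."""
    gates = []
    for entry in entries:
        predicates = tuple(
            (p[:-1], p[-1]) for p in entry["predicates"]
        )
        gates.append(
            GateDefinition(
                name=entry["name"],
                predicates=predicates,
                parent=entry.get("parent"),
                terminal=entry.get("terminal", True),
                priority=entry.get("priority", 0),
            )
        )
    return gates


def _gate_depth(gate: GateDefinition, by_name: dict[str, GateDefinition]) -> int:
    depth, g = 0, gate
    seen = {gate.name}
    while g.parent is not None:
        if g.parent not in by_name:
            raise KeyError(f"gate {g.name!r}: unknown parent {g.parent!r}")
        g = by_name[g.parent]
        if g.name in seen:
            raise ValueError(f"gate parent chain contains a cycle at {g.name!r}")
        seen.add(g.name)
        depth += 1
    return depth


def _gate_mask(
    gate: GateDefinition,
    profile: pd.DataFrame,
    by_name: dict[str, GateDefinition],
    _seen: frozenset[str] = frozenset(),
) -> np.ndarray:
    if gate.name in _seen:
        raise ValueError(f"gate parent chain contains a cycle at {gate.name!r}")
    mask = np.ones(len(profile), dtype=bool)
    for marker, sign in gate.predicates:
        if marker not in profile.columns:
            raise KeyError(f"gate {gate.name!r}: marker {marker!r} missing from profile")
        col = profile[marker].to_numpy()
        mask &= (col > 0) if sign == "+" else (col == 0)
    if gate.parent is not None:
        if gate.parent not in by_name:
            raise KeyError(f"gate {gate.name!r}: unknown parent {gate.parent!r}")
        mask &= _gate_mask(by_name[gate.parent], profile, by_name, _seen | {gate.name})
    return mask


def evaluate_gate(
    profile: pd.DataFrame | pd.Series,
    gate: GateDefinition,
    gates: list[GateDefinition] | None = None,
) -> np.ndarray | bool:
    """True where every "+" marker is > 0, every "-" marker is 0, and the
    parent gate (if any) is satisfied. Accepts one cell (Series) or many."""
    single = isinstance(profile, pd.Series)
    frame = profile.to_frame().T if single else profile
    by_name = {g.name: g for g in (gates or [])}
    by_name.setdefault(gate.name, gate)
    mask = _gate_mask(gate, frame, by_name)
    return bool(mask[0]) if single else mask


def assign_major_types(
    thresholded: pd.DataFrame, gates: list[GateDefinition]
) -> pd.Series:
    """Assign each cell the unique deepest terminal gate it satisfies.

    Cells satisfying no terminal gate are labelled ``unassigned``; cells
    satisfying several equally deep gates are resolved by gate priority
    (lower wins) and logged.
    """
    labels = pd.Series(UNASSIGNED, index=thresholded.index, name="major_type", dtype=object)
    by_name = {g.name: g for g in gates}
    terminals = [g for g in gates if g.terminal]
    if not terminals:
        return labels
    masks = np.stack([_gate_mask(g, thresholded, by_name) for g in terminals])
    depths = np.array([_gate_depth(g, by_name) for g in terminals])
    priorities = np.array([g.priority for g in terminals])
    # rank gates: deeper wins, then lower priority number
    order = np.lexsort((priorities, -depths))
    n_multi = 0
    assigned = np.zeros(len(thresholded), dtype=bool)
    for gi in order:
        hit = masks[gi] & ~assigned
        labels.iloc[np.flatnonzero(hit)] = terminals[gi].name
        assigned |= hit
    multi = masks.sum(axis=0) > 1
    n_multi = int(multi.sum())
    if n_multi:
        logger.info("%d cells satisfied multiple terminal gates; resolved by depth/priority", n_multi)
    return labels
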