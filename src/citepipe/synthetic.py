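"""Synthetic CITE-seq-like cohorts with known ground truth.

Generates antibody (ADT), targeted-transcript (RNA) and sample-tag count
matrices for a multi-group participant cohort, with planted cell-type
proportion shifts, planted differentially expressed genes, and injected
hashtag doublets, all reproducible from a single master seed.

Count model: ADT counts are ``round(exp(Normal))`` on a log scale (signal
parameters for type-positive markers, shared background parameters
otherwise); RNA counts are Poisson with per-(type, gene) rates; sample tags
are Poisson with one dominant tag per singlet.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from citepipe.matrix import CountMatrix

__all__ = [
    "PlantedDE",
    "PlantedShift",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate_cohort",
    "truth_report",
]


@dataclass(frozen=True)
class PlantedDE:
    """A planted fold change on one gene, in one cell type, for one group."""

    gene: str
    cell_type: str
    group: str
    log2fc: float


@dataclass(frozen=True)
class PlantedShift:
    """A planted multiplier on one cell type's fraction in one group."""

    cell_type: str
    group: str
    multiplier: float


@dataclass
class SyntheticConfig:
    groups: dict[str, int]
    cells_per_participant: int
    cell_type_fractions: dict[str, dict[str, float]]
    adt_signal: dict[str, dict[str, tuple[float, float]]]
    adt_background: dict[str, tuple[float, float]]
    rna_rates: dict[str, dict[str, float]]
    planted_de: list[PlantedDE] = field(default_factory=list)
    planted_prop_shift: list[PlantedShift] = field(default_factory=list)
    doublet_rate: float = 0.075
    n_tags_per_plate: int = 4
    tag_dominant_rate: float = 60.0
    tag_ambient_rate: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("groups: at least one group required")
        for g, n in self.groups.items():
            if n < 1:
                raise ValueError(f"groups: group {g!r} has {n} participants")
        if self.cells_per_participant < 1:
            raise ValueError(
                f"cells_per_participant: must be >= 1, got {self.cells_per_participant}"
            )
        for g in self.groups:
            if g not in self.cell_type_fractions:
                raise ValueError(f"cell_type_fractions: missing group {g!r}")
            total = sum(self.cell_type_fractions[g].values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(
                    f"cell_type_fractions: group {g!r} fractions sum to {total}, not 1"
                )
            for t, f in self.cell_type_fractions[g].items():
                if f < 0:
                    raise ValueError(
                        f"cell_type_fractions: negative fraction for ({g!r}, {t!r})"
                    )
        if not (0 <= self.doublet_rate < 0.5):
            raise ValueError(f"doublet_rate: must be in [0, 0.5), got {self.doublet_rate}")
        if self.n_tags_per_plate < 1:
            raise ValueError(f"n_tags_per_plate: must be >= 1, got {self.n_tags_per_plate}")
        for m, (mu, sd) in self.adt_background.items():
            if sd <= 0:
                raise ValueError(f"adt_background: sd for marker {m!r} must be > 0")
        for t, sig in self.adt_signal.items():
            for m, (mu, sd) in sig.items():
                if m not in self.adt_background:
                    raise ValueError(
                        f"adt_signal: marker {m!r} (type {t!r}) has no background parameters"
                    )
                if sd <= 0:
                    raise ValueError(f"adt_signal: sd for ({t!r}, {m!r}) must be > 0")
        for t, rates in self.rna_rates.items():
            for gene, r in rates.items():
                if r <= 0:
                    raise ValueError(f"rna_rates: rate for ({t!r}, {gene!r}) must be > 0")
        if self.tag_dominant_rate <= 0 or self.tag_ambient_rate <= 0:
            raise ValueError("tag_dominant_rate/tag_ambient_rate: must be > 0")

    def to_dict(self) -> dict:
        """Plain key-value representation (YAML/JSON serializable)."""
        return {
            "groups": dict(self.groups),
            "cells_per_participant": self.cells_per_participant,
            "cell_type_fractions": {g: dict(f) for g, f in self.cell_type_fractions.items()},
            "adt_signal": {
                t: {m: [float(p[0]), float(p[1])] for m, p in sig.items()}
                for t, sig in self.adt_signal.items()
            },
            "adt_background": {
                m: [float(p[0]), float(p[1])] for m, p in self.adt_background.items()
            },
            "rna_rates": {t: {g: float(r) for g, r in rates.items()}
                          for t, rates in self.rna_rates.items()},
            "planted_de": [vars(e) for e in self.planted_de],
            "planted_prop_shift": [vars(s) for s in self.planted_prop_shift],
            "doublet_rate": self.doublet_rate,
            "n_tags_per_plate": self.n_tags_per_plate,
            "tag_dominant_rate": self.tag_dominant_rate,
            "tag_ambient_rate": self.tag_ambient_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        data["adt_signal"] = {
            t: {m: tuple(p) for m, p in sig.items()}
            for t, sig in data.get("adt_signal", {}).items()
        }
        data["adt_background"] = {
            m: tuple(p) for m, p in data.get("adt_background", {}).items()
        }
        data["planted_de"] = [PlantedDE(**e) for e in data.get("planted_de", [])]
        data["planted_prop_shift"] = [
            PlantedShift(**s) for s in data.get("planted_prop_shift", [])
        ]
        return cls(**data)

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            for t in self.cell_type_fractions[g]:
                seen.setdefault(t)
        return list(seen)

    @property
    def markers(self) -> list[str]:
        return list(self.adt_background)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.rna_rates:
            for gene in self.rna_rates[t]:
                seen.setdefault(gene)
        return list(seen)


@dataclass
class GroundTruth:
    """Per-cell truth plus the planted-effect registry for a generated cohort."""

    cells: pd.DataFrame  # index cell id: true_type, is_doublet, partner_type, partner_tag
    positive_markers: dict[str, set[str]]
    planted_de: list[PlantedDE]
    planted_prop_shift: list[PlantedShift]

    @property
    def doublet_fraction(self) -> float:
        return float(self.cells["is_doublet"].mean())


# --- default cohort emulating the study design -------------------------------

MAJOR_TYPES = ("B", "CD4 T", "CD8 T", "CM", "INT", "NCM", "NK")

DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "B": ("CD19", "CD20", "CD27"),
    "CD4 T": ("CD3", "CD4", "CD127", "CD27"),
    "CD8 T": ("CD3", "CD8", "CD27"),
    "CM": ("CD14", "CD163"),
    "INT": ("CD14", "CD16", "CD11c"),
    "NCM": ("CD16", "CD11c"),
    "NK": ("CD56", "CD16"),
}

DEFAULT_MARKERS = (
    "CD3", "CD4", "CD8", "CD14", "CD16", "CD19", "CD20", "CD56",
    "CD123", "CD206", "CD25", "CD127", "CD11c", "CXCR3", "CD163", "CD27",
)

DEFAULT_FRACTIONS = {
    "B": 0.08, "CD4 T": 0.30, "CD8 T": 0.26, "CM": 0.20,
    "INT": 0.04, "NCM": 0.03, "NK": 0.09,
}

DEFAULT_GROUPS = ("HIV-", "HIV+CVD-", "HIV+CVD+", "HIV+CVD+CRT+")


def default_config(
    seed: int = 0,
    n_participants_per_group: int = 8,
    cells_per_participant: int = 1300,
    n_filler_genes: int = 40,
    doublet_rate: float = 0.075,
    planted_de: Sequence[PlantedDE] = (),
    planted_prop_shift: Sequence[PlantedShift] = (),
    groups: Sequence[str] = DEFAULT_GROUPS,
    signal: tuple[float, float] = (np.log(120.0), 0.45),
    background: tuple[float, float] = (np.log(2.0), 0.6),
) -> SyntheticConfig:
    """Cohort config emulating the study design: matched groups of eight
    participants, ~1,300 cells each, seven gated PBMC types, 7.5% doublets."""
    fractions = {g: dict(DEFAULT_FRACTIONS) for g in groups}
    adt_background = {m: background for m in DEFAULT_MARKERS}
    adt_signal = {
        t: {m: signal for m in sig} for t, sig in DEFAULT_SIGNATURES.items()
    }
    # Antibody-named genes are elevated in the types whose signature carries
    # the antibody; filler genes share a flat baseline.
    genes = list(DEFAULT_MARKERS) + [f"GENE{i:03d}" for i in range(1, n_filler_genes + 1)]
    rna_rates: dict[str, dict[str, float]] = {}
    for t in MAJOR_TYPES:
        rates = {}
        for gene in genes:
            if gene in DEFAULT_SIGNATURES[t]:
                rates[gene] = 3.0
            elif gene.startswith("GENE"):
                rates[gene] = 0.5
            else:
                rates[gene] = 0.1
        rna_rates[t] = rates
    return SyntheticConfig(
        groups={g: n_participants_per_group for g in groups},
        cells_per_participant=cells_per_participant,
        cell_type_fractions=fractions,
        adt_signal=adt_signal,
        adt_background=adt_background,
        rna_rates=rna_rates,
        planted_de=list(planted_de),
        planted_prop_shift=list(planted_prop_shift),
        doublet_rate=doublet_rate,
        seed=seed,
    )


# --- generation --------------------------------------------------------------


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream fanned out from the master seed (stage-level reproducibility)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


def _participant_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    idx = 0
    for g, n in config.groups.items():
        for _ in range(n):
            rows.append(
                {
                    "participant": f"P{idx + 1:02d}",
                    "group": g,
                    "plate": f"plate{idx // config.n_tags_per_plate + 1}",
                    "tag": f"Tag{idx % config.n_tags_per_plate + 1}",
                }
            )
            idx += 1
    return pd.DataFrame(rows).set_index("participant")


def _group_fractions(config: SyntheticConfig, group: str, types: list[str]) -> np.ndarray:
    frac = np.array(
        [config.cell_type_fractions[group].get(t, 0.0) for t in types], dtype=float
    )
    for shift in config.planted_prop_shift:
        if shift.group == group and shift.cell_type in types:
            frac[types.index(shift.cell_type)] *= shift.multiplier
    return frac / frac.sum()


def _adt_params(config: SyntheticConfig, types: list[str]) -> tuple[np.ndarray, np.ndarray]:
    markers = config.markers
    mean = np.empty((len(types), len(markers)))
    sd = np.empty_like(mean)
    for i, t in enumerate(types):
        sig = config.adt_signal.get(t, {})
        for j, m in enumerate(markers):
            mean[i, j], sd[i, j] = sig.get(m, config.adt_background[m])
    return mean, sd


def _rna_rate_matrix(config: SyntheticConfig, types: list[str]) -> np.ndarray:
    genes = config.genes
    rate = np.full((len(types), len(genes)), 1e-4)
    for i, t in enumerate(types):
        rates = config.rna_rates.get(t, {})
        for j, gene in enumerate(genes):
            if gene in rates:
                rate[i, j] = rates[gene]
    return rate


def _simulate_adt(
    type_idx: np.ndarray, mean: np.ndarray, sd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    z = rng.standard_normal((len(type_idx), mean.shape[1]))
    return np.rint(np.exp(mean[type_idx] + sd[type_idx] * z)).astype(np.int64)


def _simulate_rna(
    type_idx: np.ndarray,
    group_idx: np.ndarray,
    rate: np.ndarray,
    fc: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    # fc has shape (n_groups, n_types, n_genes): planted fold-change multipliers
    lam = rate[type_idx] * fc[group_idx, type_idx]
    return rng.poisson(lam).astype(np.int64)


def _simulate_tags(
    tag_idx: np.ndarray, n_tags: int, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    counts = rng.poisson(config.tag_ambient_rate, size=(len(tag_idx), n_tags))
    counts[np.arange(len(tag_idx)), tag_idx] += rng.poisson(
        config.tag_dominant_rate, size=len(tag_idx)
    )
    return counts.astype(np.int64)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[CountMatrix, CountMatrix, CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate ADT/RNA/tag count matrices, the per-cell metadata table and
    the ground truth for one synthetic cohort.

    Doublets are injected by overwriting a Binomial(n, doublet_rate) subset of
    cells with the sum of their own counts and a freshly simulated partner
    profile drawn from a random participant on the same plate.
    """
    config.validate()
    types = config.cell_types
    markers = config.markers
    genes = config.genes
    participants = _participant_table(config)
    groups = list(config.groups)

    # per-cell host participant
    host = np.repeat(participants.index.to_numpy(), config.cells_per_participant)
    n = len(host)
    p_group = participants["group"]
    p_plate = participants["plate"]
    p_tag = participants["tag"]
    tag_names = [f"Tag{i + 1}" for i in range(config.n_tags_per_plate)]
    cell_group = p_group.loc[host].to_numpy()
    cell_tag_idx = np.array([tag_names.index(t) for t in p_tag.loc[host]])
    group_idx = np.array([groups.index(g) for g in cell_group])

    # true types per cell
    rng_types = _stream(config.seed, "types")
    type_idx = np.empty(n, dtype=np.int64)
    for gi, g in enumerate(groups):
        sel = group_idx == gi
        frac = _group_fractions(config, g, types)
        type_idx[sel] = rng_types.choice(len(types), size=sel.sum(), p=frac)

    # planted DE fold changes
    fc = np.ones((len(groups), len(types), len(genes)))
    for eff in config.planted_de:
        if eff.group in groups and eff.cell_type in types and eff.gene in genes:
            fc[groups.index(eff.group), types.index(eff.cell_type),
               genes.index(eff.gene)] *= 2.0 ** eff.log2fc

    mean, sd = _adt_params(config, types)
    rate = _rna_rate_matrix(config, types)

    adt = _simulate_adt(type_idx, mean, sd, _stream(config.seed, "adt"))
    rna = _simulate_rna(type_idx, group_idx, rate, fc, _stream(config.seed, "rna"))
    tags = _simulate_tags(cell_tag_idx, config.n_tags_per_plate, config,
                          _stream(config.seed, "tags"))

    # doublet injection: chosen cells absorb a fresh partner profile
    rng_dbl = _stream(config.seed, "doublets")
    is_doublet = rng_dbl.random(n) < config.doublet_rate
    partner_type = np.full(n, "", dtype=object)
    partner_tag = np.full(n, "", dtype=object)
    d_idx = np.flatnonzero(is_doublet)
    if d_idx.size:
        plate_members = {
            pl: participants.index[p_plate == pl].to_numpy()
            for pl in p_plate.unique()
        }
        partner_host = np.array(
            [rng_dbl.choice(plate_members[p_plate.loc[h]]) for h in host[d_idx]]
        )
        pg_idx = np.array([groups.index(p_group.loc[h]) for h in partner_host])
        ptype_idx = np.empty(len(d_idx), dtype=np.int64)
        for gi in np.unique(pg_idx):
            sel = pg_idx == gi
            frac = _group_fractions(config, groups[gi], types)
            ptype_idx[sel] = rng_dbl.choice(len(types), size=sel.sum(), p=frac)
        ptag_idx = np.array([tag_names.index(p_tag.loc[h]) for h in partner_host])
        adt[d_idx] += _simulate_adt(ptype_idx, mean, sd, _stream(config.seed, "adt-partner"))
        rna[d_idx] += _simulate_rna(ptype_idx, pg_idx, rate, fc,
                                    _stream(config.seed, "rna-partner"))
        tags[d_idx] += _simulate_tags(ptag_idx, config.n_tags_per_plate, config,
                                      _stream(config.seed, "tags-partner"))
        partner_type[d_idx] = [types[i] for i in ptype_idx]
        partner_tag[d_idx] = [tag_names[i] for i in ptag_idx]

    cell_ids = pd.Index([f"cell{i + 1:06d}" for i in range(n)], name="cell")
    cell_table = pd.DataFrame(
        {
            "participant": host,
            "plate": p_plate.loc[host].to_numpy(),
            "group": cell_group,
        },
        index=cell_ids,
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "true_type": [types[i] for i in type_idx],
                "is_doublet": is_doublet,
                "partner_type": partner_type,
                "true_tag": [tag_names[i] for i in cell_tag_idx],
                "partner_tag": partner_tag,
            },
            index=cell_ids,
        ),
        positive_markers={
            t: set(config.adt_signal.get(t, {})) for t in types
        },
        planted_de=list(config.planted_de),
        planted_prop_shift=list(config.planted_prop_shift),
    )
    return (
        CountMatrix(cell_ids, pd.Index(markers), adt, "ADT"),
        CountMatrix(cell_ids, pd.Index(genes), rna, "RNA"),
        CountMatrix(cell_ids, pd.Index(tag_names), tags, "TAG"),
        cell_table,
        truth,
    )


def truth_report(truth: GroundTruth) -> pd.DataFrame:
    """One row per planted effect (DE genes and proportion shifts)."""
    rows = []
    for eff in truth.planted_de:
        rows.append(
            {
                "kind": "de",
                "gene": eff.gene,
                "cell_type": eff.cell_type,
                "group": eff.group,
                "log2fc": eff.log2fc,
                "multiplier": np.nan,
            }
        )
    for shift in truth.planted_prop_shift:
        rows.append(
            {
                "kind": "prop_shift",
                "gene": "",
                "cell_type": shift.cell_type,
                "group": shift.group,
                "log2fc": np.nan,
                "multiplier": shift.multiplier,
            }
        )
    return pd.DataFrame(
        rows, columns=["kind", "gene", "cell_type", "group", "log2fc", "multiplier"]
    )
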