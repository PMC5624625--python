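"""Core domain types for gradient-diversity analyses.

The analysis operates on four kinds of input — a rooted, branch-length-bearing
phylogeny; a plots × species cover-abundance matrix; a species × trait table;
and per-plot environmental metadata — plus square distance matrices that carry
phylogenetic, functional, geographic and environmental distances between
analysis units.  Each type validates its own invariants on construction so
that downstream stages can assume clean inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "CommunityMatrix",
    "TraitTable",
    "PairMatrix",
    "DistanceMatrix",
    "TRAIT_COLUMNS",
    "CLIMATE_COLUMNS",
    "METADATA_COLUMNS",
    "FormatError",
]

#: canonical trait columns (units: m, cm, cm, month, mg)
TRAIT_COLUMNS = ("max_height", "leaf_length", "leaf_width", "flowering_onset", "seed_mass")

#: the seven climate variables recorded per plot
CLIMATE_COLUMNS = (
    "temp_annual",
    "temp_january",
    "temp_august",
    "temp_growing",
    "temp_range",
    "precip_annual",
    "precip_growing",
)

#: required non-climate metadata columns
METADATA_COLUMNS = ("transect_id", "elevation", "latitude", "longitude", "slope", "rar")


class FormatError(ValueError):
    """Raised when an input file or table violates a structural invariant."""


@dataclass
class Phylogeny:
    """A rooted phylogenetic tree with branch lengths in time-like units.

    Thin wrapper around a :class:`dendropy.Tree` that enforces unique,
    non-empty tip labels, non-negative branch lengths and at least two tips.
    """

    tree: dendropy.Tree
    tips: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label if leaf.taxon else "" for leaf in self.tree.leaf_node_iter()]
        if len(labels) < 2:
            raise FormatError("phylogeny must have at least 2 tips")
        if any(not lab for lab in labels):
            raise FormatError("empty tip label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError("missing branch length")
            if edge.length < 0:
                raise FormatError(f"negative branch length: {edge.length}")
        self.tips = sorted(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depths = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def patristic_distances(self) -> "DistanceMatrix":
        """Pairwise sum-of-branch-length (patristic) distances between tips."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in set(self.tips)}
        n = len(self.tips)
        d = np.zeros((n, n))
        for i, a in enumerate(self.tips):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[self.tips[j]])
        return DistanceMatrix(labels=list(self.tips), values=d)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class CommunityMatrix:
    """Plots × species abundance (cover) matrix.

    Abundances are non-negative cover units; weights derived from them are
    always within-plot relative abundances, so any positive scaling of a
    row leaves every downstream statistic unchanged.
    """

    data: pd.DataFrame  # index: plot ids, columns: species ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise FormatError("duplicate plot or species labels in community matrix")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            raise FormatError("negative abundance in community matrix")
        if np.any(values.sum(axis=1) <= 0):
            empty = list(self.data.index[values.sum(axis=1) <= 0])
            raise FormatError(f"plots with no positive abundance: {empty}")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    def abundances(self, plot: str) -> np.ndarray:
        return self.data.loc[plot].to_numpy(dtype=float)

    def relative(self) -> np.ndarray:
        """Row-normalised (within-plot relative) abundance matrix."""
        values = self.data.to_numpy(dtype=float)
        return values / values.sum(axis=1, keepdims=True)

    def check_against_tree(self, phylogeny: Phylogeny, drop_unmatched: bool = False) -> "CommunityMatrix":
        """Verify species ⊆ tree tips; optionally drop unmatched species."""
        missing = [s for s in self.species_ids if s not in set(phylogeny.tips)]
        if not missing:
            return self
        if not drop_unmatched:
            raise FormatError(f"species absent from phylogeny: {missing}")
        kept = self.data.drop(columns=missing)
        return CommunityMatrix(kept)


@dataclass
class TraitTable:
    """Species × functional-trait table.

    Expected traits: maximum height (m), leaf length (cm), leaf width (cm),
    flowering onset (month 1–12) and seed mass (mg).  All values must be
    strictly positive so the log transform used throughout is defined.
    """

    data: pd.DataFrame  # index: species ids, columns ⊇ TRAIT_COLUMNS

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate species in trait table")
        missing = [c for c in TRAIT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing trait columns: {missing}")
        values = self.data[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise FormatError("trait values must be finite and strictly positive")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def matrix(self) -> pd.DataFrame:
        return self.data[list(TRAIT_COLUMNS)].astype(float)


@dataclass
class PairMatrix:
    """Square symmetric matrix over ordered unique labels with zero diagonal.

    Carrier for pairwise quantities that may be negative (e.g. between-plot
    NRI); :class:`DistanceMatrix` adds the non-negativity invariant.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in pairwise matrix")
        if self.values.shape != (n, n):
            raise FormatError(f"pairwise matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise FormatError("pairwise matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise FormatError("pairwise matrix diagonal not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def reindex(self, labels: list[str]) -> "PairMatrix":
        """Return a copy whose rows/columns follow ``labels`` (a subset is allowed)."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = np.array([pos[l] for l in labels])
        return type(self)(labels=list(labels), values=self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a 1-D vector (scipy condensed order)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class DistanceMatrix(PairMatrix):
    """Square symmetric distance matrix: a :class:`PairMatrix` with d_ij ≥ 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise FormatError("negative distances")
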