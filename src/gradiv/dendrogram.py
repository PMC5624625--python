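"""Functional trait dendrogram: log-standardised traits → PCA → UPGMA.

Traits are natural-log-transformed and z-scored per trait, summarised by PCA
on their correlation matrix to remove redundancy, and the Euclidean distance
over the retained component scores is clustered with UPGMA (average linkage)
to give an ultrametric functional dendrogram whose cophenetic distances feed
the functional diversity calculations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet as _scipy_cophenet
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .datamodel import DistanceMatrix, TraitTable

__all__ = [
    "prepare_traits",
    "trait_pca",
    "euclidean_distance",
    "upgma",
    "cophenetic",
    "PCAResult",
    "Dendrogram",
]


def prepare_traits(traits: TraitTable | pd.DataFrame) -> pd.DataFrame:
    """Natural log then per-trait z-score (mean 0, sample SD 1 across species)."""
    table = traits.matrix() if isinstance(traits, TraitTable) else traits.astype(float)
    if (table <= 0).any().any():
        raise ValueError("traits must be strictly positive for the log transform")
    logged = np.log(table)
    sd = logged.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance trait(s) after log transform: {bad}")
    return (logged - logged.mean(axis=0)) / sd


@dataclass
class PCAResult:
    """Principal components of the standardised trait matrix."""

    scores: pd.DataFrame  # species × retained components
    loadings: pd.DataFrame  # traits × retained components
    explained_fraction: np.ndarray  # per component over ALL components, sums to 1

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_fraction)


def trait_pca(standardized: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA via eigendecomposition of the correlation matrix of standardised traits.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making outputs deterministic across platforms.
    """
    if n_components is not None and n_components < 1:
        raise ValueError("n_components must be >= 1")
    Z = standardized.to_numpy(dtype=float)
    n, p = Z.shape
    k = p if n_components is None else min(n_components, p)
    corr = Z.T @ Z / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    for j in range(p):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    explained = eigval / eigval.sum()
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(Z @ eigvec[:, :k], index=standardized.index, columns=comps)
    loadings = pd.DataFrame(eigvec[:, :k], index=standardized.columns, columns=comps)
    return PCAResult(scores=scores, loadings=loadings, explained_fraction=explained)


def euclidean_distance(scores: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance over rows of a score matrix."""
    d = squareform(pdist(scores.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(labels=[str(i) for i in scores.index], values=d)


@dataclass
class Dendrogram:
    """UPGMA merge history over a set of tip labels.

    ``merge[i] = (a, b, d, size)`` in scipy linkage convention where ``d`` is
    the average pairwise distance between the merged clusters; the merge
    *height* in the ultrametric sense is ``d / 2`` and the cophenetic
    distance between tips joined at that merge is ``d``.
    """

    labels: list[str]
    merge: np.ndarray  # scipy linkage matrix, shape (n-1, 4)

    def __post_init__(self) -> None:
        heights = self.merge[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("UPGMA merge heights must be non-decreasing")

    def cophenetic(self) -> DistanceMatrix:
        """Cophenetic distances: twice the merge height joining each tip pair."""
        return DistanceMatrix(labels=list(self.labels), values=squareform(_scipy_cophenet(self.merge)))

    def as_newick(self, precision: int = 10) -> str:
        """Ultrametric Newick string (tip depths equal the root merge height)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        newick = {i: self.labels[i] for i in range(n)}
        for i, (a, b, d, _) in enumerate(self.merge):
            a, b = int(a), int(b)
            h = d / 2.0
            la = h - height[a]
            lb = h - height[b]
            node = n + i
            newick[node] = (
                f"({newick[a]}:{la:.{precision}g},{newick[b]}:{lb:.{precision}g})"
            )
            height[node] = h
        return newick[2 * n - 2] + ";"


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Labels are processed in sorted order so tie-breaking is deterministic
    across platforms and input orderings.
    """
    if len(dm) < 2:
        raise ValueError("need at least 2 labels")
    if np.any(~np.isfinite(dm.values)):
        raise ValueError("NaN/inf in distance matrix")
    order = sorted(dm.labels)
    dm = dm.reindex(order)
    Z = _scipy_linkage(dm.condensed(), method="average")
    return Dendrogram(labels=order, merge=Z)


def cophenetic(dendrogram: Dendrogram) -> DistanceMatrix:
    """Cophenetic distance matrix of a dendrogram (module-level convenience)."""
    return dendrogram.cophenetic()


def functional_dendrogram(
    traits: TraitTable, n_components: int = 4
) -> tuple[Dendrogram, PCAResult]:
    """Full pipeline: log-standardise, PCA, Euclidean distance, UPGMA."""
    std = prepare_traits(traits)
    pca = trait_pca(std, n_components=n_components)
    dist = euclidean_distance(pca.scores)
    return upgma(dist), pca
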