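"""Alpha and beta diversity: richness, Bray-Curtis, abundance-weighted MPD and NRI.

Taxonomic diversity is species richness (alpha) and Bray-Curtis similarity
(beta).  Phylogenetic and functional dispersion use the abundance-weighted
mean pairwise distance (MPD) within a plot or between plot pairs, measured on
patristic tree distances or cophenetic dendrogram distances, standardised
against a tip-shuffle null model:

    NRI = −1 × (MPD_obs − mean MPD_null) / sd MPD_null

The null shuffles species names across the tips of the tree or dendrogram
while holding the community matrix fixed, so observed richness, abundance and
occupancy structure are preserved in every randomisation.  Positive NRI means
co-occurring species are closer than expected (clustering); negative NRI
means overdispersion.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, DistanceMatrix

__all__ = [
    "richness",
    "bray_curtis_similarity",
    "bray_curtis_matrix",
    "mpd_alpha",
    "mpd_beta",
    "tip_shuffle_null",
    "nri",
    "dispersion_profiles",
    "DegenerateNullWarning",
]


class DegenerateNullWarning(UserWarning):
    """Null distribution has zero spread; NRI reported as 0."""


def richness(community: CommunityMatrix, plot: str) -> int:
    """Number of species with positive abundance in a plot."""
    return int(np.count_nonzero(community.abundances(plot) > 0))


def richness_table(community: CommunityMatrix) -> pd.Series:
    counts = (community.data.to_numpy(dtype=float) > 0).sum(axis=1)
    return pd.Series(counts.astype(int), index=community.plot_ids, name="richness")


def bray_curtis_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis similarity, 1 − Σ|x−y| / Σ(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    total = np.sum(x + y)
    if total == 0:
        raise ValueError("both abundance vectors are all-zero")
    return float(1.0 - np.sum(np.abs(x - y)) / total)


def bray_curtis_matrix(community: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis *dissimilarity* between plots (similarity = 1 − d)."""
    A = community.data.to_numpy(dtype=float)
    diff = np.abs(A[:, None, :] - A[None, :, :]).sum(axis=2)
    tot = (A[:, None, :] + A[None, :, :]).sum(axis=2)
    d = diff / tot
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=community.plot_ids, values=d)


def _relative(abund: np.ndarray) -> np.ndarray:
    abund = np.asarray(abund, dtype=float)
    s = abund.sum()
    if s <= 0:
        raise ValueError("empty plot: no positive abundance")
    return abund / s


def mpd_alpha(dm: DistanceMatrix, abundances: np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance within a plot.

    MPD = Σ_{i≠j} f_i f_j d_ij / Σ_{i≠j} f_i f_j with f the within-plot
    relative abundances.  Undefined (NaN) for plots with fewer than two
    species present.
    """
    f = _relative(abundances)
    if np.count_nonzero(f > 0) < 2:
        return float("nan")
    num = f @ dm.values @ f  # diagonal of d is 0, so i=j terms vanish
    den = 1.0 - f @ f
    return float(num / den)


def mpd_beta(dm: DistanceMatrix, abundances_x: np.ndarray, abundances_y: np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance between two plots.

    Averages d over all cross-plot species pairs weighted by the product of
    within-plot relative abundances; pairs of the same species contribute
    d = 0, so shared species pull the value down.
    """
    f = _relative(abundances_x)
    g = _relative(abundances_y)
    return float(f @ dm.values @ g)


def tip_shuffle_null(
    dm: DistanceMatrix,
    community: CommunityMatrix,
    unit: str | tuple[str, str],
    n_null: int = 1000,
    seed: int | None = None,
    pool: list[str] | None = None,
) -> np.ndarray:
    """Null MPD sample for one plot (alpha) or plot pair (beta).

    Each replicate permutes the species labels of the distance matrix over
    the pool (equivalent to shuffling names across tree tips) and recomputes
    MPD; the community matrix is untouched.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    species = pool if pool is not None else community.species_ids
    if len(species) < 2:
        raise ValueError("species pool must have at least 2 members")
    dm = dm.reindex(species)
    idx = [community.species_ids.index(s) for s in species]
    rng = np.random.default_rng(seed)
    if isinstance(unit, tuple):
        fx = community.abundances(unit[0])[idx]
        fy = community.abundances(unit[1])[idx]
        func = lambda D: mpd_beta(DistanceMatrix(species, D), fx, fy)  # noqa: E731
    else:
        f = community.abundances(unit)[idx]
        func = lambda D: mpd_alpha(DistanceMatrix(species, D), f)  # noqa: E731
    out = np.empty(n_null)
    for r in range(n_null):
        perm = rng.permutation(len(species))
        out[r] = func(dm.values[np.ix_(perm, perm)])
    return out


def nri(mpd_obs: float, null_sample: np.ndarray) -> float:
    """Net relatedness index: −1 × (MPD_obs − null mean) / null SD (ddof=1)."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size < 2:
        raise ValueError("null sample must have >= 2 replicates")
    sd = null_sample.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate null (sd = 0); NRI reported as 0", DegenerateNullWarning)
        return 0.0
    return float(-1.0 * (mpd_obs - null_sample.mean()) / sd)


def _profiles_one_pool(
    D: np.ndarray,
    F: np.ndarray,
    mode: str,
    n_null: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed MPD, null mean and null SD for every unit in one species pool.

    F is the plots × species relative-abundance matrix restricted to the pool;
    alpha returns per-plot vectors, beta returns condensed per-pair vectors.
    Null moments are accumulated with running sums to keep memory flat.
    """
    s = D.shape[0]

    if mode == "alpha":
        def stat(Dm: np.ndarray) -> np.ndarray:
            num = np.einsum("ps,st,pt->p", F, Dm, F, optimize=True)
            den = 1.0 - np.einsum("ps,ps->p", F, F)
            with np.errstate(divide="ignore", invalid="ignore"):
                return num / den
    else:
        iu = np.triu_indices(F.shape[0], k=1)

        def stat(Dm: np.ndarray) -> np.ndarray:
            return (F @ Dm @ F.T)[iu]

    obs = stat(D)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(s)
        v = stat(D[np.ix_(perm, perm)])
        acc += v
        acc2 += v * v
    mean = acc / n_null
    var = (acc2 - n_null * mean**2) / (n_null - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return obs, mean, sd


def dispersion_profiles(
    dm: DistanceMatrix,
    community: CommunityMatrix,
    mode: str = "alpha",
    n_null: int = 1000,
    seed: int | None = None,
    transects: pd.Series | None = None,
) -> pd.DataFrame:
    """Observed MPD, null moments and NRI for every plot (alpha) or pair (beta).

    The same engine serves phylogenetic distances (patristic) and functional
    distances (cophenetic).  With ``transects`` given (plot → transect id),
    the null pool is the species observed on each plot's transect and beta
    pairs are formed within transects; otherwise a single global pool is
    used.  Plots with fewer than two species are excluded from alpha
    profiles; beta pairs require one present species per plot.
    """
    if mode not in {"alpha", "beta"}:
        raise ValueError("mode must be 'alpha' or 'beta'")
    if n_null < 2:
        raise ValueError("n_null must be >= 2 to estimate a null SD")
    rng = np.random.default_rng(seed)

    if transects is None:
        groups = {"__all__": community.plot_ids}
    else:
        groups = {
            str(t): [p for p in community.plot_ids if str(transects.loc[p]) == str(t)]
            for t in sorted(set(str(v) for v in transects.loc[community.plot_ids]))
        }

    rows = []
    for _, plots in groups.items():
        sub = community.data.loc[plots]
        pool = [s for s in community.species_ids if sub[s].sum() > 0]
        if len(pool) < 2:
            raise ValueError("species pool must have at least 2 members")
        Dsub = dm.reindex(pool).values
        A = sub[pool].to_numpy(dtype=float)

        if mode == "alpha":
            present = (A > 0).sum(axis=1)
            keep = present >= 2
            if not np.all(keep):
                warnings.warn(
                    f"excluding {np.count_nonzero(~keep)} plot(s) with richness < 2 from alpha NRI",
                    UserWarning,
                )
            plots_kept = [p for p, k in zip(plots, keep) if k]
            F = A[keep] / A[keep].sum(axis=1, keepdims=True)
            obs, mean, sd = _profiles_one_pool(Dsub, F, "alpha", n_null, rng)
            units = [(p,) for p in plots_kept]
        else:
            F = A / A.sum(axis=1, keepdims=True)
            obs, mean, sd = _profiles_one_pool(Dsub, F, "beta", n_null, rng)
            iu = np.triu_indices(len(plots), k=1)
            units = [(plots[i], plots[j]) for i, j in zip(*iu)]

        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, -1.0 * (obs - mean) / sd, 0.0)
        if np.any(sd == 0):
            warnings.warn("degenerate null (sd = 0) for some units", DegenerateNullWarning)
        for u, o, m, s_, n_ in zip(units, obs, mean, sd, z):
            row = {"mpd_obs": o, "null_mean": m, "null_sd": s_, "nri": n_,
                   "n_null": n_null, "seed": seed}
            if mode == "alpha":
                row["plot"] = u[0]
            else:
                row["plot_a"], row["plot_b"] = u
            rows.append(row)

    df = pd.DataFrame(rows)
    front = ["plot"] if mode == "alpha" else ["plot_a", "plot_b"]
    return df[front + ["mpd_obs", "null_mean", "null_sd", "nri", "n_null", "seed"]]
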