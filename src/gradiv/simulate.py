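"""Synthetic elevational-gradient communities with known ground truth.

Every downstream stage (signal tests, dendrograms, NRI null models, driver
attribution) gets a recovery test from this module: a Yule phylogeny with
unit depth, traits evolved under a λ-scaled Brownian-motion covariance,
plots along a mountain transect whose communities are assembled by
environmental filtering, limiting-similarity competition or neutrally, and
plot metadata whose climate variables track elevation the way temperature
lapse and orographic precipitation do on a real transect.

Scenario ground truth:

* ``filtering`` — each species' elevational optimum is a linear map of its
  (phylogenetically conserved) first trait, so co-occurring species are
  close relatives and plot-level NRI is pushed positive.
* ``competition`` — optima are random, but species whose first trait lies
  within a limiting-similarity radius of an already-admitted resident are
  excluded from the plot, pushing NRI negative when traits carry signal.
* ``neutral`` — optima are uniform at random; NRI is centred on zero.
"""
from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, Phylogeny, TraitTable
from .signal import phylo_vcv

__all__ = [
    "ScenarioConfig",
    "simulate_tree",
    "simulate_traits",
    "traits_to_table",
    "simulate_gradient_community",
    "simulate_scenario",
]

#: per-trait medians used to map zero-mean latent values to positive units
#: (m, cm, cm, month, mg)
TRAIT_MEDIANS = {
    "max_height": 5.0,
    "leaf_length": 8.0,
    "leaf_width": 4.0,
    "flowering_onset": 6.0,
    "seed_mass": 10.0,
}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic transect.

    Defaults mirror the scale of a single study transect: ~60 species over
    ~60 plots spanning 300–1700 m, Brownian traits on a unit-depth tree
    (``sigma2`` is then trait variance accumulated root → tip) and a niche
    breadth of 250 m around each species' elevational optimum.
    """

    n_species: int = 60
    n_plots: int = 60
    elevation_range: tuple[float, float] = (300.0, 1700.0)
    scenario: str = "filtering"
    lambda_true: float = 1.0
    sigma2: float = 1.0
    niche_breadth: float = 250.0
    seed: int = 0
    n_traits: int = 5
    base_abundance: float = 20.0
    richness_gradient: float = 0.5  # fraction by which amplitude declines toward the top
    limiting_radius: float = 0.4  # trait-1 units, competition scenario only
    rar_elevation_weight: float = 0.0
    transect_id: str = "T1"
    retry_cap: int = 100

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.n_plots < 2:
            raise ValueError("n_plots must be >= 2")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be > 0")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.scenario not in {"filtering", "competition", "neutral"}:
            raise ValueError("scenario must be filtering, competition or neutral")


def simulate_tree(n_species: int, seed: int | None = None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with tip depth normalised to 1.

    Tips are relabelled ``s001, s002, ...`` in a deterministic traversal
    order, so the same seed yields a byte-identical Newick string.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = _random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"s{i:0{width}d}"
    # the simulator stops at the n-th speciation, leaving the youngest pair
    # with zero pendant edges (and a singular covariance matrix); extend all
    # pendant edges by the Exp(n·birth_rate) waiting time to the next event
    extra = rng.expovariate(n_species * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = _max_depth(tree)
    if depth <= 0:
        raise RuntimeError("simulated tree has zero depth")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return Phylogeny(tree)


def _max_depth(tree: dendropy.Tree) -> float:
    best = 0.0
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        best = max(best, d)
    return best


def simulate_traits(
    phylogeny: Phylogeny,
    lambda_true: float = 1.0,
    sigma2: float = 1.0,
    seed: int | None = None,
    n_traits: int = 5,
) -> pd.DataFrame:
    """Traits from a zero-mean MVN with covariance σ²·C(λ).

    C is the tree's shared-branch-length matrix; C(λ) scales its
    off-diagonal by λ, so λ = 1 is Brownian motion and λ = 0 makes tips
    independent with their BM variances.  Columns are ``trait_1..n``;
    rows follow ``phylogeny.tips``.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    C, tips = phylo_vcv(phylogeny)
    Cl = lambda_true * C
    np.fill_diagonal(Cl, np.diag(C))
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        X = np.zeros((len(tips), n_traits))
    else:
        jitter = 1e-12 * np.trace(Cl) / len(tips)
        L = np.linalg.cholesky(sigma2 * Cl + jitter * np.eye(len(tips)))
        X = L @ rng.standard_normal((len(tips), n_traits))
    return pd.DataFrame(X, index=tips, columns=[f"trait_{j + 1}" for j in range(n_traits)])


def traits_to_table(latent: pd.DataFrame) -> TraitTable:
    """Map latent (log-scale) traits onto positive values in field units.

    ``value = median · exp(latent)`` per trait, so the analysis pipeline's
    log transform recovers the latent scale exactly (up to the affine
    z-scoring, to which every downstream statistic is invariant).
    """
    names = list(TRAIT_MEDIANS)
    if latent.shape[1] < len(names):
        raise ValueError(f"need {len(names)} latent traits")
    data = {
        name: TRAIT_MEDIANS[name] * np.exp(latent.iloc[:, j].to_numpy())
        for j, name in enumerate(names)
    }
    return TraitTable(pd.DataFrame(data, index=latent.index))


def _assemble_weights(
    elevations: np.ndarray,
    optima: np.ndarray,
    amplitude: np.ndarray,
    breadth: float,
) -> np.ndarray:
    """Expected abundance: Gaussian niche kernel around each species optimum."""
    z = (elevations[:, None] - optima[None, :]) / breadth
    return amplitude[None, :] * np.exp(-0.5 * z**2)


def simulate_gradient_community(
    phylogeny: Phylogeny,
    traits: pd.DataFrame,
    cfg: ScenarioConfig,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Communities along one elevational transect plus plot metadata.

    Plots sit evenly over ``cfg.elevation_range`` on a straight ~5 km
    lon/lat line (geographic and elevational distance are collinear, as on
    a single mountain flank) with a few metres of coordinate jitter.
    Abundance of species s in plot p is Poisson with mean from a Gaussian
    kernel of |elevation_p − optimum_s| / niche_breadth; how optima relate
    to traits is the scenario's ground truth (see module docstring).
    Climate metadata follow a temperature lapse with elevation and an
    orographic increase in precipitation, each with observation noise;
    slope is terrain noise and RAR is noise optionally tilted toward high
    elevation by ``rar_elevation_weight``.
    """
    rng = np.random.default_rng(cfg.seed)
    tips = phylogeny.tips
    if list(traits.index) != list(tips):
        traits = traits.loc[tips]
    n_p, n_s = cfg.n_plots, cfg.n_species
    if len(tips) != n_s:
        raise ValueError("tree size does not match cfg.n_species")
    e_min, e_max = cfg.elevation_range
    elevations = np.linspace(e_min, e_max, n_p)

    t1 = traits.iloc[:, 0].to_numpy(dtype=float)
    if cfg.scenario == "filtering":
        # linear map of the conserved trait onto the gradient
        span = np.ptp(t1)
        optima = e_min + (t1 - t1.min()) / (span if span > 0 else 1.0) * (e_max - e_min)
    else:
        optima = rng.uniform(e_min, e_max, size=n_s)

    frac = (optima - e_min) / (e_max - e_min)
    amplitude = cfg.base_abundance * (1.0 - cfg.richness_gradient * np.clip(frac, 0, 1))
    mean = _assemble_weights(elevations, optima, amplitude, cfg.niche_breadth)

    if cfg.scenario == "competition":
        # sequential assembly: reject entrants within the limiting-similarity
        # radius of an already-admitted resident (first trait axis)
        admitted = np.ones_like(mean, dtype=bool)
        for p in range(n_p):
            order = np.argsort(-mean[p])
            residents: list[int] = []
            for s in order:
                if mean[p, s] <= 0:
                    break
                if all(abs(t1[s] - t1[r]) > cfg.limiting_radius for r in residents):
                    residents.append(s)
            keep = np.zeros(n_s, dtype=bool)
            keep[residents] = True
            admitted[p] = keep
        mean = mean * admitted

    abundance = rng.poisson(mean).astype(float)
    for p in range(n_p):
        tries = 0
        while abundance[p].sum() == 0:
            tries += 1
            if tries > cfg.retry_cap:
                raise RuntimeError(
                    f"plot {p} empty after {cfg.retry_cap} redraws; "
                    "niche_breadth too narrow for the gradient"
                )
            abundance[p] = rng.poisson(mean[p])

    plot_ids = [f"{cfg.transect_id}_p{p + 1:03d}" for p in range(n_p)]
    community = CommunityMatrix(pd.DataFrame(abundance, index=plot_ids, columns=tips))

    # transect geometry: a straight ~5 km line heading north, tiny jitter
    lat0, lon0 = 38.0, 128.3
    pos = np.linspace(0.0, 1.0, n_p)
    transect_km = 5.0
    lat = lat0 + pos * (transect_km * 1000.0 / 111_194.9) + rng.normal(0, 1e-5, n_p)
    lon = lon0 + rng.normal(0, 1e-5, n_p)

    z = (elevations - elevations.mean()) / elevations.std()
    moisture = rng.standard_normal(n_p)  # second, elevation-independent latent factor
    s_t = 0.3
    meta = pd.DataFrame(
        {
            "transect_id": cfg.transect_id,
            "elevation": elevations,
            "latitude": lat,
            "longitude": lon,
            "slope": np.clip(rng.normal(25.0, 8.0, n_p), 1.0, 60.0),
            "rar": np.clip(
                (1 - cfg.rar_elevation_weight) * rng.normal(0.3, 0.15, n_p)
                + cfg.rar_elevation_weight
                * (0.1 + 0.6 * (elevations - e_min) / (e_max - e_min)),
                0.0,
                1.0,
            ),
            "temp_annual": 11.0 - 5.5 * z + rng.normal(0, s_t, n_p),
            "temp_january": -5.0 - 6.0 * z + rng.normal(0, s_t, n_p),
            "temp_august": 23.0 - 5.0 * z + rng.normal(0, s_t, n_p),
            "temp_growing": 18.0 - 5.2 * z + rng.normal(0, s_t, n_p),
            "temp_range": 28.0 + 1.0 * z + rng.normal(0, s_t, n_p),
            "precip_annual": 1228.0 * np.exp(0.12 * z + 0.05 * moisture + rng.normal(0, 0.02, n_p)),
            "precip_growing": 700.0 * np.exp(0.14 * z + 0.05 * moisture + rng.normal(0, 0.02, n_p)),
        },
        index=plot_ids,
    )
    return community, meta


def simulate_scenario(
    cfg: ScenarioConfig,
) -> tuple[Phylogeny, pd.DataFrame, TraitTable, CommunityMatrix, pd.DataFrame]:
    """One full synthetic dataset: tree, latent traits, trait table, community, metadata.

    Stage seeds are derived from ``cfg.seed`` so the whole bundle is
    reproducible from the single config.
    """
    tree = simulate_tree(cfg.n_species, seed=cfg.seed)
    latent = simulate_traits(
        tree, cfg.lambda_true, cfg.sigma2, seed=cfg.seed + 1, n_traits=cfg.n_traits
    )
    table = traits_to_table(latent)
    community, meta = simulate_gradient_community(tree, latent, cfg)
    return tree, latent, table, community, meta
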