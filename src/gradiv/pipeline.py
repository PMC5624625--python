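"""End-to-end orchestration: simulate/load → signal → dendrogram → NRI → drivers.

A single :class:`RunConfig` (parsed from a YAML key-value file or built in
code) drives the whole analysis deterministically: every stochastic stage has
an explicit seed, every output table carries a header comment with the config
hash and stage seed, and a run log records stages, parameters and wall time.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, drivers, io
from .datamodel import CommunityMatrix, PairMatrix, Phylogeny, TraitTable
from .dendrogram import functional_dendrogram
from .signal import signal_results_frame, signal_table
from .simulate import ScenarioConfig, simulate_scenario

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger("gradiv")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Either ``scenario`` (synthetic data) or all four input paths must be
    given.  Seeds are mandatory for every stochastic stage so runs are
    reproducible by construction.
    """

    out_dir: str = "gradiv_out"
    # inputs: synthetic scenario ...
    scenario: ScenarioConfig | None = None
    # ... or observed data files
    tree_path: str | None = None
    community_path: str | None = None
    traits_path: str | None = None
    metadata_path: str | None = None
    braun_blanquet: bool = False
    drop_unmatched: bool = False
    # stage parameters
    n_components: int = 4
    n_null: int = 1000
    n_perm_signal: int = 1000
    n_perm_matrix: int = 999
    pool: str = "transect"  # 'transect' or 'global'
    seed_signal: int | None = None
    seed_null: int | None = None
    seed_perm: int | None = None

    def validate(self) -> None:
        has_files = all(
            p is not None
            for p in (self.tree_path, self.community_path, self.traits_path, self.metadata_path)
        )
        if self.scenario is None and not has_files:
            raise ValueError("config needs either a scenario or all four input paths")
        for name in ("seed_signal", "seed_null", "seed_perm"):
            if getattr(self, name) is None:
                raise ValueError(f"config missing required seed: {name}")
        if self.pool not in {"transect", "global"}:
            raise ValueError("pool must be 'transect' or 'global'")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        scenario = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scenario is not None:
            if isinstance(scenario, dict):
                if "elevation_range" in scenario:
                    scenario["elevation_range"] = tuple(scenario["elevation_range"])
                cfg.scenario = ScenarioConfig(**scenario)
            else:
                raise ValueError("scenario must be a mapping of ScenarioConfig fields")
        return cfg


def _load_inputs(cfg: RunConfig) -> tuple[Phylogeny, TraitTable, CommunityMatrix, pd.DataFrame]:
    if cfg.scenario is not None:
        tree, _, traits, community, meta = simulate_scenario(cfg.scenario)
        return tree, traits, community, meta
    tree = io.read_newick(cfg.tree_path)
    community = io.read_community(cfg.community_path, braun_blanquet=cfg.braun_blanquet)
    traits = io.read_traits(cfg.traits_path)
    meta = io.read_metadata(cfg.metadata_path)
    community = community.check_against_tree(tree, drop_unmatched=cfg.drop_unmatched)
    return tree, traits, community, meta


def _ols_table(alpha: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """Simple-OLS R²/sign/p of each alpha index against each predictor."""
    rows = []
    for index_name in alpha.columns:
        y = alpha[index_name].to_numpy(dtype=float)
        keep = np.isfinite(y)
        for var in env.columns:
            r2, sign, p = drivers.simple_ols(y[keep], env.loc[alpha.index[keep], var].to_numpy())
            rows.append(
                {"diversity_index": index_name, "variable": var, "r2": r2, "sign": sign, "p": p}
            )
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a map of stage name → output path."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}

    def save(df: pd.DataFrame, name: str, seed: int | None = None) -> None:
        path = out / name
        io.write_table(df, path, header_comment=f"config={chash} seed={seed}")
        outputs[name] = path

    try:
        t0 = time.time()
        logger.info("run start (config %s)", chash)
        tree, traits, community, meta = _load_inputs(cfg)
        logger.info(
            "inputs: %d tips, %d plots, %d species (%.1fs)",
            tree.n_tips, len(community.plot_ids), len(community.species_ids), time.time() - t0,
        )

        # stage: provenance
        (out / "provenance.json").write_text(
            json.dumps(asdict(cfg), indent=2, default=str) + "\n", encoding="utf-8"
        )

        # stage: phylogenetic signal
        t = time.time()
        sig = signal_results_frame(
            signal_table(tree, traits, n_perm=cfg.n_perm_signal, seed=cfg.seed_signal)
        )
        save(sig, "signal.tsv", cfg.seed_signal)
        logger.info("signal stage done (%.1fs)", time.time() - t)

        # stage: functional dendrogram
        t = time.time()
        dendro, pca = functional_dendrogram(traits, n_components=cfg.n_components)
        (out / "dendro.nwk").write_text(dendro.as_newick() + "\n", encoding="utf-8")
        outputs["dendro.nwk"] = out / "dendro.nwk"
        pca_tab = pca.loadings.copy()
        pca_tab.loc["explained_fraction"] = pca.explained_fraction[: pca.loadings.shape[1]]
        save(pca_tab, "pca.tsv")
        logger.info(
            "dendrogram stage done; %d components explain %.1f%% (%.1fs)",
            cfg.n_components, 100 * pca.cumulative_explained[cfg.n_components - 1], time.time() - t,
        )

        # stage: alpha and beta diversity (taxonomic, phylogenetic, functional)
        t = time.time()
        transects = meta["transect_id"] if cfg.pool == "transect" else None
        phylo_d = tree.patristic_distances()
        func_d = dendro.cophenetic()

        rich = diversity.richness_table(community)
        alpha_phylo = diversity.dispersion_profiles(
            phylo_d, community, "alpha", n_null=cfg.n_null, seed=cfg.seed_null, transects=transects
        )
        alpha_func = diversity.dispersion_profiles(
            func_d, community, "alpha", n_null=cfg.n_null, seed=cfg.seed_null + 1, transects=transects
        )
        save(rich.to_frame(), "alpha_taxonomic.tsv")
        save(alpha_phylo.set_index("plot"), "alpha_phylogenetic.tsv", cfg.seed_null)
        save(alpha_func.set_index("plot"), "alpha_functional.tsv", cfg.seed_null + 1)

        bc = diversity.bray_curtis_matrix(community)
        beta_taxo = pd.DataFrame(
            {
                "plot_a": [bc.labels[i] for i, j in zip(*np.triu_indices(len(bc), 1))],
                "plot_b": [bc.labels[j] for i, j in zip(*np.triu_indices(len(bc), 1))],
                "bray_curtis_dissimilarity": bc.condensed(),
                "bray_curtis_similarity": 1.0 - bc.condensed(),
            }
        )
        beta_phylo = diversity.dispersion_profiles(
            phylo_d, community, "beta", n_null=cfg.n_null, seed=cfg.seed_null + 2, transects=transects
        )
        beta_func = diversity.dispersion_profiles(
            func_d, community, "beta", n_null=cfg.n_null, seed=cfg.seed_null + 3, transects=transects
        )
        save(beta_taxo.set_index("plot_a"), "beta_taxonomic.tsv")
        save(beta_phylo.set_index("plot_a"), "beta_phylogenetic.tsv", cfg.seed_null + 2)
        save(beta_func.set_index("plot_a"), "beta_functional.tsv", cfg.seed_null + 3)
        logger.info("diversity stage done (%.1fs)", time.time() - t)

        # stage: drivers
        t = time.time()
        env = drivers.env_table(meta)
        alpha_table = pd.DataFrame(
            {
                "TAD": rich.astype(float),
                "PAD": alpha_phylo.set_index("plot")["nri"],
                "FAD": alpha_func.set_index("plot")["nri"],
            }
        )
        save(_ols_table(alpha_table, env).set_index("diversity_index"), "ols.tsv")

        # alpha: AICc importance + variation partitioning per response
        imp_rows, part_rows = [], []
        for name in alpha_table.columns:
            y = alpha_table[name].to_numpy(dtype=float)
            keep = np.isfinite(y)
            X = env.loc[alpha_table.index[keep]]
            mset = drivers.all_subsets_aicc(y[keep], X)
            imp = drivers.importance_values(mset)
            imp_rows.append(imp.rename(name))
            part = drivers.variation_partition_alpha(
                y[keep], X[["pc1_clim", "pc2_clim"]], X[["slope_t", "rar_t"]]
            )
            part_rows.append(
                {
                    "response": name,
                    "pure_climate": part.pure_a,
                    "shared": part.shared,
                    "pure_habitat": part.pure_b,
                    "unexplained": part.unexplained,
                }
            )

        # beta: Mantel, distance-matrix AICc importance, MRM partitioning —
        # analysed within transects (pairs never span transects)
        geo = drivers.geographic_distance(meta)
        dist_clim, dist_habit, dist_env = drivers.env_distances(env)
        sim = PairMatrix(bc.labels, np.where(np.eye(len(bc)), 0.0, 1.0 - bc.values))
        groups = (
            {t: list(meta.index[meta["transect_id"] == t]) for t in sorted(meta["transect_id"].unique())}
            if cfg.pool == "transect"
            else {"all": list(meta.index)}
        )
        mantel_rows = []
        for tname, plots_t in groups.items():
            beta_responses = {
                "TBD": sim.reindex(plots_t),  # Bray-Curtis similarity carrier
                "PBD": _pair_matrix_from_profiles(beta_phylo, plots_t),
                "FBD": _pair_matrix_from_profiles(beta_func, plots_t),
            }
            geo_t = geo.reindex(plots_t)
            env_t = dist_env.reindex(plots_t)
            predictors = {
                "dist_geo": geo_t,
                "dist_clim": dist_clim.reindex(plots_t),
                "dist_habit": dist_habit.reindex(plots_t),
            }
            for rname, resp in beta_responses.items():
                for pname, pred in predictors.items():
                    res = drivers.mantel(resp, pred, n_perm=cfg.n_perm_matrix, seed=cfg.seed_perm)
                    mantel_rows.append(
                        {"transect": tname, "diversity_index": rname,
                         "distance": pname, "r": res.r, "p": res.p}
                    )
                frame = drivers.distance_predictor_frame(predictors, resp.labels)
                mset = drivers.all_subsets_aicc(resp.condensed(), frame)
                imp_rows.append(drivers.importance_values(mset).rename(f"{rname}_{tname}"))
                part = drivers.variation_partition_beta(resp, geo_t, env_t)
                part_rows.append(
                    {
                        "response": f"{rname}_{tname}",
                        "pure_climate": np.nan,
                        "shared": part.shared,
                        "pure_habitat": np.nan,
                        "pure_geographic": part.pure_a,
                        "pure_environmental": part.pure_b,
                        "unexplained": part.unexplained,
                    }
                )
                mrm_res = drivers.mrm(
                    resp, {"dist_geo": geo_t, "dist_env": env_t},
                    n_perm=cfg.n_perm_matrix, seed=cfg.seed_perm,
                )
                logger.info(
                    "MRM %s/%s: R²=%.3f coefficients=%s",
                    rname, tname, mrm_res.r2, mrm_res.coefficients,
                )

        save(pd.DataFrame(mantel_rows).set_index("diversity_index"), "mantel.tsv", cfg.seed_perm)
        save(pd.concat(imp_rows, axis=1).T, "importance.tsv")
        save(pd.DataFrame(part_rows).set_index("response"), "partition.tsv")
        logger.info("drivers stage done (%.1fs)", time.time() - t)
        logger.info("run complete (%.1fs total)", time.time() - t0)
    except Exception:
        logger.exception("run failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs


def _pair_matrix_from_profiles(profiles: pd.DataFrame, plot_ids: list[str]) -> PairMatrix:
    """Square between-plot NRI matrix from a beta dispersion table.

    Only pairs with both plots in ``plot_ids`` are used (beta pairs are
    formed within transects, so the table never spans transect groups).
    """
    allowed = set(plot_ids)
    seen = set(profiles["plot_a"]) | set(profiles["plot_b"])
    plots = [p for p in plot_ids if p in seen]
    pos = {p: i for i, p in enumerate(plots)}
    values = np.zeros((len(plots), len(plots)))
    for _, row in profiles.iterrows():
        if row["plot_a"] in allowed and row["plot_b"] in allowed:
            i, j = pos[row["plot_a"]], pos[row["plot_b"]]
            values[i, j] = values[j, i] = row["nri"]
    return PairMatrix(labels=plots, values=values)
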