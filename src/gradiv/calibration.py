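"""Calibration and recovery experiments on synthetic data.

These are the package's own validation studies: null calibration of the NRI
under neutral assembly, type-I error of the permutation tests, parameter
recovery for Pagel's λ and Blomberg's K, and direction recovery for the
filtering and competition assembly scenarios.  Each experiment is
deterministic given its seed and returns plain floats, so the same routines
back both the test suite and the reproduction script.

Problem sizes are chosen so each experiment runs in seconds to a few minutes
on one CPU while leaving Monte-Carlo error well inside the bands checked by
the test suite; the replicate counts below are the package's reference
conditions and are documented in docs/methods.md.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor

from .datamodel import DistanceMatrix
from .diversity import dispersion_profiles
from .drivers import mantel
from .signal import _fit_lambda, _k_from_parts, phylo_vcv, signal_pvalue
from .simulate import ScenarioConfig, simulate_scenario, simulate_traits, simulate_tree

__all__ = [
    "neutral_nri_calibration",
    "scenario_mean_nri",
    "signal_pvalue_type1_rate",
    "mantel_type1_rate",
    "lambda_recovery",
    "blomberg_k_calibration",
]


def _spawn(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit child seeds derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _scenario_nri(
    scenario: str,
    n_replicates: int,
    n_plots: int,
    n_null: int,
    seed: int,
    lambda_true: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-plot NRI values and per-replicate means for one assembly scenario."""
    seeds = _spawn(seed, 2 * n_replicates)
    all_nri, rep_means = [], []
    for r in range(n_replicates):
        cfg = ScenarioConfig(
            n_species=60,
            n_plots=n_plots,
            scenario=scenario,
            lambda_true=lambda_true,
            seed=int(seeds[2 * r]),
        )
        tree, _, _, comm, _ = simulate_scenario(cfg)
        prof = dispersion_profiles(
            tree.patristic_distances(), comm, "alpha",
            n_null=n_null, seed=int(seeds[2 * r + 1]),
        )
        all_nri.extend(prof["nri"])
        rep_means.append(prof["nri"].mean())
    return np.asarray(all_nri), np.asarray(rep_means)


def neutral_nri_calibration(
    seed: int,
    n_replicates: int = 80,
    n_plots: int = 8,
    n_null: int = 999,
) -> dict[str, float]:
    """Mean alpha NRI and |NRI| > 1.96 rejection rate under neutral assembly.

    Communities are assembled with elevational optima independent of the
    phylogeny, so the tip-shuffle null is exact and both quantities estimate
    the null behaviour of the index.  Independent transect replicates are
    pooled because all plots of one replicate share a single tree and
    optimum draw.
    """
    nri, _ = _scenario_nri("neutral", n_replicates, n_plots, n_null, seed)
    return {
        "mean_nri": float(nri.mean()),
        "rejection_rate": float(np.mean(np.abs(nri) > 1.96)),
        "n_plots": int(nri.size),
    }


def scenario_mean_nri(
    scenario: str,
    seed: int,
    n_replicates: int = 10,
    n_plots: int = 25,
    n_null: int = 999,
) -> dict[str, float]:
    """Mean alpha NRI for a structured scenario with a one-sample test.

    The t-test is applied to replicate means (replicates are independent;
    plots within a replicate are not) against zero, one-sided in the
    direction the scenario predicts (filtering > 0, competition < 0).
    """
    nri, rep_means = _scenario_nri(scenario, n_replicates, n_plots, n_null, seed)
    alternative = "greater" if scenario == "filtering" else "less"
    t = stats.ttest_1samp(rep_means, 0.0, alternative=alternative)
    return {
        "mean_nri": float(nri.mean()),
        "p_value": float(t.pvalue),
        "n_plots": int(nri.size),
    }


def signal_pvalue_type1_rate(
    seed: int,
    n_trials: int = 1000,
    n_tips: int = 50,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of trials with p < alpha for traits with no phylogenetic signal.

    Traits are i.i.d. normal across tips (independent of the tree), so the
    tip-shuffle null holds exactly and the rejection rate should match alpha
    up to the discreteness of the +1-corrected permutation p-value.
    """
    seeds = _spawn(seed, n_trials + 1)
    tree = simulate_tree(n_tips, seed=int(seeds[-1]))
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for t in range(n_trials):
        x = pd.Series(rng.standard_normal(n_tips), index=tree.tips)
        p = signal_pvalue(tree, x, "K", n_perm=n_perm, seed=int(seeds[t]))
        hits += p < alpha
    return {"rate": hits / n_trials, "n_trials": n_trials}


def mantel_type1_rate(
    seed: int,
    n_trials: int = 1000,
    n_labels: int = 20,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the Mantel permutation test on independent distance matrices."""
    rng = np.random.default_rng(seed)
    labels = [f"u{i}" for i in range(n_labels)]
    hits = 0
    for t in range(n_trials):
        def rand_dm() -> DistanceMatrix:
            pts = rng.normal(size=(n_labels, 2))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(labels, d)

        res = mantel(rand_dm(), rand_dm(), n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        hits += res.p < alpha
    return {"rate": hits / n_trials, "n_trials": n_trials}


def lambda_recovery(
    lambda_true: float,
    seed: int,
    n_replicates: int = 200,
    n_tips: int = 200,
) -> dict[str, float]:
    """Mean maximum-likelihood λ̂ over replicate trees and trait simulations."""
    seeds = _spawn(seed, 2 * n_replicates)
    est = []
    for r in range(n_replicates):
        tree = simulate_tree(n_tips, seed=int(seeds[2 * r]))
        C, tips = phylo_vcv(tree)
        x = simulate_traits(
            tree, lambda_true, 1.0, seed=int(seeds[2 * r + 1]), n_traits=1
        ).to_numpy()[:, 0]
        est.append(_fit_lambda(C, x)[0])
    return {"mean_lambda_hat": float(np.mean(est)), "n_replicates": n_replicates}


def blomberg_k_calibration(
    seed: int,
    n_replicates: int = 500,
    n_tips: int = 100,
) -> dict[str, float]:
    """Mean Blomberg's K for Brownian-motion traits (theory: E[K] ≈ 1).

    All replicates share one tree; traits are drawn jointly and K is
    evaluated column-wise with the factorised solve.
    """
    tree = simulate_tree(n_tips, seed=seed)
    C, tips = phylo_vcv(tree)
    X = simulate_traits(tree, 1.0, 1.0, seed=seed + 1, n_traits=n_replicates).to_numpy()
    ks = _k_from_parts(C, cho_factor(C), X)
    return {"mean_k": float(np.mean(ks)), "n_replicates": n_replicates}
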