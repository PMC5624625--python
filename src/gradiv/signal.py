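"""Phylogenetic signal of functional traits: Blomberg's K and Pagel's λ.

Blomberg's K compares the observed phylogenetically corrected trait variance
with its Brownian-motion expectation on the same tree: K = 1 under Brownian
motion, K > 1 when relatives are more similar than BM predicts, K < 1 when
they are less similar.  Pagel's λ rescales the off-diagonal of the
phylogenetic variance–covariance matrix C: the maximum-likelihood λ on [0, 1]
measures how far trait covariance tracks shared ancestry (λ = 0 no signal,
λ = 1 Brownian motion).  Significance for either statistic comes from
permuting trait values across the tips of the tree (a tip-shuffle null),
with the +1-corrected upper-tail p-value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .datamodel import Phylogeny, TraitTable

__all__ = [
    "phylo_vcv",
    "blomberg_k",
    "pagel_lambda",
    "signal_pvalue",
    "signal_table",
    "SignalResult",
    "LambdaUnidentifiableWarning",
]


class LambdaUnidentifiableWarning(UserWarning):
    """λ has no information in the data (e.g. star phylogeny: C(λ) constant)."""


@dataclass
class SignalResult:
    """Per-trait signal statistics with permutation p-values."""

    trait_name: str
    k: float
    p_k: float
    lambda_hat: float
    loglik: float
    p_lambda: float
    n_perm: int
    seed: int


def phylo_vcv(phylogeny: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic variance–covariance matrix C.

    ``C[i, j]`` is the root-to-MRCA shared branch length of tips i and j and
    ``C[i, i]`` the root-to-tip distance; tips are ordered as
    ``phylogeny.tips``.  C is symmetric positive semidefinite by construction.
    """
    tips = phylogeny.tips
    index = {lab: i for i, lab in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))

    # node depth from root, then fill shared depth at each internal node
    depth: dict[int, float] = {id(phylogeny.tree.seed_node): 0.0}
    for node in phylogeny.tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    tipsets: dict[int, list[int]] = {}
    for node in phylogeny.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[id(node)]
            tipsets[id(node)] = [i]
        else:
            children = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        C[i, children[b]] = d
                        C[np.array(children[b]), i] = d
            tipsets[id(node)] = [i for ch in children for i in ch]
    if np.trace(C) <= 0:
        raise ValueError("tree has zero total depth")
    return C, list(tips)


def _align(phylogeny: Phylogeny, trait_values: pd.Series | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C, tips = phylo_vcv(phylogeny)
    if isinstance(trait_values, pd.Series):
        missing = [t for t in tips if t not in trait_values.index]
        if missing:
            raise ValueError(f"trait values missing for tips: {missing}")
        x = trait_values.loc[tips].to_numpy(dtype=float)
    else:
        x = np.asarray(trait_values, dtype=float)
        if x.shape != (len(tips),):
            raise ValueError("trait vector length does not match number of tips")
    return C, x


def _k_from_parts(C: np.ndarray, cho, x: np.ndarray) -> float:
    """K for trait column(s) x given C and its Cholesky factorisation."""
    n = C.shape[0]
    ones = np.ones(n)
    Cinv_ones = cho_solve(cho, ones)
    denom_ones = ones @ Cinv_ones
    a_hat = (Cinv_ones @ x) / denom_ones  # GLS mean, scalar or (B,)
    resid = x - (a_hat if np.ndim(x) == 1 else a_hat[np.newaxis, :])
    mse0 = np.sum(resid * resid, axis=0) if resid.ndim > 1 else resid @ resid
    Cinv_resid = cho_solve(cho, resid)
    mse = np.sum(resid * Cinv_resid, axis=0) if resid.ndim > 1 else resid @ Cinv_resid
    expected = (np.trace(C) - n / denom_ones) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (mse0 / mse) / expected


def blomberg_k(phylogeny: Phylogeny, trait_values: pd.Series | np.ndarray) -> float:
    """Blomberg's K for one trait.

    K is the ratio of the observed mean squared error of the trait about its
    GLS (phylogenetic) mean to the phylogenetically corrected mean squared
    error, divided by the Brownian-motion expectation of that ratio on the
    same tree, so K = 1 under Brownian motion regardless of topology.
    """
    C, x = _align(phylogeny, trait_values)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: zero phylogenetically corrected variance")
    cho = cho_factor(C)
    return float(_k_from_parts(C, cho, x))


def _lambda_scaled(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _lambda_loglik(C: np.ndarray, x: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of λ (GLS mean and σ² maximised analytically)."""
    n = len(x)
    Cl = _lambda_scaled(C, lam)
    try:
        cho = cho_factor(Cl)
    except np.linalg.LinAlgError:
        return -np.inf
    ones = np.ones(n)
    Cinv_ones = cho_solve(cho, ones)
    mu = (Cinv_ones @ x) / (ones @ Cinv_ones)
    resid = x - mu
    sigma2 = resid @ cho_solve(cho, resid) / n
    if sigma2 <= 0:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda(
    phylogeny: Phylogeny, trait_values: pd.Series | np.ndarray, tol: float = 1e-6
) -> tuple[float, float]:
    """Maximum-likelihood Pagel's λ on [0, 1] with its log-likelihood.

    The search is bounded at [0, 1], the scale on which λ is interpreted;
    values slightly above 1 can be likelihood-optimal on some trees but are
    not explored.  On a star phylogeny C(λ) does not depend on λ: the
    likelihood is flat, a :class:`LambdaUnidentifiableWarning` is emitted and
    ``lambda_hat`` is returned as NaN.
    """
    C, x = _align(phylogeny, trait_values)
    if np.ptp(x) == 0:
        raise ValueError("constant trait")
    off = C[~np.eye(len(x), dtype=bool)]
    if np.allclose(off, 0.0):
        warnings.warn("star phylogeny: lambda unidentifiable", LambdaUnidentifiableWarning)
        return float("nan"), _lambda_loglik(C, x, 0.0)
    return _fit_lambda(C, x, tol)


def _fit_lambda(C: np.ndarray, x: np.ndarray, tol: float = 1e-6) -> tuple[float, float]:
    res = minimize_scalar(
        lambda lam: -_lambda_loglik(C, x, lam),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": tol},
    )
    # the bounded search never evaluates the endpoints; boundary optima are common
    candidates = [(float(res.x), float(-res.fun))] + [
        (lam, _lambda_loglik(C, x, lam)) for lam in (0.0, 1.0)
    ]
    return max(candidates, key=lambda c: c[1])


def signal_pvalue(
    phylogeny: Phylogeny,
    trait_values: pd.Series | np.ndarray,
    statistic: str = "K",
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Tip-shuffle permutation p-value for K or λ.

    Trait values are permuted across tips ``n_perm`` times; the one-tailed
    upper p-value is ``(1 + #{null ≥ observed}) / (n_perm + 1)``.
    """
    if statistic not in {"K", "lambda"}:
        raise ValueError("statistic must be 'K' or 'lambda'")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives unstable p-values", UserWarning)
    rng = np.random.default_rng(seed)
    C, x = _align(phylogeny, trait_values)
    if statistic == "K":
        cho = cho_factor(C)
        observed = _k_from_parts(C, cho, x)
        X = np.column_stack([rng.permutation(x) for _ in range(n_perm)])
        null = _k_from_parts(C, cho, X)
    else:
        observed, _ = pagel_lambda(phylogeny, x)
        null = np.array(
            [_fit_lambda(C, rng.permutation(x), tol=1e-4)[0] for _ in range(n_perm)]
        )
    return float((1 + np.sum(null >= observed)) / (n_perm + 1))


def signal_table(
    phylogeny: Phylogeny,
    traits: TraitTable,
    n_perm: int = 1000,
    seed: int = 0,
    log_standardize: bool = True,
) -> list[SignalResult]:
    """K and λ with permutation p-values for every trait column.

    Traits are log-transformed and z-standardised by default (matching the
    treatment used for the functional dendrogram); both statistics are in
    fact invariant to affine transforms, so this only guards against
    numerical issues with heavily skewed raw values.
    """
    from .dendrogram import prepare_traits

    table = prepare_traits(traits) if log_standardize else traits.matrix()
    results = []
    for i, name in enumerate(table.columns):
        x = table[name]
        k = blomberg_k(phylogeny, x)
        lam, ll = pagel_lambda(phylogeny, x)
        p_k = signal_pvalue(phylogeny, x, "K", n_perm=n_perm, seed=seed + 2 * i)
        p_l = signal_pvalue(phylogeny, x, "lambda", n_perm=n_perm, seed=seed + 2 * i + 1)
        results.append(SignalResult(name, k, p_k, lam, ll, p_l, n_perm, seed))
    return results


def signal_results_frame(results: list[SignalResult]) -> pd.DataFrame:
    rows = [
        {
            "trait": r.trait_name,
            "blomberg_k": r.k,
            "p_k": r.p_k,
            "pagel_lambda": r.lambda_hat,
            "loglik": r.loglik,
            "p_lambda": r.p_lambda,
            "n_perm": r.n_perm,
            "seed": r.seed,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("trait")
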