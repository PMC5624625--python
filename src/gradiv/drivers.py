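"""Driver attribution for alpha and beta diversity.

Environmental predictors are reduced to four per-plot variables — two climate
PCA axes (seven climate variables, precipitation log-transformed, then
z-scored), log-slope and arcsine-sqrt rocky-area ratio — and, for beta
diversity, to three plot-pair distance matrices: geographic distance under an
equidistant cylindrical projection, climatic distance (Euclidean over the two
climate axes) and habitat distance (Euclidean over the two transformed
habitat variables).  Attribution combines simple OLS per predictor, simple
Mantel tests per distance matrix, all-subsets OLS with AICc-based Akaike
weights and per-variable importance (summed weights), variation partitioning
by partial regressions, and multiple regression on distance matrices (MRM)
with permutation significance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CLIMATE_COLUMNS, DistanceMatrix, PairMatrix
from .dendrogram import trait_pca

__all__ = [
    "EARTH_RADIUS_M",
    "climate_pca",
    "transform_habitat",
    "env_table",
    "simple_ols",
    "geographic_distance",
    "env_distances",
    "mantel",
    "all_subsets_aicc",
    "importance_values",
    "variation_partition_alpha",
    "variation_partition_beta",
    "mrm",
    "MantelResult",
    "ModelFit",
    "ModelSet",
    "MRMResult",
    "VariationPartition",
]

EARTH_RADIUS_M = 6_371_000.0

_PRECIP_COLUMNS = ("precip_annual", "precip_growing")


def climate_pca(metadata: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """First two PCA axes of the seven climate variables.

    The two precipitation variables are log-transformed, all seven variables
    are z-scored, and PCA is taken on their correlation matrix.  Returns the
    per-plot scores (columns ``pc1_clim``, ``pc2_clim``) and the per-axis
    explained fractions over all seven axes.
    """
    missing = [c for c in CLIMATE_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"missing climate columns: {missing}")
    clim = metadata[list(CLIMATE_COLUMNS)].astype(float).copy()
    for col in _PRECIP_COLUMNS:
        if (clim[col] <= 0).any():
            raise ValueError(f"{col} must be positive for the log transform")
        clim[col] = np.log(clim[col])
    sd = clim.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant climate column(s): {list(sd.index[sd == 0])}")
    z = (clim - clim.mean(axis=0)) / sd
    pca = trait_pca(z, n_components=2)
    scores = pca.scores.rename(columns={"PC1": "pc1_clim", "PC2": "pc2_clim"})
    return scores, pca.explained_fraction


def transform_habitat(
    slope: np.ndarray | float, rar: np.ndarray | float, offset: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Habitat transforms: slope → log(slope + c), RAR → arcsin(√RAR).

    The log offset ``c`` is 0 when all slopes are positive and 1 otherwise
    (so zero slopes map to 0); pass ``offset`` to fix it explicitly.
    """
    slope = np.asarray(slope, dtype=float)
    rar = np.asarray(rar, dtype=float)
    if np.any((rar < 0) | (rar > 1)):
        raise ValueError("rar outside [0, 1]")
    if np.any(slope < 0):
        raise ValueError("negative slope")
    c = offset if offset is not None else (0.0 if np.all(slope > 0) else 1.0)
    return np.log(slope + c), np.arcsin(np.sqrt(rar))


def env_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-plot predictor table: pc1_clim, pc2_clim, slope_t, rar_t."""
    scores, _ = climate_pca(metadata)
    slope_t, rar_t = transform_habitat(
        metadata["slope"].to_numpy(), metadata["rar"].to_numpy()
    )
    out = scores.copy()
    out["slope_t"] = slope_t
    out["rar_t"] = rar_t
    return out


def simple_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, int, float]:
    """Univariate OLS with intercept: (R², slope sign, two-sided slope p)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), int(np.sign(res.slope)), float(res.pvalue)


def geographic_distance(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise plot distances (m) under an equidistant cylindrical projection.

    x = R·lon·cos(lat₀), y = R·lat (radians) with lat₀ the mean plot latitude
    and R = 6,371,000 m, then Euclidean distance on (x, y).
    """
    lat = np.radians(metadata["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata["longitude"].to_numpy(dtype=float))
    lat0 = lat.mean()
    x = EARTH_RADIUS_M * lon * np.cos(lat0)
    y = EARTH_RADIUS_M * lat
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=[str(i) for i in metadata.index], values=d)


def _euclid(points: np.ndarray, labels: list[str]) -> DistanceMatrix:
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, values=d)


def env_distances(env: pd.DataFrame) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """(Dist_clim, Dist_habit, Dist_env) from the predictor table.

    Climatic distance is Euclidean over (pc1_clim, pc2_clim), habitat distance
    over (slope_t, rar_t), and environmental distance over all four, so
    Dist_env² = Dist_clim² + Dist_habit² holds exactly.
    """
    labels = [str(i) for i in env.index]
    clim = _euclid(env[["pc1_clim", "pc2_clim"]].to_numpy(dtype=float), labels)
    habit = _euclid(env[["slope_t", "rar_t"]].to_numpy(dtype=float), labels)
    full = _euclid(env[["pc1_clim", "pc2_clim", "slope_t", "rar_t"]].to_numpy(dtype=float), labels)
    return clim, habit, full


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None


def mantel(
    a: PairMatrix,
    b: PairMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Simple Mantel test: Pearson r over lower-triangle entries.

    Significance by simultaneously permuting rows and columns of ``b``,
    two-tailed on |r| with the +1 correction.
    """
    if a.labels != b.labels:
        b = b.reindex(a.labels)
    va = a.condensed()
    B = b.values
    vb = b.condensed()
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant distance matrix in Mantel test")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(a.labels)
    iu, ju = np.triu_indices(n, k=1)
    za = (va - va.mean()) / va.std()
    m = len(va)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = B[perm[iu], perm[ju]]
        r_null = float(za @ ((vp - vp.mean()) / vp.std())) / m
        if abs(r_null) >= abs(r_obs):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed)


@dataclass
class ModelFit:
    variables: tuple[str, ...]
    coefficients: dict[str, float]
    r2: float
    aicc: float
    delta_aicc: float = field(default=np.nan)
    weight: float = field(default=np.nan)


@dataclass
class ModelSet:
    models: list[ModelFit]
    best: ModelFit

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variables": "+".join(m.variables),
                "k": len(m.variables),
                "r2": m.r2,
                "aicc": m.aicc,
                "delta_aicc": m.delta_aicc,
                "weight": m.weight,
            }
            for m in self.models
        ]
        return pd.DataFrame(rows)


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(coefficients incl. intercept, RSS, R²) by least squares."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef, rss, r2


def _aicc(rss: float, n: int, k_predictors: int) -> float:
    """AICc for a Gaussian OLS model: p counts the intercept and the variance."""
    p = k_predictors + 2
    if n - p - 1 <= 0:
        raise ValueError(f"n={n} too small for {k_predictors} predictors")
    rss = max(rss, 1e-300)  # guard exact fits
    return float(n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1))


def all_subsets_aicc(y: np.ndarray, predictors: pd.DataFrame) -> ModelSet:
    """Fit every non-empty predictor subset by OLS and weight by AICc.

    With k predictors there are 2^k − 1 models (the intercept-only model is
    excluded).  Akaike weights are exp(−Δᵢ/2) normalised over the set.  For
    distance-matrix responses, pass lower-triangle vectors (see
    :func:`distance_predictor_frame`).
    """
    names = list(predictors.columns)
    k = len(names)
    if not 1 <= k <= 10:
        raise ValueError("need 1-10 candidate predictors")
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = predictors.to_numpy(dtype=float)
    cond = np.linalg.cond(np.column_stack([np.ones(n), X]))
    if cond > 1e10:
        warnings.warn(f"collinear predictors (condition number {cond:.3g})", UserWarning)

    fits: list[ModelFit] = []
    for r in range(1, k + 1):
        for subset in combinations(range(k), r):
            coef, rss, r2 = _ols_fit(y, X[:, subset])
            vars_ = tuple(names[i] for i in subset)
            coefs = {"intercept": float(coef[0])}
            coefs.update({v: float(c) for v, c in zip(vars_, coef[1:])})
            fits.append(ModelFit(vars_, coefs, r2, _aicc(rss, n, r)))

    best_aicc = min(m.aicc for m in fits)
    raw = np.array([np.exp(-(m.aicc - best_aicc) / 2.0) for m in fits])
    weights = raw / raw.sum()
    for m, w in zip(fits, weights):
        m.delta_aicc = m.aicc - best_aicc
        m.weight = float(w)
    best = min(fits, key=lambda m: m.aicc)
    return ModelSet(models=fits, best=best)


def importance_values(model_set: ModelSet) -> pd.Series:
    """Per-variable importance: sum of Akaike weights over models containing it."""
    names = sorted({v for m in model_set.models for v in m.variables})
    imp = {
        v: float(sum(m.weight for m in model_set.models if v in m.variables))
        for v in names
    }
    return pd.Series(imp, name="importance")


@dataclass
class VariationPartition:
    """R² decomposition into pure and shared fractions of two predictor blocks."""

    pure_a: float
    shared: float
    pure_b: float
    unexplained: float

    @property
    def r2_full(self) -> float:
        return self.pure_a + self.shared + self.pure_b


def _partition_from_r2(r2_a: float, r2_b: float, r2_ab: float) -> VariationPartition:
    return VariationPartition(
        pure_a=r2_ab - r2_b,
        shared=r2_a + r2_b - r2_ab,
        pure_b=r2_ab - r2_a,
        unexplained=1.0 - r2_ab,
    )


def variation_partition_alpha(
    y: np.ndarray, block_a: pd.DataFrame, block_b: pd.DataFrame
) -> VariationPartition:
    """Variation partitioning of an alpha-diversity response by partial regressions.

    ``pure_a = R²(a+b) − R²(b)``, ``pure_b = R²(a+b) − R²(a)``,
    ``shared = R²(a) + R²(b) − R²(a+b)``; fractions are unadjusted R².
    """
    shared_cols = set(block_a.columns) & set(block_b.columns)
    if shared_cols:
        raise ValueError(f"blocks must be disjoint; shared: {sorted(shared_cols)}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    k_full = block_a.shape[1] + block_b.shape[1]
    if n - (k_full + 2) - 1 <= 0:
        raise ValueError("too few observations for the full model")
    _, _, r2_a = _ols_fit(y, block_a.to_numpy(dtype=float))
    _, _, r2_b = _ols_fit(y, block_b.to_numpy(dtype=float))
    _, _, r2_ab = _ols_fit(
        y, np.column_stack([block_a.to_numpy(dtype=float), block_b.to_numpy(dtype=float)])
    )
    return _partition_from_r2(r2_a, r2_b, r2_ab)


def distance_predictor_frame(predictors: dict[str, PairMatrix], labels: list[str]) -> pd.DataFrame:
    """Lower-triangle vectors of predictor distance matrices as a DataFrame."""
    return pd.DataFrame(
        {name: dm.reindex(labels).condensed() for name, dm in predictors.items()}
    )


@dataclass
class MRMResult:
    coefficients: dict[str, float]
    r2: float
    p_values: dict[str, float]
    n_perm: int
    seed: int | None


def mrm(
    dist_y: PairMatrix,
    predictors: dict[str, PairMatrix],
    n_perm: int = 999,
    seed: int | None = None,
) -> MRMResult:
    """Multiple regression on distance matrices.

    OLS of the response's lower-triangle vector on the predictors' vectors;
    coefficient significance by permuting rows/columns of the response matrix
    and refitting, two-tailed on |coefficient| with the +1 correction.
    """
    labels = dist_y.labels
    Xf = distance_predictor_frame(predictors, labels)
    names = list(Xf.columns)
    X = Xf.to_numpy(dtype=float)
    y = dist_y.condensed()
    if any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        raise ValueError("zero-variance predictor distance matrix")
    coef, _, r2 = _ols_fit(y, X)

    rng = np.random.default_rng(seed)
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    Y = dist_y.values
    design = np.column_stack([np.ones(len(y)), X])
    pinv = np.linalg.pinv(design)
    exceed = np.zeros(len(coef))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = Y[perm[iu], perm[ju]]
        cp = pinv @ yp
        exceed += np.abs(cp) >= np.abs(coef)
    p = (1 + exceed) / (n_perm + 1)
    coefs = {"intercept": float(coef[0]), **{v: float(c) for v, c in zip(names, coef[1:])}}
    pvals = {"intercept": float(p[0]), **{v: float(q) for v, q in zip(names, p[1:])}}
    return MRMResult(coefficients=coefs, r2=float(r2), p_values=pvals, n_perm=n_perm, seed=seed)


def variation_partition_beta(
    dist_y: PairMatrix, dist_a: PairMatrix, dist_b: PairMatrix
) -> VariationPartition:
    """Variation partitioning of a beta-diversity (distance) response.

    Same algebra as the alpha version but with MRM R² values computed on the
    lower-triangle vectors, blocks being single distance matrices.
    """
    labels = dist_y.labels
    y = dist_y.condensed()
    va = dist_a.reindex(labels).condensed()
    vb = dist_b.reindex(labels).condensed()
    _, _, r2_a = _ols_fit(y, va[:, None])
    _, _, r2_b = _ols_fit(y, vb[:, None])
    _, _, r2_ab = _ols_fit(y, np.column_stack([va, vb]))
    return _partition_from_r2(r2_a, r2_b, r2_ab)
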