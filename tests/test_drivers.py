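import numpy as np
import pandas as pd
import pytest

from gradiv.datamodel import DistanceMatrix, PairMatrix
from gradiv.drivers import (
    EARTH_RADIUS_M,
    all_subsets_aicc,
    climate_pca,
    env_distances,
    env_table,
    geographic_distance,
    importance_values,
    mantel,
    mrm,
    simple_ols,
    transform_habitat,
    variation_partition_alpha,
    variation_partition_beta,
)
from gradiv.simulate import ScenarioConfig, simulate_scenario


@pytest.fixture(scope="module")
def scenario_meta():
    cfg = ScenarioConfig(n_species=20, n_plots=30, seed=2)
    return simulate_scenario(cfg)[4]


class TestClimatePCA:
    def test_two_latent_factors_retained(self, scenario_meta):
        """Synthetic climate is built from elevation + moisture, so two axes suffice."""
        scores, explained = climate_pca(scenario_meta)
        assert explained[:2].sum() > 0.95
        assert list(scores.columns) == ["pc1_clim", "pc2_clim"]

    def test_constant_column_rejected(self, scenario_meta):
        meta = scenario_meta.copy()
        meta["temp_annual"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            climate_pca(meta)

    def test_collinear_pair_spans_one_axis(self):
        rng = np.random.default_rng(0)
        n = 40
        z = rng.normal(size=n)
        meta = pd.DataFrame(
            {
                "temp_annual": z,
                "temp_january": 2 * z + 1,  # exactly collinear with temp_annual
                "temp_august": rng.normal(size=n),
                "temp_growing": rng.normal(size=n),
                "temp_range": rng.normal(size=n),
                "precip_annual": np.exp(rng.normal(size=n)),
                "precip_growing": np.exp(rng.normal(size=n)),
            }
        )
        _, explained = climate_pca(meta)
        # 7 columns but only 6 independent directions
        assert explained[-1] == pytest.approx(0.0, abs=1e-10)


class TestHabitatTransforms:
    def test_arcsine_sqrt_endpoints(self):
        _, r0 = transform_habitat(10.0, 0.0)
        _, r1 = transform_habitat(10.0, 1.0)
        assert float(r0) == pytest.approx(0.0)
        assert float(r1) == pytest.approx(np.pi / 2)

    def test_arcsine_sqrt_midpoint(self):
        _, r = transform_habitat(10.0, 0.5)
        assert float(r) == pytest.approx(np.pi / 4)

    def test_zero_slope_offset(self):
        s, _ = transform_habitat(np.array([0.0, 5.0]), np.array([0.1, 0.2]))
        assert float(s[0]) == pytest.approx(0.0)  # offset 1 applied automatically

    def test_positive_slopes_no_offset(self):
        s, _ = transform_habitat(np.array([1.0, np.e]), np.array([0.1, 0.2]))
        np.testing.assert_allclose(s, [0.0, 1.0])

    def test_rar_out_of_range(self):
        with pytest.raises(ValueError):
            transform_habitat(5.0, 1.2)


class TestSimpleOLS:
    def test_exact_fit(self):
        x = np.arange(10.0)
        r2, sign, p = simple_ols(2 * x, x)
        assert r2 == pytest.approx(1.0)
        assert sign == 1

    def test_negative_slope_sign(self):
        rng = np.random.default_rng(1)
        x = np.arange(50.0)
        r2, sign, p = simple_ols(-x + rng.normal(0, 1, 50), x)
        assert sign == -1
        assert p < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            simple_ols(np.arange(5.0), np.ones(5))


class TestGeographicDistance:
    def _meta(self, lats, lons):
        return pd.DataFrame({"latitude": lats, "longitude": lons},
                            index=[f"p{i}" for i in range(len(lats))])

    def test_identical_coordinates(self):
        d = geographic_distance(self._meta([38.0, 38.0], [128.0, 128.0]))
        assert d.values[0, 1] == 0.0

    def test_one_degree_latitude(self):
        d = geographic_distance(self._meta([38.0, 39.0], [128.0, 128.0]))
        assert d.values[0, 1] == pytest.approx(EARTH_RADIUS_M * np.pi / 180, rel=1e-9)

    def test_one_degree_longitude_at_lat(self):
        d = geographic_distance(self._meta([38.0, 38.0], [128.0, 129.0]))
        expected = EARTH_RADIUS_M * np.pi / 180 * np.cos(np.radians(38.0))
        assert d.values[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_agrees_with_haversine_at_short_range(self):
        rng = np.random.default_rng(3)
        lats = 38.0 + rng.uniform(-0.2, 0.2, 12)
        lons = 128.0 + rng.uniform(-0.2, 0.2, 12)
        d = geographic_distance(self._meta(lats, lons)).values
        lat_r, lon_r = np.radians(lats), np.radians(lons)
        dlat = lat_r[:, None] - lat_r[None, :]
        dlon = lon_r[:, None] - lon_r[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat_r)[:, None] * np.cos(lat_r)[None, :] * np.sin(dlon / 2) ** 2
        )
        hav = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))
        mask = (hav > 0) & (hav < 50_000)
        assert np.all(np.abs(d[mask] - hav[mask]) / hav[mask] < 0.01)


class TestEnvDistances:
    def test_pythagorean_identity(self, scenario_meta):
        clim, habit, full = env_distances(env_table(scenario_meta))
        np.testing.assert_allclose(
            full.values**2, clim.values**2 + habit.values**2, atol=1e-9
        )

    def test_single_axis_difference(self):
        env = pd.DataFrame(
            {"pc1_clim": [0.0, 3.0], "pc2_clim": [1.0, 1.0],
             "slope_t": [2.0, 2.0], "rar_t": [0.3, 0.3]},
            index=["p1", "p2"],
        )
        clim, habit, full = env_distances(env)
        assert clim.values[0, 1] == pytest.approx(3.0)
        assert habit.values[0, 1] == 0.0
        assert full.values[0, 1] == pytest.approx(3.0)


class TestMantel:
    def test_self_correlation_is_one(self, random_distance):
        res = mantel(random_distance, random_distance, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_affine_invariance(self, random_distance):
        vals = 2 * random_distance.values + 5.0
        np.fill_diagonal(vals, 0.0)
        other = DistanceMatrix(random_distance.labels, vals)
        res = mantel(random_distance, other, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_r_matches_streaming_pearson_oracle(self, random_distance):
        """Mantel r equals an independently computed Pearson correlation."""
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 2))
        d2 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d2, 0.0)
        other = DistanceMatrix(random_distance.labels, d2)
        res = mantel(random_distance, other, n_perm=9, seed=0)
        # streaming formula: r = (n·Σxy − ΣxΣy)/sqrt((n·Σx²−(Σx)²)(n·Σy²−(Σy)²))
        x = random_distance.condensed()
        y = other.condensed()
        n = len(x)
        sx, sy = x.sum(), y.sum()
        sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
        r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        assert res.r == pytest.approx(r, abs=1e-12)

    def test_same_seed_reproducible(self, random_distance):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(10, 2))
        d2 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d2, 0.0)
        other = DistanceMatrix(random_distance.labels, d2)
        p1 = mantel(random_distance, other, n_perm=99, seed=5).p
        p2 = mantel(random_distance, other, n_perm=99, seed=5).p
        assert p1 == p2

    def test_constant_matrix_rejected(self, random_distance):
        flat = np.full((10, 10), 2.0)
        np.fill_diagonal(flat, 0.0)
        with pytest.raises(ValueError, match="constant"):
            mantel(random_distance, DistanceMatrix(random_distance.labels, flat))


class TestAllSubsets:
    @pytest.mark.parametrize("k,expected", [(4, 15), (3, 7)])
    def test_model_counts(self, k, expected):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, k)), columns=[f"v{i}" for i in range(k)])
        y = rng.normal(size=50)
        assert len(all_subsets_aicc(y, X).models) == expected

    def test_weights_sum_to_one_and_best_delta_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 0.5, 60)
        ms = all_subsets_aicc(y, X)
        assert sum(m.weight for m in ms.models) == pytest.approx(1.0, abs=1e-9)
        assert ms.best.delta_aicc == 0.0
        assert min(m.delta_aicc for m in ms.models) == 0.0

    def test_exact_predictor_wins(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = 3.0 * X["b"].to_numpy() + rng.normal(0, 0.01, 80)
        ms = all_subsets_aicc(y, X)
        assert ms.best.variables == ("b",)

    def test_ranking_invariant_to_shifting_response(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(0, 1, 40)
        rank1 = [m.variables for m in sorted(all_subsets_aicc(y, X).models, key=lambda m: m.aicc)]
        rank2 = [m.variables for m in sorted(all_subsets_aicc(y + 100.0, X).models, key=lambda m: m.aicc)]
        assert rank1 == rank2

    def test_collinearity_warns(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.warns(UserWarning, match="collinear"):
            all_subsets_aicc(rng.normal(size=30), X)


class TestImportance:
    def test_single_predictor_importance_one(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"only": rng.normal(size=30)})
        imp = importance_values(all_subsets_aicc(rng.normal(size=30), X))
        assert imp["only"] == pytest.approx(1.0)

    def test_duplicate_predictors_symmetric(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=40)
        y = a + rng.normal(0, 0.3, 40)
        X = pd.DataFrame({"a1": a, "a2": a.copy()})
        with pytest.warns(UserWarning, match="collinear"):
            imp = importance_values(all_subsets_aicc(y, X))
        assert imp["a1"] == pytest.approx(imp["a2"], rel=1e-6)

    def test_strong_beats_noise(self):
        rng = np.random.default_rng(7)
        n = 200
        strong = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = strong + rng.normal(0, 0.5, n)
        imp = importance_values(all_subsets_aicc(y, pd.DataFrame({"strong": strong, "noise": noise})))
        assert imp["strong"] > 0.95 > imp["noise"]


class TestVariationPartitioning:
    def test_fraction_identity(self):
        rng = np.random.default_rng(8)
        n = 100
        a = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a1", "a2"])
        b = pd.DataFrame(rng.normal(size=(n, 2)), columns=["b1", "b2"])
        y = a["a1"].to_numpy() + b["b1"].to_numpy() + rng.normal(0, 1, n)
        vp = variation_partition_alpha(y, a, b)
        assert vp.pure_a + vp.shared + vp.pure_b + vp.unexplained == pytest.approx(1.0, abs=1e-9)

    def test_noise_block_contributes_nothing(self):
        rng = np.random.default_rng(9)
        n = 2000
        a = pd.DataFrame({"a1": rng.normal(size=n)})
        b = pd.DataFrame({"b1": rng.normal(size=n)})
        y = 2 * a["a1"].to_numpy() + rng.normal(0, 0.5, n)
        vp = variation_partition_alpha(y, a, b)
        assert abs(vp.pure_b) < 0.01
        assert vp.pure_a > 0.8

    def test_redundant_blocks_all_shared(self):
        rng = np.random.default_rng(10)
        n = 100
        a = pd.DataFrame({"a1": rng.normal(size=n)})
        b = pd.DataFrame({"b1": a["a1"].to_numpy() * 1.0})
        y = a["a1"].to_numpy() + rng.normal(0, 0.3, n)
        vp = variation_partition_alpha(y, a, b)
        assert abs(vp.pure_a) < 1e-6 and abs(vp.pure_b) < 1e-6
        assert vp.shared > 0.5

    def test_overlapping_blocks_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="disjoint"):
            variation_partition_alpha(np.arange(3.0), df, df)

    def test_beta_version_mirrors_alpha_algebra(self, random_distance):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 2))
        d2 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d2, 0.0)
        other = DistanceMatrix(random_distance.labels, d2)
        vp = variation_partition_beta(random_distance, random_distance, other)
        assert vp.pure_a + vp.shared + vp.pure_b + vp.unexplained == pytest.approx(1.0, abs=1e-9)
        assert vp.pure_a + vp.shared + vp.pure_b == pytest.approx(1.0, abs=1e-9)  # self-explained


class TestMRM:
    def test_exact_predictor(self, random_distance):
        res = mrm(random_distance, {"self": random_distance}, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients["self"] == pytest.approx(1.0)
        assert res.p_values["self"] == pytest.approx(1 / 100)

    def test_same_seed_reproducible(self, random_distance):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 2))
        d2 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d2, 0.0)
        other = DistanceMatrix(random_distance.labels, d2)
        r1 = mrm(random_distance, {"x": other}, n_perm=99, seed=3)
        r2 = mrm(random_distance, {"x": other}, n_perm=99, seed=3)
        assert r1.p_values == r2.p_values

    def test_accepts_signed_pair_matrix(self, random_distance):
        vals = random_distance.values - random_distance.values.mean()
        np.fill_diagonal(vals, 0.0)
        signed = PairMatrix(random_distance.labels, (vals + vals.T) / 2)
        res = mrm(signed, {"d": random_distance}, n_perm=19, seed=0)
        assert np.isfinite(res.r2)
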