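import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from narweb.env_drivers import (
    AdjacencySpec,
    bray_curtis_pair,
    climate_summary,
    commonality_analysis,
    fit_z_regression,
    morans_i_layer,
    region_bray_curtis,
    region_habitat_clustering,
    select_predictors,
)
from narweb.grid_io import ClimateRaster, GridSpec, HabitatRaster
from narweb.synthetic_data import gen_habitat


def brute_force_morans_i(x, grid, region, scheme="rook"):
    """Literal double-sum evaluation of the autocorrelation formula."""
    cells = [int(c) for c in grid.region_cells(region)]
    xv = np.asarray(x, float)[cells]
    n = len(cells)
    xbar = xv.mean()
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    pos = {cell: k for k, cell in enumerate(cells)}
    num = 0.0
    W = 0
    for i, ci in enumerate(cells):
        r, c = divmod(ci, grid.n_cols)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                j = pos.get(rr * grid.n_cols + cc)
                if j is not None:
                    W += 1
                    num += (xv[i] - xbar) * (xv[j] - xbar)
    den = ((xv - xbar) ** 2).sum()
    if den == 0 or W == 0:
        return None
    return (n / W) * num / den


class TestBrayCurtis:
    def test_identical(self):
        assert bray_curtis_pair([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint(self):
        assert bray_curtis_pair([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_worked_triple(self):
        assert bray_curtis_pair([0.6, 0.4, 0.0], [0.2, 0.3, 0.5]) == pytest.approx(0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_pair([-0.1, 1.1], [0.5, 0.5])

    def test_richness_convention(self):
        # counts: 2 and 3 habitats present; C = 0.2 + 0.3 = 0.5
        got = bray_curtis_pair(
            [0.6, 0.4, 0.0], [0.2, 0.3, 0.5], convention="richness"
        )
        assert got == pytest.approx(1.0 - 2 * 0.5 / 5)

    def test_richness_equals_abundance_on_one_hot(self):
        a = bray_curtis_pair([1.0, 0.0], [0.0, 1.0], convention="richness")
        b = bray_curtis_pair([1.0, 0.0], [0.0, 1.0])
        assert a == b == 1.0

    @given(
        st.lists(st.floats(0, 1), min_size=3, max_size=3),
        st.lists(st.floats(0, 1), min_size=3, max_size=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, u, v):
        if sum(u) == 0 and sum(v) == 0:
            return
        a = bray_curtis_pair(u, v)
        b = bray_curtis_pair(v, u)
        assert a == pytest.approx(b)
        assert -1e-12 <= a <= 1 + 1e-12


class TestRegionBrayCurtis:
    def test_two_cell_region(self):
        grid = GridSpec(1, 2)
        hab = HabitatRaster(
            grid=grid,
            class_ids=("a", "b"),
            proportions=np.array([[0.6, 0.4], [0.2, 0.8]]),
        )
        expected = bray_curtis_pair([0.6, 0.4], [0.2, 0.8])
        val, est = region_bray_curtis(hab, "R1")
        assert val == pytest.approx(expected)
        assert not est

    def test_identical_cells_zero(self):
        grid = GridSpec(3, 3)
        hab = HabitatRaster(
            grid=grid, class_ids=("a",), proportions=np.ones((9, 1))
        )
        val, _ = region_bray_curtis(hab, "R1")
        assert val == pytest.approx(0.0)

    def test_single_cell_missing(self):
        grid = GridSpec(1, 1)
        hab = HabitatRaster(grid=grid, class_ids=("a",), proportions=np.ones((1, 1)))
        assert region_bray_curtis(hab, "R1") == (None, False)

    def test_exact_matches_pair_oracle(self):
        hab = gen_habitat(GridSpec(5, 5), 3, 0.5, seed=2)
        val, est = region_bray_curtis(hab, "R1")
        cells = hab.grid.region_cells("R1")
        pairs = [
            bray_curtis_pair(hab.proportions[i], hab.proportions[j])
            for i, j in itertools.combinations(cells, 2)
        ]
        assert not est
        assert val == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_richness_convention_region_mean(self):
        grid = GridSpec(1, 3)
        rng = np.random.default_rng(2)
        props = rng.dirichlet([3.0, 3.0], size=3)
        hab = HabitatRaster(grid=grid, class_ids=("a", "b"), proportions=props)
        val, _ = region_bray_curtis(hab, "R1", convention="richness")
        oracle = np.mean(
            [
                bray_curtis_pair(props[i], props[j], convention="richness")
                for i, j in itertools.combinations(range(3), 2)
            ]
        )
        assert val == pytest.approx(oracle, abs=1e-12)

    def test_subsampled_close_to_exact(self):
        """Sampled estimate within 0.02 of the exact mean on a 40-cell
        region (20 seeds)."""
        grid = GridSpec(5, 8)
        rng = np.random.default_rng(9)
        props = rng.dirichlet([5.0] * 4, size=40)
        hab = HabitatRaster(grid=grid, class_ids=("a", "b", "c", "d"), proportions=props)
        exact, _ = region_bray_curtis(hab, "R1", pair_budget=10_000)
        for seed in range(20):
            est, flagged = region_bray_curtis(hab, "R1", pair_budget=500, seed=seed)
            assert flagged
            assert abs(est - exact) < 0.02


class TestMoransI:
    def test_constant_layer_undefined(self):
        grid = GridSpec(3, 3)
        assert morans_i_layer(np.ones(9), grid, "R1") is None

    def test_checkerboard_rook(self):
        grid = GridSpec(6, 6)
        x = np.array([(r + c) % 2 for r in range(6) for c in range(6)], float)
        assert morans_i_layer(x, grid, "R1") == pytest.approx(-1.0)

    def test_2x2_single_presence(self):
        grid = GridSpec(2, 2)
        x = np.array([1.0, 0.0, 0.0, 0.0])
        assert morans_i_layer(x, grid, "R1") == pytest.approx(-1 / 3)

    def test_brute_force_agreement(self):
        """Exact agreement with the literal double sum on 100 random 10x10
        layers."""
        rng = np.random.default_rng(11)
        grid = GridSpec(10, 10)
        for _ in range(100):
            x = (rng.random(100) < rng.uniform(0.2, 0.8)).astype(float)
            expected = brute_force_morans_i(x, grid, "R1")
            got = morans_i_layer(x, grid, "R1")
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_queen_adjacency(self):
        rng = np.random.default_rng(3)
        grid = GridSpec(8, 8)
        x = (rng.random(64) < 0.5).astype(float)
        got = morans_i_layer(x, grid, "R1", AdjacencySpec("queen"))
        assert got == pytest.approx(
            brute_force_morans_i(x, grid, "R1", scheme="queen"), abs=1e-12
        )

    def test_region_restriction(self):
        labels = ["A"] * 8 + ["outside"] * 8
        grid = GridSpec(4, 4, region_label=tuple(labels))
        rng = np.random.default_rng(5)
        x = (rng.random(16) < 0.5).astype(float)
        got = morans_i_layer(x, grid, "A")
        assert got == pytest.approx(brute_force_morans_i(x, grid, "A"), abs=1e-12)


class TestHabitatClustering:
    def test_compact_half_positive(self):
        grid = GridSpec(6, 6)
        props = np.zeros((36, 2))
        for cell in range(36):
            props[cell, 0 if cell % 6 < 3 else 1] = 1.0
        hab = HabitatRaster(grid=grid, class_ids=("a", "b"), proportions=props)
        assert region_habitat_clustering(hab, "R1") > 0

    def test_single_class_undefined(self):
        hab = gen_habitat(GridSpec(4, 4), 1, 0.5, seed=0)
        assert region_habitat_clustering(hab, "R1") is None

    def test_threshold_invariant_on_one_hot(self):
        hab = gen_habitat(GridSpec(8, 8), 3, 0.6, seed=1)
        a = region_habitat_clustering(hab, "R1", presence_threshold=0.0)
        b = region_habitat_clustering(hab, "R1", presence_threshold=0.5)
        assert a == pytest.approx(b)


class TestClimateSummary:
    def _raster(self, values):
        n = len(values)
        grid = GridSpec(1, n)
        return ClimateRaster(grid=grid, variables={"t": np.asarray(values, float)})

    def test_constant(self):
        out = climate_summary(self._raster([4.0, 4.0, 4.0]), "R1")
        assert out["t"] == (4.0, 0.0)

    def test_two_values(self):
        mean, sd = climate_summary(self._raster([0.0, 10.0]), "R1")["t"]
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(np.sqrt(50.0))

    def test_single_cell_sd_zero(self):
        assert climate_summary(self._raster([3.0]), "R1")["t"][1] == 0.0

    def test_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            vals = rng.normal(size=rng.integers(2, 30))
            mean, sd = climate_summary(self._raster(vals), "R1")["t"]
            m = sum(vals) / len(vals)
            v = sum((x - m) ** 2 for x in vals) / (len(vals) - 1)
            assert mean == pytest.approx(m, abs=1e-12)
            assert sd == pytest.approx(np.sqrt(v), abs=1e-12)


class TestCommonality:
    def test_single_predictor(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        y = 2 * X["a"].to_numpy() + rng.normal(0, 0.5, 20)
        ca = commonality_analysis(X, y)
        assert ca.unique_effect("a") == pytest.approx(ca.full_r2)
        assert len(ca.coefficients) == 1

    def test_orthogonal_predictors(self):
        n = 32
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"a": a, "b": b})
        y = 1.0 * a + 0.5 * b
        ca = commonality_analysis(X, y)
        assert ca.coefficients[frozenset({"a", "b"})] == pytest.approx(0.0, abs=1e-10)
        assert ca.unique_effect("a") == pytest.approx(
            ca.subset_r2[frozenset({"a"})], abs=1e-10
        )

    def test_sum_identity_random_designs(self):
        rng = np.random.default_rng(42)
        for p in (2, 3, 4, 5, 6):
            X = pd.DataFrame(
                rng.normal(size=(30, p)), columns=[f"x{i}" for i in range(p)]
            )
            y = rng.normal(size=30) + X.sum(axis=1).to_numpy()
            ca = commonality_analysis(X, y)
            assert sum(ca.coefficients.values()) == pytest.approx(
                ca.full_r2, abs=1e-10
            )
            assert len(ca.coefficients) == 2**p - 1

    def test_collinear_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank-deficient"):
            commonality_analysis(X, rng.normal(size=20))


class TestZRegression:
    def test_exact_linear(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) ** 2})
        y = 2.0 + 0.5 * X["a"] - 0.1 * X["b"]
        out = fit_z_regression(X, y)
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        coef = dict(zip(out["term"], out["coef"]))
        assert coef["a"] == pytest.approx(0.5, abs=1e-8)

    def test_coefficient_recovery_with_noise(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(
            {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        )
        y = 0.54 * X["a"] + 0.06 * X["b"] + rng.normal(0, 0.02, 10)
        out = fit_z_regression(X, y).set_index("term")
        for term, truth in (("a", 0.54), ("b", 0.06)):
            assert abs(out.loc[term, "coef"] - truth) <= 2 * out.loc[term, "se"]
        assert out["df_resid"].iloc[0] == 7

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12)})
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 12)
        base = fit_z_regression(X, y)
        perm = rng.permutation(12)
        other = fit_z_regression(X.iloc[perm].reset_index(drop=True), y[perm])
        np.testing.assert_allclose(base["coef"], other["coef"], atol=1e-10)

    def test_collinear_error(self):
        a = np.arange(10.0)
        X = pd.DataFrame({"a": a, "b": 3 * a})
        with pytest.raises(ValueError, match="collinear"):
            fit_z_regression(X, a)

    def test_sign_recovery_in_constructed_scenarios(self):
        """z built to rise with habitat clustering and temperature SD ->
        both coefficients positive in >= 80% of seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng([seed, 55])
            n = 10
            clustering = rng.uniform(0, 1, n)
            temp_sd = rng.uniform(0, 5, n)
            z = 0.5 * clustering + 0.06 * temp_sd + rng.normal(0, 0.03, n)
            X = pd.DataFrame({"morans_i": clustering, "temp_sd": temp_sd})
            out = fit_z_regression(X, z).set_index("term")
            wins += (out.loc["morans_i", "coef"] > 0) and (
                out.loc["temp_sd", "coef"] > 0
            )
        assert wins >= 16


class TestSelectPredictors:
    def test_prefers_high_unique_effect(self):
        rng = np.random.default_rng(4)
        n = 40
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        noise = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b, "junk": noise})
        y = a + 0.7 * b
        chosen = select_predictors(X, y, n_select=2)
        assert set(chosen) == {"a", "b"}

    def test_correlated_predictors_pruned(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=40)
        X = pd.DataFrame({"a": a, "a2": a + rng.normal(0, 0.01, 40)})
        y = a
        chosen = select_predictors(X, y, n_select=2)
        assert len(chosen) == 1
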