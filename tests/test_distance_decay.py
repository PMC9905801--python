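import numpy as np
import pandas as pd
import pytest

from graminet.core import DistanceMatrix, SampleTable, ValidationError
from graminet.distance_decay import (
    compare_slopes,
    fit_ddr,
    geographic_distance_matrix,
    haversine_km,
    variable_divergence_matrix,
)
from graminet.diversity import bray_curtis_matrix
from graminet.simulate import GeneratorConfig, simulate_bundle


def _frame(lat, lon, **cols):
    data = pd.DataFrame({"latitude": lat, "longitude": lon, **cols},
                        index=pd.Index([f"s{i}" for i in range(len(lat))],
                                       name="sample_id"))
    return SampleTable(data)


class TestGeographicDistance:
    def test_identical_points_zero(self):
        assert haversine_km(10, 20, 10, 20) == pytest.approx(0.0)

    def test_one_degree_longitude_at_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_matrix_symmetry(self):
        rng = np.random.default_rng(0)
        frame = _frame(rng.uniform(-60, 60, 6), rng.uniform(-170, 170, 6))
        dm = geographic_distance_matrix(frame)
        np.testing.assert_allclose(dm.values, dm.values.T)
        assert dm.metric == "haversine_km"

    def test_missing_coordinates_error(self):
        frame = _frame([1.0, np.nan], [2.0, 3.0])
        with pytest.raises(ValidationError):
            geographic_distance_matrix(frame)


class TestVariableDivergence:
    def test_identical_rows_zero(self):
        frame = _frame([0, 0, 0], [0, 0, 0], pH=[7.0, 7.0, 8.0], CD=[50, 50, 60])
        dm = variable_divergence_matrix(frame, ["pH", "CD"])
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_variable_dropped_with_warning(self):
        frame = _frame([0, 0, 0], [0, 0, 0], pH=[7.0, 7.5, 8.0], CD=[50, 50, 50])
        with pytest.warns(UserWarning):
            dm = variable_divergence_matrix(frame, ["pH", "CD"])
        ref = variable_divergence_matrix(frame, ["pH"])
        np.testing.assert_allclose(dm.values, ref.values)

    def test_one_sd_apart_distance_one(self):
        # sd of [0,0,2,2] (ddof=1) is 2/sqrt(3); construct so two samples
        # differ by exactly one sd
        vals = np.array([0.0, 1.1547005383792515, 2.0, 1.0])
        sd = np.std(vals, ddof=1)
        frame = _frame([0] * 4, [0] * 4, pH=vals)
        dm = variable_divergence_matrix(frame, ["pH"])
        i, j = 0, 3  # differ by 1.0 raw
        assert dm.values[i, j] == pytest.approx(abs(vals[i] - vals[j]) / sd)

    def test_variable_order_invariance(self):
        rng = np.random.default_rng(1)
        frame = _frame([0] * 5, [0] * 5, pH=rng.normal(7, 1, 5), CD=rng.uniform(10, 90, 5))
        a = variable_divergence_matrix(frame, ["pH", "CD"])
        b = variable_divergence_matrix(frame, ["CD", "pH"])
        np.testing.assert_allclose(a.values, b.values)


class TestFitDdr:
    def _dms(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, n)
        x = np.abs(pts[:, None] - pts[None, :])
        labels = [f"s{i}" for i in range(n)]
        return DistanceMatrix(labels, x, "x")

    def test_exact_linear_recovery(self):
        xdm = self._dms()
        ydm = DistanceMatrix(xdm.labels, 0.002 * xdm.values, "y")
        fit = fit_ddr(ydm, xdm, n_perm=49, seed=0)
        assert fit.slope == pytest.approx(0.002, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_pairs == 15

    def test_constant_predictor_errors(self):
        n = 5
        labels = [f"s{i}" for i in range(n)]
        const = np.ones((n, n)) - np.eye(n)
        xdm = DistanceMatrix(labels, const, "x")
        ydm = self._dms(n)
        with pytest.raises(ValidationError):
            fit_ddr(ydm, xdm, n_perm=9)

    def test_too_few_samples_errors(self):
        labels = ["a", "b", "c"]
        vals = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        dm = DistanceMatrix(labels, vals, "m")
        with pytest.raises(ValidationError):
            fit_ddr(dm, dm)

    def test_label_permutation_invariance(self):
        xdm = self._dms(seed=3)
        rng = np.random.default_rng(4)
        ydm = DistanceMatrix(
            xdm.labels,
            0.01 * xdm.values + squareform_sym(rng, len(xdm)), "y")
        fit1 = fit_ddr(ydm, xdm, n_perm=0)
        perm = list(np.random.default_rng(5).permutation(xdm.labels))
        fit2 = fit_ddr(ydm.select(perm), xdm.select(perm), n_perm=0)
        assert fit1.slope == pytest.approx(fit2.slope, rel=1e-12)

    def test_permutation_p_significant_for_strong_signal(self):
        xdm = self._dms(n=12, seed=6)
        ydm = DistanceMatrix(xdm.labels, 0.005 * xdm.values, "y")
        fit = fit_ddr(ydm, xdm, n_perm=199, seed=0)
        assert fit.p_permutation <= 0.01


def squareform_sym(rng, n, scale=0.05):
    m = rng.normal(0, scale, (n, n))
    m = np.abs(m + m.T)
    np.fill_diagonal(m, 0)
    return m


class TestCompareSlopes:
    def _fit_from(self, xdm, ydm, name):
        return fit_ddr(ydm, xdm, organism_group=name, n_perm=0)

    def test_duplicate_dataset_no_difference(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, 8)
        labels = [f"s{i}" for i in range(8)]
        xdm = DistanceMatrix(labels, np.abs(pts[:, None] - pts[None, :]), "x")
        ydm = DistanceMatrix(labels, 0.01 * xdm.values + squareform_sym(rng, 8), "y")
        fits = [self._fit_from(xdm, ydm, "g1"), self._fit_from(xdm, ydm, "g2")]
        out = compare_slopes(fits)
        assert out["delta"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] > 0.99

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, 8)
        labels = [f"s{i}" for i in range(8)]
        xdm = DistanceMatrix(labels, np.abs(pts[:, None] - pts[None, :]), "x")
        y1 = DistanceMatrix(labels, 0.01 * xdm.values + squareform_sym(rng, 8), "y")
        y2 = DistanceMatrix(labels, 0.02 * xdm.values + squareform_sym(rng, 8), "y")
        f1, f2 = self._fit_from(xdm, y1, "a"), self._fit_from(xdm, y2, "b")
        d_ab = compare_slopes([f1, f2])["delta"].iloc[0]
        d_ba = compare_slopes([f2, f1])["delta"].iloc[0]
        assert d_ab == pytest.approx(-d_ba)

    def test_single_fit_errors(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, 6)
        labels = [f"s{i}" for i in range(6)]
        xdm = DistanceMatrix(labels, np.abs(pts[:, None] - pts[None, :]), "x")
        ydm = DistanceMatrix(labels, 0.01 * xdm.values, "y")
        with pytest.raises(ValidationError):
            compare_slopes([self._fit_from(xdm, ydm, "only")])

    def test_grass_fungi_contrast_power(self):
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = GeneratorConfig.turnover_reference(
                seed, n_grass_species=24, n_taxa={"fungi": 40})
            b = simulate_bundle(cfg)
            geo = None
            from graminet.distance_decay import geographic_distance_matrix

            geo = geographic_distance_matrix(b.frame)
            fg = fit_ddr(bray_curtis_matrix(b.grass), geo, organism_group="grass", n_perm=0)
            ff = fit_ddr(bray_curtis_matrix(b.microbes["fungi"]), geo,
                         organism_group="fungi", n_perm=0)
            out = compare_slopes([fg, ff])
            if out["p_adj"].iloc[0] < 0.05 and out["delta"].iloc[0] > 0:
                hits += 1
        assert hits >= 5
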