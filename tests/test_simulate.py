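"""Synthetic-data generator: determinism, calibration and sampling laws."""

import numpy as np
import pytest
from scipy import stats

import gtsdm as g
from gtsdm.simulate import InfeasibleSamplingError, sample_bias_surface


def morans_i(field: np.ndarray) -> float:
    """Moran's I with rook adjacency, computed by brute force."""
    z = field - field.mean()
    n_rows, n_cols = field.shape
    num = 0.0
    w_sum = 0
    for i in range(n_rows):
        for j in range(n_cols):
            for di, dj in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                i2, j2 = i + di, j + dj
                if 0 <= i2 < n_rows and 0 <= j2 < n_cols:
                    num += z[i, j] * z[i2, j2]
                    w_sum += 1
    return field.size / w_sum * num / (z ** 2).sum()


class TestLandscape:
    def test_same_seed_bit_identical(self):
        a = g.generate_landscape(5, 20, 20, 50.0)
        b = g.generate_landscape(5, 20, 20, 50.0)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.values, lb.values)

    def test_zero_sd_gives_constant_layer(self):
        s = g.generate_landscape(1, 16, 16, 10.0,
                                 continuous_specs=[("flat", 2.0, 7.5, 0.0)],
                                 categorical_spec=None)
        np.testing.assert_array_equal(s.layer("flat").values, 7.5)

    def test_requested_moments_honoured(self):
        s = g.generate_landscape(2, 32, 32, 10.0,
                                 continuous_specs=[("t", 3.0, 12.0, 2.5)],
                                 categorical_spec=None)
        v = s.layer("t").values
        assert v.mean() == pytest.approx(12.0, abs=1e-9)
        assert v.std() == pytest.approx(2.5, abs=1e-9)

    def test_smoothing_raises_spatial_autocorrelation(self):
        spec = [("smooth", 4.0, 0.0, 1.0), ("rough", 0.0, 0.0, 1.0)]
        s = g.generate_landscape(3, 32, 32, 10.0, continuous_specs=spec,
                                 categorical_spec=None)
        assert morans_i(s.layer("smooth").values) > morans_i(s.layer("rough").values)

    def test_categorical_levels_complete_and_coded(self):
        s = g.generate_landscape(4, 30, 30, 10.0, continuous_specs=[],
                                 categorical_spec=("lc", 5, 2.0))
        lyr = s.layer("lc")
        assert lyr.codes == (0, 1, 2, 3, 4)
        assert set(np.unique(lyr.values)) == {0, 1, 2, 3, 4}

    @pytest.mark.parametrize("kwargs", [
        {"n_rows": 4}, {"cell_size": 0.0}, {"categorical_spec": ("c", 1, 1.0)},
        {"categorical_spec": ("c", 300, 1.0)},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            g.generate_landscape(1, **({"n_rows": 16, "n_cols": 16} | kwargs))


class TestVirtualSpecies:
    def test_zero_coefficients_give_constant_suitability(self, stack):
        vs = g.define_virtual_species(stack, "L", np.zeros(6), 0.3, seed=1)
        ok = np.isfinite(vs.suitability)
        np.testing.assert_allclose(vs.suitability[ok], 0.3, atol=1e-9)

    def test_prevalence_calibrated_to_1e6(self, stack):
        for link in ("logistic", "cloglog"):
            vs = g.define_virtual_species(stack, "LQ", np.r_[np.ones(6), -0.5 * np.ones(6)],
                                          0.2, link=link, seed=2)
            ok = np.isfinite(vs.suitability)
            assert abs(vs.suitability[ok].mean() - 0.2) <= 1e-6

    def test_realized_occupancy_within_binomial_error(self):
        s = g.generate_landscape(7, 64, 64, 10.0, categorical_spec=None)
        vs = g.define_virtual_species(s, "L", (1.0, 0, 0, 0, 0, 0), 0.3, seed=3)
        n = 64 * 64
        se = np.sqrt(0.3 * 0.7 / n)
        # realized prevalence averages cell-level Bernoulli draws whose mean
        # suitability is exactly 0.3
        assert abs(vs.realized_prevalence - 0.3) < 3 * se + 0.02

    def test_positive_linear_coefficient_is_monotone(self, stack):
        vs = g.define_virtual_species(stack, "L", (2.0, 0, 0, 0, 0, 0), 0.3, seed=4)
        lyr = stack.layer("env1").values
        lo = lyr < np.quantile(lyr, 0.2)
        hi = lyr > np.quantile(lyr, 0.8)
        assert vs.suitability[hi].mean() > vs.suitability[lo].mean()

    def test_coefficient_length_mismatch_rejected(self, stack):
        with pytest.raises(ValueError, match="coefficients"):
            g.define_virtual_species(stack, "LQ", np.zeros(6), 0.3)


class TestPresenceSampling:
    def test_zero_draws_gives_empty_set(self, species, stack):
        occ = g.sample_presence_records(species, stack, 0, seed=1)
        assert len(occ) == 0

    def test_same_seed_identical_records(self, species, stack):
        a = g.sample_presence_records(species, stack, 50, seed=9)
        b = g.sample_presence_records(species, stack, 50, seed=9)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_cell_frequencies_match_product_law(self):
        """On a tiny support the empirical cell distribution matches the
        normalised occupancy x bias law (chi-square oracle)."""
        s = g.generate_landscape(8, 8, 8, 10.0, categorical_spec=None)
        vs = g.define_virtual_species(s, "L", np.zeros(6), 0.5, seed=5)
        # restrict occupancy to 10 cells with known bias weights
        vs.occupancy[:] = False
        rng = np.random.default_rng(0)
        cells = [(i, j) for i in range(8) for j in range(8)]
        chosen = [cells[k] for k in rng.choice(64, 10, replace=False)]
        bias = np.zeros(s.shape)
        weights = rng.uniform(0.5, 3.0, 10)
        for (i, j), w in zip(chosen, weights):
            vs.occupancy[i, j] = True
            bias[i, j] = w
        occ = g.sample_presence_records(vs, s, 10_000, bias_surface=bias, seed=6)
        row, col = s.cell_index(occ.xy[:, 0], occ.xy[:, 1])
        counts = np.array([np.sum((row == i) & (col == j)) for i, j in chosen])
        expected = 10_000 * weights / weights.sum()
        assert stats.chisquare(counts, expected).pvalue > 0.01

    def test_doubling_bias_weight_doubles_relative_probability(self):
        w = np.array([1.0, 1.0, 2.0])
        p = w / w.sum()
        w2 = w.copy()
        w2[0] *= 2
        p2 = w2 / w2.sum()
        assert p2[0] > p[0]
        assert p2[0] / p2[1] == pytest.approx(2 * p[0] / p[1])

    def test_infeasible_sampling_raises(self, stack):
        vs = g.define_virtual_species(stack, "L", np.zeros(6), 0.3, seed=7)
        vs.occupancy[:] = False
        with pytest.raises(InfeasibleSamplingError):
            g.sample_presence_records(vs, stack, 10, seed=8)

    def test_records_fall_on_occupied_cells(self, species, stack):
        occ = g.sample_presence_records(species, stack, 200, seed=10)
        row, col = stack.cell_index(occ.xy[:, 0], occ.xy[:, 1])
        assert species.occupancy[row, col].all()


class TestSurvey:
    def test_certain_detection_reports_occupancy(self, species, stack):
        vs_sure = g.define_virtual_species(
            stack, "L", species.true_coefficients, 0.3, seed=21,
            detection_prob={"funnel": 1.0, "pitfall": 1.0})
        df = g.simulate_survey(vs_sure, stack, [(0, 0, 2000, 2000)], 30, seed=1)
        row, col = stack.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
        np.testing.assert_array_equal(df["virtual"].to_numpy(),
                                      vs_sure.occupancy[row, col].astype(int))

    def test_zero_detection_gives_all_absences(self, species, stack):
        vs0 = g.define_virtual_species(
            stack, "L", species.true_coefficients, 0.3, seed=21,
            detection_prob={"funnel": 0.0, "pitfall": 0.0})
        df = g.simulate_survey(vs0, stack, [(0, 0, 2000, 2000)], 30, seed=2)
        assert (df["virtual"] == 0).all()

    def test_presence_count_matches_analytic_expectation(self, stack):
        vs = g.define_virtual_species(stack, "L", (1.0, 0, 0, 0, 0, 0), 0.4, seed=22,
                                      detection_prob={"funnel": 0.6, "pitfall": 0.6})
        df = g.simulate_survey(vs, stack, [(0, 0, 6000, 6000)], 1000, seed=3)
        row, col = stack.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
        p = vs.occupancy[row, col] * 0.6
        expected = p.sum()
        se = np.sqrt((p * (1 - p)).sum())
        assert abs(df["virtual"].sum() - expected) <= 3 * se

    def test_site_with_no_valid_cells_skipped_with_warning(self, species, stack):
        with pytest.warns(UserWarning, match="skipped"):
            df = g.simulate_survey(species, stack,
                                   [(-5000, -5000, -4000, -4000), (0, 0, 2000, 2000)],
                                   5, seed=4)
        assert df.attrs["skipped_sites"] == ["site000"]
        assert set(df["site"]) == {"site001"}


def test_bias_surface_positive_and_deterministic(stack):
    a = sample_bias_surface(stack, seed=3)
    b = sample_bias_surface(stack, seed=3)
    np.testing.assert_array_equal(a, b)
    assert (a > 0).all()
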