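"""Maximum-entropy core: features, penalties, solver optimality, prediction."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import gtsdm as g
from gtsdm.maxent import FeatureSpec, _BETA_SCHEDULE, _PenalizedMaxent
from gtsdm.raster import CovariateStack, Layer


def two_cont_one_cat_stack():
    rng = np.random.default_rng(5)
    return CovariateStack(10.0, (0.0, 0.0), [
        Layer("a", "continuous", rng.normal(0, 1, (12, 12))),
        Layer("b", "continuous", rng.normal(5, 2, (12, 12))),
        Layer("c", "categorical", rng.integers(0, 4, (12, 12)).astype(float), (0, 1, 2, 3)),
    ])


def grid_points(stack, step=1):
    rows, cols = np.indices(stack.shape)
    x, y = stack.cell_center(rows.ravel()[::step], cols.ravel()[::step])
    return np.column_stack([x, y])


class TestFeatures:
    def test_lq_expansion_enumerates_by_hand(self):
        """2 continuous + one 4-level categorical under LQ:
        2 linear + 2 quadratic + 4 indicators = 8 features."""
        s = two_cont_one_cat_stack()
        spec = FeatureSpec.from_background(s, grid_points(s), "LQ", 1.0)
        kinds = [f.kind for f in spec.features]
        assert len(spec.features) == 8
        assert kinds.count("linear") == 2
        assert kinds.count("quadratic") == 2
        assert kinds.count("indicator") == 4

    @pytest.mark.parametrize("fc,expected", [("L", 2 + 4), ("Q", 2 + 4), ("LQ", 4 + 4)])
    def test_feature_class_controls_expansion(self, fc, expected):
        s = two_cont_one_cat_stack()
        spec = FeatureSpec.from_background(s, grid_points(s), fc, 1.0)
        assert len(spec.features) == expected

    def test_background_extremes_scale_to_zero_and_one(self):
        s = two_cont_one_cat_stack()
        pts = grid_points(s)
        spec = FeatureSpec.from_background(s, pts, "L", 1.0)
        design = spec.transform(s, pts)
        assert design[:, 0].min() == 0.0 and design[:, 0].max() == 1.0

    def test_indicators_partition_each_point(self):
        s = two_cont_one_cat_stack()
        pts = grid_points(s)
        spec = FeatureSpec.from_background(s, pts, "LQ", 1.0)
        ind = [j for j, f in enumerate(spec.features) if f.kind == "indicator"]
        np.testing.assert_allclose(spec.transform(s, pts)[:, ind].sum(axis=1), 1.0)

    def test_constant_layer_dropped_with_warning(self):
        s = CovariateStack(10.0, (0.0, 0.0), [
            Layer("flat", "continuous", np.full((10, 10), 3.0)),
            Layer("var", "continuous", np.arange(100, dtype=float).reshape(10, 10)),
        ])
        with pytest.warns(UserWarning, match="constant"):
            spec = FeatureSpec.from_background(s, grid_points(s), "L", 1.0)
        assert [f.layer for f in spec.features] == ["var"]

    def test_clamping_truncates_beyond_training_range(self):
        """A projection point beyond the training maximum scores exactly as a
        point at the maximum when clamp is on."""
        s = two_cont_one_cat_stack()
        train = grid_points(s)
        spec = FeatureSpec.from_background(s, train, "L", 1.0)
        f0 = spec.features[0]
        hi_raw = np.array([[f0.hi + 10.0, 5.0, 1.0]])
        at_max = np.array([[f0.hi, 5.0, 1.0]])
        clamped = spec._expand(hi_raw, s.layer_names, clamp=True)
        exact = spec._expand(at_max, s.layer_names, clamp=True)
        np.testing.assert_array_equal(clamped, exact)
        unclamped = spec._expand(hi_raw, s.layer_names, clamp=False)
        assert unclamped[0, 0] > 1.0


@pytest.fixture(scope="module")
def spec():
    s = two_cont_one_cat_stack()
    return FeatureSpec.from_background(s, grid_points(s), "LQ", 1.0)


class TestPenalties:
    def test_zero_rm_gives_zero_penalties(self, spec):
        from dataclasses import replace
        assert (replace(spec, rm=0.0).default_penalties(50) == 0).all()

    def test_linear_in_rm(self, spec):
        from dataclasses import replace
        b1 = spec.default_penalties(50)
        b2 = replace(spec, rm=2.0).default_penalties(50)
        np.testing.assert_allclose(b2, 2 * b1)

    def test_schedule_breakpoints_match_table(self, spec):
        """At a tabulated sample size the interpolation returns the
        tabulated value: beta_class(30)=0.2 for linear/quadratic features."""
        xs, ys = _BETA_SCHEDULE["lq"]
        j = 0  # a linear feature
        beta = spec.default_penalties(30)
        assert beta[j] == pytest.approx(1.0 * 0.2 * spec.background_sd[j] / np.sqrt(30))
        assert np.interp(30, xs, ys) == 0.2
        xs_c, ys_c = _BETA_SCHEDULE["categorical"]
        assert np.interp(10, xs_c, ys_c) == 0.5

    def test_schedule_non_increasing_in_sample_size(self, spec):
        betas = [spec.default_penalties(n)[0] * np.sqrt(n) for n in (5, 10, 30, 100, 500)]
        assert all(a >= b for a, b in zip(betas, betas[1:]))


class TestFit:
    def test_huge_rm_zeroes_everything_and_raw_is_uniform(self, stack, study):
        model = g.MaxEnt.from_points(stack, study["occ"].xy, study["bg"].xy,
                                     "LQ", rm=1e6)
        res = model.fit()
        assert res.ncoef == 0
        raw = res.predict(model.X_bg, scale="raw")
        np.testing.assert_allclose(raw, 1.0 / len(study["bg"].xy), rtol=1e-12)

    def test_raw_normalises_over_background(self, fitted):
        model, res = fitted
        assert abs(res.predict(model.X_bg, scale="raw").sum() - 1.0) < 1e-10

    def test_kkt_conditions_with_finite_difference_gradient(self, fitted):
        """Subgradient optimality of the penalised mean log-likelihood,
        gradient checked by central differences."""
        model, res = fitted
        lam = res.params
        beta = model.penalties
        Xp, Xb = model.X_pres, model.X_bg

        def loglik(v):
            return Xp.mean(0) @ v - logsumexp(Xb @ v)

        h = 1e-6
        tol = 1e-4  # fd truncation dominates; solver residual is ~1e-12
        for j in range(len(lam)):
            e = np.zeros_like(lam)
            e[j] = h
            grad_j = (loglik(lam + e) - loglik(lam - e)) / (2 * h)
            if lam[j] == 0:
                assert abs(grad_j) <= beta[j] + tol
            else:
                assert abs(grad_j - np.sign(lam[j]) * beta[j]) <= tol

    def test_objective_trace_monotone(self, fitted):
        _, res = fitted
        diffs = np.diff(res.objective_trace)
        assert (diffs >= -1e-9 * np.abs(res.objective_trace[:-1])).all()

    def test_optimal_objective_non_increasing_in_rm(self, stack, study):
        vals = []
        for rm in (0.0, 1.0, 2.0, 5.0):
            model = g.MaxEnt.from_points(stack, study["occ"].xy, study["bg"].xy,
                                         "L", rm=rm)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals.append(model.fit().objective)
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_matches_generic_constrained_solver(self):
        """3-feature, 50-point problem: the solver agrees with an L-BFGS-B
        solve of the split-variable (lambda = u - v, u,v >= 0) program to
        1e-4 per coefficient."""
        rng = np.random.default_rng(8)
        Xb = rng.random((300, 3))
        truth = np.array([2.0, -1.5, 0.0])
        w = np.exp(Xb @ truth)
        idx = rng.choice(300, size=50, p=w / w.sum())
        Xp = Xb[idx]
        beta = np.array([0.01, 0.01, 0.01])
        res = g.MaxEnt(Xp, Xb, penalties=beta).fit(tol=1e-10)

        def neg_obj(z):
            u, v = z[:3], z[3:]
            lam = u - v
            return -(Xp.mean(0) @ lam - logsumexp(Xb @ lam) - beta @ (u + v))

        oracle = minimize(neg_obj, np.zeros(6), method="L-BFGS-B",
                          bounds=[(0, None)] * 6,
                          options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000})
        lam_oracle = oracle.x[:3] - oracle.x[3:]
        np.testing.assert_allclose(res.params, lam_oracle, atol=1e-4)

    def test_sparsity_increases_with_rm_majority(self):
        """rm=5 never uses more coefficients than rm=0 in the clear majority
        of synthetic replicates (sparsity direction, not per-instance)."""
        wins = 0
        total = 20
        for k in range(total):
            s = g.generate_landscape(200 + k, 20, 20, 50.0,
                                     continuous_specs=[("p", 2.0, 0.0, 1.0),
                                                       ("q", 2.0, 0.0, 1.0),
                                                       ("r", 0.0, 0.0, 1.0)],
                                     categorical_spec=None)
            vs = g.define_virtual_species(s, "L", (1.5, -0.5, 0.0), 0.3, seed=300 + k)
            occ = g.sample_presence_records(vs, s, 40, seed=400 + k)
            bg_rows = np.random.default_rng(500 + k).integers(0, 20, (300, 2))
            bx, by = s.cell_center(bg_rows[:, 0], bg_rows[:, 1])
            bg = np.column_stack([bx, by])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n0 = g.MaxEnt.from_points(s, occ.xy, bg, "LQ", rm=0.0).fit(
                    max_iter=300).ncoef
                n5 = g.MaxEnt.from_points(s, occ.xy, bg, "LQ", rm=5.0).fit().ncoef
            wins += n0 >= n5
        assert wins > total / 2

    def test_parameter_recovery_signs_and_cosine(self):
        """Virtual species with two nonzero linear effects, 500 presences,
        rm=1: fitted coefficients recover both signs and point within 26
        degrees of the (rescaled) truth."""
        stack = g.generate_landscape(100, 80, 80, 100.0)
        true = (2.5, -1.5, 0.0, 0.0, 0.0, 0.0)
        vs = g.define_virtual_species(stack, "L", true, 0.10, seed=101)
        occ = g.sample_presence_records(vs, stack, 500, seed=102)
        kept, _ = g.filter_occurrences(occ, stack)
        ext = g.build_study_extent(kept, stack, 3000.0)
        bg = g.sample_background(ext, stack, 2000, seed=103)
        model = g.MaxEnt.from_points(stack, kept.xy, bg.xy, "L", rm=1.0)
        res = model.fit()
        spec = model.spec
        lin = [(j, f) for j, f in enumerate(spec.features) if f.kind == "linear"]
        fit = np.array([res.params[j] for j, _ in lin])
        truth = np.array([
            c * (f.hi - f.lo) / stack.layer(f.layer).values[stack.valid_mask].std()
            for (_, f), c in zip(lin, true)
        ])
        assert np.sign(fit[0]) == 1 and np.sign(fit[1]) == -1
        cos = fit @ truth / (np.linalg.norm(fit) * np.linalg.norm(truth))
        assert cos > 0.9


class TestPredict:
    def test_cloglog_in_unit_interval_and_rank_identical(self, fitted, stack):
        _, res = fitted
        raw = res.predict_grid(stack, scale="raw")
        clog = res.predict_grid(stack, scale="cloglog")
        ok = np.isfinite(raw)
        assert ((clog[ok] > 0) & (clog[ok] < 1)).all()
        np.testing.assert_array_equal(np.argsort(raw[ok]), np.argsort(clog[ok]))

    def test_serialisation_round_trip(self, fitted, stack, study, tmp_path):
        _, res = fitted
        res.to_json(tmp_path / "m.json")
        back = g.MaxEntResults.from_json(tmp_path / "m.json")
        xy = study["bg"].xy[:50]
        np.testing.assert_allclose(
            back.predict(stack=stack, xy=xy, scale="cloglog"),
            res.predict(stack=stack, xy=xy, scale="cloglog"),
        )
        assert back.ncoef == res.ncoef

    def test_summary_mentions_fit_quality(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "nonzero coefficients" in text and "KKT" in text
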