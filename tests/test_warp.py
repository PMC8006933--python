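"""Warped path estimation: standardization, warping, OLS oracle, VIF,
bootstrap inference, fit indices and shape classification."""

import numpy as np
import pandas as pd
import pytest

from obesipath import warp
from obesipath.errors import (
    CollinearityError,
    DegenerateVariableError,
    ModelSpecificationError,
    ShapeError,
)


class TestStandardize:
    def test_closed_form(self):
        out = warp.standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["a"], [-1, 0, 1])

    def test_idempotent(self, rng):
        x = rng.standard_normal(50)
        z = warp.standardize(x)
        assert np.allclose(warp.standardize(z), z, atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(DegenerateVariableError, match="flat"):
            warp.standardize(df)


class TestWarpEdge:
    def test_linear_mode_is_identity_on_standardized_x(self, rng):
        x = warp.standardize(rng.standard_normal(100))
        y = rng.standard_normal(100)
        assert np.allclose(warp.warp_edge(x, y, "linear"), x, atol=1e-10)

    def test_noiseless_cubic_reaches_r2_one(self, rng):
        x = warp.standardize(rng.standard_normal(200))
        y = x**3
        w = warp.warp_edge(x, y, "s_curve")
        r = np.corrcoef(w, y)[0, 1]
        assert r**2 == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_gives_negative_beta(self, rng):
        x = warp.standardize(rng.standard_normal(150))
        df = pd.DataFrame({"x": x, "y": -x})
        fit = warp.fit_model(df, warp.PathModel([warp.Edge("x", "y", "s_curve")]))
        assert fit.edges[0].beta == pytest.approx(-1.0, abs=1e-8)

    def test_binary_predictor_forced_linear(self, rng):
        x = rng.integers(0, 2, 120).astype(float)
        y = rng.standard_normal(120)
        coef = warp.warp_fit(x, y, "s_curve")
        assert np.allclose(coef[2:], 0)

    def test_length_mismatch(self, rng):
        with pytest.raises(ShapeError):
            warp.warp_edge(rng.standard_normal(10), rng.standard_normal(11),
                           "linear")


class TestFitModel:
    def test_linear_mode_matches_normal_equations(self, linear_frame):
        model = warp.PathModel([warp.Edge("x1", "y", "linear"),
                                warp.Edge("x2", "y", "linear")])
        fit = warp.fit_model(linear_frame, model)
        z = warp.standardize(linear_frame)
        X = z[["x1", "x2"]].to_numpy()
        yv = z["y"].to_numpy()
        oracle = np.linalg.solve(X.T @ X, X.T @ yv)
        assert np.allclose([e.beta for e in fit.edges], oracle, atol=1e-10)

    def test_single_edge_effect_size_is_beta_squared(self, rng):
        x = rng.standard_normal(300)
        y = 0.6 * x + rng.standard_normal(300)
        df = pd.DataFrame({"x": x, "y": y})
        fit = warp.fit_model(df, warp.PathModel([warp.Edge("x", "y", "linear")]))
        e = fit.edges[0]
        assert e.effect_size == pytest.approx(e.beta**2, abs=1e-12)

    def test_s_curve_mode_consistent_under_linear_truth(self, rng):
        n = 100_000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 0.5 * x1 - 0.3 * x2 + rng.standard_normal(n) * np.sqrt(1 - 0.34)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        model = warp.PathModel([warp.Edge("x1", "y", "s_curve"),
                                warp.Edge("x2", "y", "s_curve")])
        betas = [e.beta for e in warp.fit_model(df, model).edges]
        assert betas[0] == pytest.approx(0.5, abs=0.02)
        assert betas[1] == pytest.approx(-0.3, abs=0.02)

    def test_missing_variable_rejected(self, linear_frame):
        model = warp.PathModel([warp.Edge("x1", "zz", "linear")])
        with pytest.raises(ModelSpecificationError):
            warp.fit_model(linear_frame, model)

    def test_collinear_block_rejected(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": x + 1e-14 * rng.standard_normal(100),
                           "y": rng.standard_normal(100)})
        model = warp.PathModel([warp.Edge("a", "y", "linear"),
                                warp.Edge("b", "y", "linear")])
        with pytest.raises(CollinearityError):
            warp.fit_model(df, model)


class TestVIF:
    def test_orthogonal_columns(self):
        n = 400
        rng = np.random.default_rng(5)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal in sample
        out = warp.vif(np.column_stack([a, b]))
        assert np.allclose(out, [1.0, 1.0], atol=1e-10)

    def test_near_duplicate_exceeds_threshold(self, rng):
        x = rng.standard_normal(200)
        block = np.column_stack([x, x + 0.01 * rng.standard_normal(200)])
        assert warp.vif(block).min() > 3.3

    def test_matches_precision_matrix_diagonal(self, rng):
        """VIF_j = [R^-1]_jj for the correlation matrix R of the block."""
        n = 2000
        L = np.array([[1.0, 0, 0], [0.5, 1.0, 0], [0.3, -0.4, 1.0]])
        X = rng.standard_normal((n, 3)) @ L.T
        vifs = warp.vif(X)
        R = np.corrcoef(X, rowvar=False)
        oracle = np.diag(np.linalg.inv(R))
        assert np.allclose(vifs, oracle, rtol=1e-8)

    def test_perfect_collinearity_raises(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(CollinearityError):
            warp.vif(np.column_stack([x, 2 * x, rng.standard_normal(50)]))


class TestBootstrap:
    def test_same_seed_same_pvalues(self, linear_frame):
        model = warp.PathModel([warp.Edge("x1", "y", "linear"),
                                warp.Edge("x2", "y", "linear")])
        b1 = warp.bootstrap_inference(linear_frame, model, B=150, seed=9)
        b2 = warp.bootstrap_inference(linear_frame, model, B=150, seed=9)
        assert np.array_equal(b1.p, b2.p)
        assert np.array_equal(b1.se, b2.se)

    def test_p_monotone_in_se(self):
        from scipy import stats
        beta = 0.4
        ps = [2 * stats.t.sf(beta / se, df=499) for se in (0.2, 0.1, 0.01)]
        assert ps[0] > ps[1] > ps[2]

    def test_strong_effect_significant(self, linear_frame):
        model = warp.PathModel([warp.Edge("x1", "y", "linear")])
        b = warp.bootstrap_inference(linear_frame, model, B=200, seed=2)
        assert b.p[0] < 0.01

    def test_interval_coverage_for_known_beta(self, rng):
        """95% normal-theory bootstrap intervals cover a true beta ~95%."""
        from scipy import stats
        truth, n, B, reps = 0.4, 200, 200, 250
        model = warp.PathModel([warp.Edge("x", "y", "linear")])
        tcrit = stats.t.ppf(0.975, df=B - 1)
        hits = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = truth * x + rng.standard_normal(n) * np.sqrt(1 - truth**2)
            df = pd.DataFrame({"x": x, "y": y})
            fit = warp.fit_model(df, model)
            boot = warp.bootstrap_inference(df, model, B=B, seed=int(rng.integers(2**31)))
            lo = fit.edges[0].beta - tcrit * boot.se[0]
            hi = fit.edges[0].beta + tcrit * boot.se[0]
            hits += lo <= truth <= hi
        assert 0.92 <= hits / reps <= 0.98


class TestFitIndices:
    def test_apc_is_mean_absolute_beta(self, rng):
        x1 = rng.standard_normal(500)
        x2 = rng.standard_normal(500)
        y = 0.2 * x1 + 0.4 * x2 + 0.1 * rng.standard_normal(500)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        model = warp.PathModel([warp.Edge("x1", "y", "linear"),
                                warp.Edge("x2", "y", "linear")])
        fit = warp.fit_model(df, model)
        idx = warp.fit_indices(fit, df)
        betas = np.abs([e.beta for e in fit.edges])
        assert idx.apc == pytest.approx(betas.mean(), abs=1e-12)

    def test_gof_equals_sqrt_ars_for_single_indicator(self, scored_cohort):
        from obesipath.reference import default_model
        fit = warp.fit_model(scored_cohort, default_model())
        idx = warp.fit_indices(fit, scored_cohort)
        assert idx.gof == pytest.approx(np.sqrt(idx.ars), abs=0)
        for name in ("spr", "rscr", "ssr", "nlbcdr"):
            assert 0.0 <= getattr(idx, name) <= 1.0

    def test_quality_ratios_hit_one_when_definitions_satisfied(self, rng):
        # exactly uncorrelated (centered) predictors: beta == corr per edge
        n = 300
        a = rng.standard_normal(n)
        a -= a.mean()
        b = rng.standard_normal(n)
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)
        y = 0.3 * a + 0.5 * b + rng.standard_normal(n)
        df = pd.DataFrame({"a": a, "b": b, "y": y})
        model = warp.PathModel([warp.Edge("a", "y", "linear"),
                                warp.Edge("b", "y", "linear")])
        fit = warp.fit_model(df, model)
        idx = warp.fit_indices(fit, df)
        assert idx.spr == 1.0 and idx.ssr == 1.0 and idx.rscr == 1.0

    def test_invariant_to_row_order_and_relabeling(self, rng):
        n = 250
        x = rng.standard_normal(n)
        y = 0.5 * x**3 + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y})
        model = warp.PathModel([warp.Edge("x", "y", "s_curve")])
        idx1 = warp.fit_indices(warp.fit_model(df, model), df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        idx2 = warp.fit_indices(warp.fit_model(shuffled, model), shuffled)
        renamed = df.rename(columns={"x": "u", "y": "v"})
        model_r = warp.PathModel([warp.Edge("u", "v", "s_curve")])
        idx3 = warp.fit_indices(warp.fit_model(renamed, model_r), renamed)
        for k in ("apc", "ars", "aars", "gof", "spr", "rscr", "ssr", "nlbcdr"):
            assert getattr(idx1, k) == pytest.approx(getattr(idx2, k), abs=1e-9)
            assert getattr(idx1, k) == pytest.approx(getattr(idx3, k), abs=1e-12)


class TestShapes:
    @pytest.mark.parametrize("coef,x_range,label", [
        ((0.0, 1.0), (-2, 2), "linear"),
        ((0.0, 0.0, 1.0), (-2, 2), "U"),
        ((0.0, 0.0, -1.0), (-2, 2), "inverted-U"),
        ((0.0, -1.5, 0.0, 1.0), (-2, 2), "S"),          # x^3 - 1.5x
        ((0.0, 1.5, 0.0, -1.0), (-2, 2), "inverted-S"),  # two stationary, neg
        ((0.0, 2.0, 0.4), (-2, 2), "exponential-like"),  # convex increasing
    ])
    def test_polynomial_families(self, coef, x_range, label):
        assert warp.classify_shape(coef, x_range) == label

    def test_j_curve_dip_near_left_edge(self):
        # minimum at x = -1.4 in range (-2, 2): dip in left third, convex
        coef = (0.0, 2.8, 1.0)  # derivative 2x + 2.8 -> root -1.4
        assert warp.classify_shape(coef, (-2, 2)) == "J"

    def test_relationship_curve_samples_fitted_polynomial(self, rng):
        x = rng.standard_normal(200)
        y = x**3 - 1.5 * x + 0.05 * rng.standard_normal(200)
        df = pd.DataFrame({"x": x, "y": y})
        fit = warp.fit_model(df, warp.PathModel([warp.Edge("x", "y", "s_curve")]))
        curve = warp.relationship_curve(fit.edges[0], n_points=41)
        assert len(curve) == 41
        assert curve["x"].iloc[0] == pytest.approx(fit.edges[0].x_range[0])
        assert warp.classify_shape(fit.edges[0].coef,
                                   fit.edges[0].x_range) == "S"


def test_significance_stars():
    assert warp.significance_stars(0.003) == "***"
    assert warp.significance_stars(0.03) == "**"
    assert warp.significance_stars(0.07) == "*"
    assert warp.significance_stars(0.2) == ""
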