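"""Hierarchical model: REML oracle, GLS oracle, edf limits, curves, effects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ejdisp.mixed_model import (
    ModelSpec,
    _build_design,
    _REMLProblem,
    association_curve,
    effective_df,
    fit_hierarchical,
    linear_effect,
    linearity_decision,
)
from ejdisp.splines import PenalizedSplineBasis
from ejdisp.synthetic import SyntheticConfig, make_counties, make_demographics, make_outcomes


def _toy_frame(n_states=3, n_counties=4, n_periods=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_states):
        for c in range(n_counties):
            for t in range(n_periods):
                rows.append({
                    "state_id": f"S{s}",
                    "county_id": f"S{s}C{c}",
                    "year": 1970 + 10 * t,
                    "x": rng.uniform(0, 40),
                    "z": rng.normal(),
                })
    df = pd.DataFrame(rows)
    df["y"] = (
        2.0
        + 1.5 * df["x"]
        + 0.8 * df["z"]
        + rng.normal(0, 3, len(df))
        + np.repeat(rng.normal(0, 2, n_states), n_counties * n_periods)
    )
    return df


SPEC = dict(outcome="y", predictor="x", covariates_numeric=["z"])


class TestREMLInternals:
    def test_neg2_reml_matches_dense_oracle(self):
        df = _toy_frame()
        spec = ModelSpec(mode="linear", **SPEC)
        df = df.sort_values(["state_id", "county_id", "year"]).reset_index(drop=True)
        W, *_ = _build_design(df, spec, "linear")
        y = df["y"].to_numpy()
        sc = pd.factorize(df["state_id"], sort=True)[0]
        cc = pd.factorize(df["county_id"], sort=True)[0]
        prob = _REMLProblem(y, W, sc, cc)
        for gs, gc in [(0.5, 0.2), (2.0, 1.0), (1e-4, 3.0)]:
            n, p = W.shape
            Zs = np.eye(sc.max() + 1)[sc]
            Zc = np.eye(cc.max() + 1)[cc]
            V0 = np.eye(n) + gs * Zs @ Zs.T + gc * Zc @ Zc.T
            Vi = np.linalg.inv(V0)
            M = W.T @ Vi @ W
            beta = np.linalg.solve(M, W.T @ Vi @ y)
            Q = float((y - W @ beta) @ Vi @ (y - W @ beta))
            expected = (
                np.linalg.slogdet(V0)[1]
                + np.linalg.slogdet(M)[1]
                + (n - p) * np.log(Q)
            )
            got = prob.neg2_reml(np.log([gs, gc]))
            assert got == pytest.approx(expected, rel=1e-10)

    def test_fitted_beta_is_gls_at_estimated_components(self):
        df = _toy_frame(seed=4)
        fit = fit_hierarchical(df, ModelSpec(mode="linear", **SPEC))
        df = df.sort_values(["state_id", "county_id", "year"]).reset_index(drop=True)
        spec = ModelSpec(mode="linear", **SPEC)
        W, cols, *_ = _build_design(df, spec, "linear")
        y = df["y"].to_numpy()
        sc = pd.factorize(df["state_id"], sort=True)[0]
        cc = pd.factorize(df["county_id"], sort=True)[0]
        Zs = np.eye(sc.max() + 1)[sc]
        Zc = np.eye(cc.max() + 1)[cc]
        gs = fit.sigma2_state / fit.sigma2_eps
        gc = fit.sigma2_county / fit.sigma2_eps
        Vi = np.linalg.inv(np.eye(len(y)) + gs * Zs @ Zs.T + gc * Zc @ Zc.T)
        M = W.T @ Vi @ W
        beta = np.linalg.solve(M, W.T @ Vi @ y)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta, rtol=1e-8)
        np.testing.assert_allclose(
            fit.cov.to_numpy(), fit.sigma2_eps * np.linalg.inv(M), rtol=1e-6
        )


class TestFitting:
    def test_noiseless_exact_recovery(self):
        df = _toy_frame()
        df["y"] = 2.0 + 1.5 * (df["x"] - df["x"].mean()) + 0.8 * df["z"]
        fit = fit_hierarchical(df, ModelSpec(mode="linear", **SPEC))
        assert fit.coef["x"] == pytest.approx(1.5, abs=1e-8)
        assert fit.coef["z"] == pytest.approx(0.8, abs=1e-8)
        assert fit.sigma2_eps == pytest.approx(0.0, abs=1e-8)

    def test_row_order_invariance(self):
        df = _toy_frame(seed=2)
        fit1 = fit_hierarchical(df, ModelSpec(mode="linear", **SPEC))
        shuffled = df.sample(frac=1.0, random_state=99).reset_index(drop=True)
        fit2 = fit_hierarchical(shuffled, ModelSpec(mode="linear", **SPEC))
        np.testing.assert_allclose(
            fit1.coef.to_numpy(), fit2.coef.to_numpy(), rtol=1e-10
        )
        assert fit1.sigma2_eps == pytest.approx(fit2.sigma2_eps, rel=1e-8)

    def test_variance_component_scale(self, fit_data):
        table, _ = fit_data
        spec = ModelSpec(
            outcome="chg_industry_SO2", predictor="pct_black", mode="linear"
        )
        fit = fit_hierarchical(table, spec)
        # generator: sigma_eps = 10; single-realization tolerance is loose
        assert fit.sigma2_eps == pytest.approx(100.0, rel=0.35)
        assert 0.0 <= fit.sigma2_state < 200.0
        assert 0.0 <= fit.sigma2_county < 200.0

    def test_slope_recovery_on_generated_data(self, fit_data):
        table, truths = fit_data
        spec = ModelSpec(
            outcome="chg_industry_SO2", predictor="pct_black", mode="linear"
        )
        fit = fit_hierarchical(table, spec)
        se = np.sqrt(fit.cov.loc["pct_black", "pct_black"])
        assert fit.coef["pct_black"] == pytest.approx(1.5, abs=4 * se)

    def test_county_only_mode(self):
        df = _toy_frame()
        fit = fit_hierarchical(
            df, ModelSpec(mode="linear", random_effects="county_only", **SPEC)
        )
        assert fit.sigma2_state == 0.0
        assert fit.converged

    def test_single_state_rejected_for_nested(self):
        df = _toy_frame(n_states=1)
        with pytest.raises(ValueError, match="at least 2 states"):
            fit_hierarchical(df, ModelSpec(mode="linear", **SPEC))

    def test_missing_columns_rejected(self):
        df = _toy_frame().drop(columns="z")
        with pytest.raises(KeyError, match="z"):
            fit_hierarchical(df, ModelSpec(mode="linear", **SPEC))

    def test_nan_outcome_rejected(self):
        df = _toy_frame()
        df.loc[0, "y"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            fit_hierarchical(df, ModelSpec(mode="linear", **SPEC))

    def test_predictor_duplicated_in_covariates_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            ModelSpec(outcome="y", predictor="x", covariates_numeric=["x"])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            ModelSpec(outcome="y", predictor="x", mode="loess")


class TestEdf:
    def test_ridge_edf_limits_oracle(self):
        # independent check of the edf formula on a plain penalized problem
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 300)
        basis = PenalizedSplineBasis.from_data(x, dim=10)
        B = basis.evaluate(x)
        BtB = B.T @ B
        S = basis.penalty

        def edf(lam):
            return float(np.trace(np.linalg.solve(BtB + lam * S, BtB)))

        assert edf(0.0) == pytest.approx(9.0, abs=1e-8)
        assert edf(1e12) == pytest.approx(1.0, abs=1e-3)
        lams = 10.0 ** np.linspace(-4, 10, 15)
        es = [edf(l) for l in lams]
        assert all(a >= b - 1e-9 for a, b in zip(es, es[1:]))  # monotone

    def test_fitted_penalized_edf_in_range(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table,
            ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                      mode="penalized_spline"),
        )
        e = effective_df(fit, "pct_black")
        assert 1.0 - 1e-6 <= e <= 9.0 + 1e-6
        assert fit.lambda_ is not None and fit.lambda_ > 0

    def test_effective_df_unknown_term(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table,
            ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                      mode="linear"),
        )
        with pytest.raises(KeyError):
            effective_df(fit, "nope")

    def test_linearity_decision(self):
        assert linearity_decision(1.0) == "linear"
        assert linearity_decision(1.04) == "linear"
        assert linearity_decision(1.2) == "nonlinear"
        with pytest.raises(ValueError):
            linearity_decision(0.5)


class TestAutoMode:
    def test_linear_truth_resolves_linear(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table,
            ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                      mode="auto"),
        )
        assert fit.mode in ("linear", "natural_spline")
        assert fit.screening_edf is not None and fit.screening_edf >= 1.0 - 1e-6
        # the original auto spec is preserved on the result
        assert fit.spec.mode == "auto"

    def test_strong_curvature_resolves_nonlinear(self):
        cfg = SyntheticConfig(
            n_states=8, counties_per_state=12, seed=19,
            effect_spec={"pct_poverty": {"type": "quadratic", "scale": 25}},
        )
        demo = make_demographics(cfg, make_counties(cfg))
        out, _ = make_outcomes(cfg, demo)
        fit = fit_hierarchical(
            out, ModelSpec(outcome="rel_change", predictor="pct_poverty",
                           mode="auto"),
        )
        assert fit.mode == "natural_spline"
        assert fit.screening_edf > 1.05


class TestCurvesAndEffects:
    def test_linear_curve_is_slope_times_offset(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table, ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                             mode="linear"),
        )
        curve = association_curve(fit)
        slope = fit.coef["pct_black"]
        np.testing.assert_allclose(
            curve.fit, slope * (curve.grid - fit.reference), rtol=1e-10
        )
        se = np.sqrt(fit.cov.loc["pct_black", "pct_black"])
        np.testing.assert_allclose(
            curve.hi - curve.fit,
            1.959963984540054 * np.abs(curve.grid - fit.reference) * se,
            rtol=1e-8,
        )

    def test_curve_zero_at_reference(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table, ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                             mode="natural_spline"),
        )
        curve = association_curve(fit, grid=np.array([fit.reference]))
        assert curve.fit[0] == 0.0 and curve.lo[0] == 0.0 and curve.hi[0] == 0.0

    def test_extrapolation_warns(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table, ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                             mode="linear"),
        )
        with pytest.warns(UserWarning, match="outside the observed"):
            curve = association_curve(
                fit, grid=np.array([fit.x_max + 10.0])
            )
        assert curve.extrapolated[0]

    def test_linear_effect_arithmetic(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table, ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                             mode="linear"),
        )
        eff = linear_effect(fit)
        slope = float(fit.coef["pct_black"])
        se = float(np.sqrt(fit.cov.loc["pct_black", "pct_black"]))
        assert eff["estimate"] == pytest.approx(10.0 * slope)
        assert eff["lo"] == pytest.approx(10.0 * (slope - 1.959963984540054 * se))
        assert eff["hi"] == pytest.approx(10.0 * (slope + 1.959963984540054 * se))

    def test_linear_effect_refuses_nonlinear_predictor(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table, ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                             mode="natural_spline"),
        )
        with pytest.raises(ValueError, match="nonlinear"):
            linear_effect(fit)

    def test_linear_effect_on_covariate_of_nonlinear_model(self, fit_data):
        table, _ = fit_data
        fit = fit_hierarchical(
            table,
            ModelSpec(outcome="chg_industry_SO2", predictor="pct_black",
                      mode="natural_spline", covariates_numeric=["pct_white"]),
        )
        eff = linear_effect(fit, "pct_white")
        assert eff["estimate"] == pytest.approx(10.0 * fit.coef["pct_white"])
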