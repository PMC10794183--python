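"""Hierarchical models for county-level relative emission changes.

The model is a linear mixed model with random intercepts for counties nested
within states,

    Y_tc = (β0 + b_s + b_c|s) + g(X_tc) + βz' Z_tc + ε_tc ,

where Y_tc is the relative decennial emission change (percentage points) of
county c from year t to t+10, X is the predictor of interest, Z collects
covariates (population density, urbanicity, region group, year as categorical,
plus any adjustment variables), b_s ~ N(0, σ²_state), b_c|s ~ N(0, σ²_county)
and ε ~ N(0, σ²_ε). The predictor term g(·) is either linear, a penalized
cubic B-spline smooth (smoothing parameter chosen by GCV), or an unpenalized
natural cubic spline; ``mode="auto"`` runs the two-stage protocol used for the
main analyses: a penalized-spline screening fit, the edf > 1 rule to decide
linearity, then a final linear or natural-spline(4 df) refit.

Everything is estimated from scratch: variance components by profiled REML
(Woodbury identities on the two sparse random-intercept blocks keep each
evaluation at O(q³) for q = #states + #counties), fixed effects by generalized
least squares given the variance components, and the smoothing parameter by
GCV on the whitened penalized least-squares problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .splines import NaturalSplineBasis, PenalizedSplineBasis, natural_spline_basis

__all__ = [
    "ModelSpec",
    "FitResult",
    "AssociationCurve",
    "fit_hierarchical",
    "effective_df",
    "linearity_decision",
    "association_curve",
    "linear_effect",
]

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class ModelSpec:
    """Specification of one hierarchical model.

    ``mode`` ∈ {"auto", "linear", "penalized_spline", "natural_spline"}.
    ``covariates_numeric`` enter linearly; ``covariates_categorical`` are
    dummy-coded with the alphabetically first level as reference. ``reference``
    is the predictor value at which association curves are centered (default:
    the predictor's sample mean).
    """

    outcome: str
    predictor: str
    mode: str = "auto"
    ns_df: int = 4
    bspline_dim: int = 10
    covariates_numeric: list = field(default_factory=list)
    covariates_categorical: list = field(default_factory=list)
    state_col: str = "state_id"
    county_col: str = "county_id"
    reference: float | None = None
    linearity_tolerance: float = 0.05
    gcv_gamma: float = 1.4  # edf inflation guarding against GCV undersmoothing
    random_effects: str = "nested"  # or "county_only" for sensitivity

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "linear", "penalized_spline", "natural_spline"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.predictor in self.covariates_numeric:
            raise ValueError("predictor duplicated in the covariate list")
        if self.random_effects not in ("nested", "county_only"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")


@dataclass
class AssociationCurve:
    """Centered fitted curve ĝ(x) − ĝ(x_ref) with pointwise 95% CI."""

    grid: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    reference: float
    extrapolated: np.ndarray | None = None  # mask of grid points outside data


@dataclass
class FitResult:
    """A fitted hierarchical model."""

    spec: ModelSpec
    coef: pd.Series
    cov: pd.DataFrame
    sigma2_state: float
    sigma2_county: float
    sigma2_eps: float
    lambda_: float | None
    edf: dict
    log_reml: float
    converged: bool
    n: int
    n_states: int
    n_counties: int
    mode: str  # the mode actually fitted (auto resolves to linear/natural_spline)
    term_columns: dict  # term name -> list of coefficient names
    basis: NaturalSplineBasis | PenalizedSplineBasis | None
    reference: float
    x_min: float
    x_max: float
    x_inner: tuple  # (5th, 95th) percentile of the predictor
    screening_edf: float | None = None  # edf of the auto-mode screening smooth
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "predictor": self.spec.predictor,
            "mode": self.mode,
            "coef": self.coef.to_dict(),
            "se": {k: float(np.sqrt(self.cov.loc[k, k])) for k in self.coef.index},
            "sigma2_state": self.sigma2_state,
            "sigma2_county": self.sigma2_county,
            "sigma2_eps": self.sigma2_eps,
            "lambda": self.lambda_,
            "edf": self.edf,
            "screening_edf": self.screening_edf,
            "log_reml": self.log_reml,
            "converged": self.converged,
            "n": self.n,
            "n_states": self.n_states,
            "n_counties": self.n_counties,
            "reference": self.reference,
        }


class _REMLProblem:
    """Profiled REML for a two-level random-intercept LMM.

    All O(n) cross-products are computed once; each objective evaluation
    costs one Cholesky of the q × q capacitance matrix (q = S + C).
    """

    def __init__(self, y, W, state_codes, county_codes, nested=True):
        self.n, self.p = W.shape
        self.nested = nested
        self.S = int(state_codes.max()) + 1 if nested else 0
        self.C = int(county_codes.max()) + 1
        self.yy = float(y @ y)
        self.Wy = W.T @ y
        self.WW = W.T @ W
        self.ZcW = np.zeros((self.C, self.p))
        np.add.at(self.ZcW, county_codes, W)
        self.Zcy = np.bincount(county_codes, weights=y, minlength=self.C)
        self.nc = np.bincount(county_codes, minlength=self.C).astype(float)
        if nested:
            self.ZsW = np.zeros((self.S, self.p))
            np.add.at(self.ZsW, state_codes, W)
            self.Zsy = np.bincount(state_codes, weights=y, minlength=self.S)
            self.ns = np.bincount(state_codes, minlength=self.S).astype(float)
            # county -> state map (each county belongs to exactly one state)
            cs = np.full(self.C, -1, dtype=int)
            cs[county_codes] = state_codes
            self.county_state = cs

    def gls_blocks(self, gs: float, gc: float):
        """Return (M, my, yVy, logdetV0) for V0 = I + γs ZsZs' + γc ZcZc'."""
        if self.nested:
            q = self.S + self.C
            A = np.zeros((q, q))
            A[np.arange(self.S), np.arange(self.S)] = 1.0 + gs * self.ns
            idx = self.S + np.arange(self.C)
            A[idx, idx] = 1.0 + gc * self.nc
            cross = np.sqrt(gs * gc) * self.nc
            A[self.county_state, idx] = cross
            A[idx, self.county_state] = cross
            UtW = np.vstack([np.sqrt(gs) * self.ZsW, np.sqrt(gc) * self.ZcW])
            Uty = np.concatenate([np.sqrt(gs) * self.Zsy, np.sqrt(gc) * self.Zcy])
        else:
            A = np.diag(1.0 + gc * self.nc)
            UtW = np.sqrt(gc) * self.ZcW
            Uty = np.sqrt(gc) * self.Zcy
        cf = cho_factor(A, lower=True)
        logdetV0 = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        AinvUtW = cho_solve(cf, UtW)
        AinvUty = cho_solve(cf, Uty)
        M = self.WW - UtW.T @ AinvUtW
        my = self.Wy - UtW.T @ AinvUty
        yVy = self.yy - float(Uty @ AinvUty)
        return M, my, yVy, logdetV0

    def neg2_reml(self, log_g) -> float:
        gs = float(np.exp(np.clip(log_g[0], -30, 30))) if self.nested else 0.0
        gc = float(np.exp(np.clip(log_g[-1], -30, 30)))
        M, my, yVy, logdetV0 = self.gls_blocks(gs, gc)
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(M, my)
        Q = max(yVy - float(my @ beta), 1e-300)
        return logdetV0 + logdetM + (self.n - self.p) * np.log(Q)


def _dummies(series: pd.Series, name: str) -> pd.DataFrame:
    """Reference-level dummy coding; reference = first level alphabetically."""
    levels = sorted(pd.unique(series.astype(str)))
    cols = {}
    for lev in levels[1:]:
        cols[f"{name}[{lev}]"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def _build_design(data: pd.DataFrame, spec: ModelSpec, mode: str):
    """Assemble (W, colnames, term_columns, basis, reference)."""
    x = data[spec.predictor].to_numpy(dtype=float)
    reference = float(np.mean(x)) if spec.reference is None else float(spec.reference)
    parts = [pd.Series(1.0, index=data.index, name="(intercept)")]
    term_columns: dict = {"(intercept)": ["(intercept)"]}
    for c in spec.covariates_categorical:
        d = _dummies(data[c], c)
        parts.append(d)
        term_columns[c] = list(d.columns)
    for c in spec.covariates_numeric:
        parts.append(data[c].astype(float).rename(c))
        term_columns[c] = [c]
    basis = None
    if mode == "linear":
        pred = pd.Series(x - reference, index=data.index, name=spec.predictor)
        parts.append(pred)
        term_columns[spec.predictor] = [spec.predictor]
    elif mode == "natural_spline":
        basis = natural_spline_basis(x, df=spec.ns_df, reference=reference)
        Bm = basis.evaluate(x)
        names = [f"{spec.predictor}.ns{i+1}" for i in range(Bm.shape[1])]
        parts.append(pd.DataFrame(Bm, index=data.index, columns=names))
        term_columns[spec.predictor] = names
    elif mode == "penalized_spline":
        basis = PenalizedSplineBasis.from_data(
            x, dim=spec.bspline_dim, reference=reference
        )
        Bm = basis.evaluate(x)
        names = [f"{spec.predictor}.ps{i+1}" for i in range(Bm.shape[1])]
        parts.append(pd.DataFrame(Bm, index=data.index, columns=names))
        term_columns[spec.predictor] = names
    else:  # pragma: no cover
        raise ValueError(mode)
    Wdf = pd.concat(parts, axis=1)
    return Wdf.to_numpy(dtype=float), list(Wdf.columns), term_columns, basis, reference


def _golden_min(f, lo: float, hi: float, tol: float = 1e-3) -> float:
    """Golden-section minimizer on [lo, hi] (used on log10 λ)."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_hierarchical(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the hierarchical model described by ``spec``.

    Records are internally sorted by (state, county, year) so that estimates
    are invariant to input row order. Requires a complete outcome column and,
    for nested random effects, at least two states.
    """
    needed = (
        [spec.outcome, spec.predictor, spec.state_col, spec.county_col]
        + spec.covariates_numeric
        + spec.covariates_categorical
    )
    missing_cols = [c for c in needed if c not in data.columns]
    if missing_cols:
        raise KeyError(f"data lacks columns {missing_cols}")
    if data[spec.outcome].isna().any():
        raise ValueError("missing values in the outcome column")
    sort_cols = [spec.state_col, spec.county_col]
    if "year" in data.columns:
        sort_cols.append("year")
    df = data.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    state_codes = pd.factorize(df[spec.state_col], sort=True)[0]
    county_codes = pd.factorize(df[spec.county_col], sort=True)[0]
    n_states = int(state_codes.max()) + 1
    n_counties = int(county_codes.max()) + 1
    nested = spec.random_effects == "nested"
    if nested and n_states < 2:
        raise ValueError("nested random effects need at least 2 states")

    if spec.mode == "auto":
        screen_spec = ModelSpec(**{**spec.__dict__, "mode": "penalized_spline"})
        screen = fit_hierarchical(df, screen_spec)
        decision = linearity_decision(
            screen.edf[spec.predictor], spec.linearity_tolerance
        )
        final_mode = "linear" if decision == "linear" else "natural_spline"
        final_spec = ModelSpec(**{**spec.__dict__, "mode": final_mode})
        result = fit_hierarchical(df, final_spec)
        result.screening_edf = screen.edf[spec.predictor]
        result.spec = spec
        return result

    W, colnames, term_columns, basis, reference = _build_design(df, spec, spec.mode)
    y = df[spec.outcome].to_numpy(dtype=float)
    x = df[spec.predictor].to_numpy(dtype=float)
    n, p = W.shape
    prob = _REMLProblem(y, W, state_codes, county_codes, nested=nested)

    # degenerate noiseless data: OLS residual ~ 0 => skip the REML search
    beta_ols, res_ols, *_ = np.linalg.lstsq(W, y, rcond=None)
    rss_ols = float(np.sum((y - W @ beta_ols) ** 2))
    degenerate = rss_ols <= 1e-12 * max(prob.yy, 1.0)

    converged = True
    message = ""
    if degenerate:
        gs_hat, gc_hat = 0.0, 0.0
        log_reml = np.inf
    else:
        x0 = [0.0, 0.0] if nested else [0.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimize.minimize(
                prob.neg2_reml,
                x0=np.asarray(x0),
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 500},
            )
        converged = bool(opt.success)
        message = str(opt.message)
        if nested:
            gs_hat = float(np.exp(np.clip(opt.x[0], -30, 30)))
            gc_hat = float(np.exp(np.clip(opt.x[-1], -30, 30)))
        else:
            gs_hat, gc_hat = 0.0, float(np.exp(np.clip(opt.x[0], -30, 30)))
        log_reml = -0.5 * float(opt.fun)

    M, my, yVy, _ = prob.gls_blocks(gs_hat, gc_hat)

    lam = None
    edf: dict = {}
    if spec.mode == "penalized_spline":
        sl = [colnames.index(c) for c in term_columns[spec.predictor]]
        S_full = np.zeros((p, p))
        S_full[np.ix_(sl, sl)] = basis.penalty

        def gcv(log10_lam: float) -> float:
            P = (10.0 ** log10_lam) * S_full
            try:
                cf = cho_factor(M + P, lower=True)
            except np.linalg.LinAlgError:
                return np.inf
            delta = cho_solve(cf, my)
            E = cho_solve(cf, M)
            edf_tot = float(np.trace(E))
            rss = yVy - 2.0 * float(my @ delta) + float(delta @ M @ delta)
            denom = max(n - spec.gcv_gamma * edf_tot, 1e-8)
            return n * max(rss, 1e-300) / denom**2

        grid = np.linspace(-4.0, 8.0, 25)
        vals = [gcv(g) for g in grid]
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        lam = 10.0 ** _golden_min(gcv, lo, hi)
        P = lam * S_full
        cf = cho_factor(M + P, lower=True)
        beta = cho_solve(cf, my)
        E = cho_solve(cf, M)
        edf_tot = float(np.trace(E))
        edf[spec.predictor] = float(np.trace(E[np.ix_(sl, sl)]))
        rss = yVy - 2.0 * float(my @ beta) + float(beta @ M @ beta)
        sigma2_eps = max(rss, 0.0) / max(n - edf_tot, 1.0)
        cov = sigma2_eps * cho_solve(cf, np.eye(p))  # Bayesian covariance
    else:
        try:
            cf = cho_factor(M, lower=True)
            beta = cho_solve(cf, my)
            Minv = cho_solve(cf, np.eye(p))
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(M, my, rcond=None)
            Minv = np.linalg.pinv(M)
        Q = max(yVy - float(my @ beta), 0.0)
        sigma2_eps = Q / max(n - p, 1)
        cov = sigma2_eps * Minv
        if spec.mode == "natural_spline":
            edf[spec.predictor] = float(len(term_columns[spec.predictor]))
        else:
            edf[spec.predictor] = 1.0

    pct = np.percentile(x, [5, 95])
    return FitResult(
        spec=spec,
        coef=pd.Series(beta, index=colnames),
        cov=pd.DataFrame(cov, index=colnames, columns=colnames),
        sigma2_state=gs_hat * sigma2_eps,
        sigma2_county=gc_hat * sigma2_eps,
        sigma2_eps=sigma2_eps,
        lambda_=lam,
        edf=edf,
        log_reml=log_reml,
        converged=converged,
        n=n,
        n_states=n_states,
        n_counties=n_counties,
        mode=spec.mode,
        term_columns=term_columns,
        basis=basis,
        reference=reference,
        x_min=float(x.min()),
        x_max=float(x.max()),
        x_inner=(float(pct[0]), float(pct[1])),
        message=message,
    )


def effective_df(fit: FitResult, term: str) -> float:
    """Effective degrees of freedom of a fitted smooth term.

    For a penalized smooth this is the trace of the hat-matrix block of the
    term; 1 means the smooth has collapsed to a straight line.
    """
    if term not in fit.edf:
        raise KeyError(f"term {term!r} not found in fit (has {sorted(fit.edf)})")
    return fit.edf[term]


def linearity_decision(edf: float, tolerance: float = 0.05) -> str:
    """Classify a smooth as linear (edf ≈ 1) or nonlinear (edf > 1)."""
    if edf < 1.0 - 1e-6:
        raise ValueError(f"edf must be >= 1, got {edf}")
    return "linear" if edf <= 1.0 + tolerance else "nonlinear"


def _curve_design(fit: FitResult, grid: np.ndarray, reference: float) -> np.ndarray:
    """Design rows for the centered contrast ĝ(x) − ĝ(reference)."""
    if fit.mode == "linear":
        return (grid - reference)[:, None]
    if fit.mode == "natural_spline":
        raw = fit.basis._raw(grid) - fit.basis._raw(np.array([reference]))
        return raw
    return fit.basis.evaluate_centered(grid, reference)


def association_curve(
    fit: FitResult,
    term: str | None = None,
    grid: np.ndarray | None = None,
    reference: float | None = None,
) -> AssociationCurve:
    """Centered association curve with pointwise 95% CI.

    The curve is ĝ(x) − ĝ(x_ref) with a delta-method CI from the fixed-effect
    covariance of the term's coefficients; it is exactly (0, 0, 0) at the
    reference. Grid points outside the observed predictor range are flagged
    as extrapolated (with a warning).
    """
    if not fit.converged:
        raise RuntimeError("association_curve requires a converged fit")
    term = term or fit.spec.predictor
    if term not in fit.term_columns:
        raise KeyError(f"term {term!r} not in model")
    ref = fit.reference if reference is None else float(reference)
    if grid is None:
        grid = np.linspace(fit.x_min, fit.x_max, 101)
    grid = np.asarray(grid, dtype=float)
    extrap = (grid < fit.x_min) | (grid > fit.x_max)
    if extrap.any():
        warnings.warn(
            "association curve evaluated outside the observed predictor range",
            stacklevel=2,
        )
    cols = fit.term_columns[term]
    Xg = _curve_design(fit, grid, ref)
    beta = fit.coef[cols].to_numpy()
    V = fit.cov.loc[cols, cols].to_numpy()
    est = Xg @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
    return AssociationCurve(
        grid=grid,
        fit=est,
        lo=est - Z975 * se,
        hi=est + Z975 * se,
        reference=ref,
        extrapolated=extrap,
    )


def linear_effect(fit: FitResult, term: str | None = None, delta: float = 10.0):
    """Effect (with 95% CI) per ``delta``-unit increase of a linear term.

    The conventional report is the percentage-point change in the relative
    emission change per 10 pp increase in the demographic variable. Refuses
    nonlinear terms.
    """
    term = term or fit.spec.predictor
    if fit.mode != "linear" and term == fit.spec.predictor:
        raise ValueError(f"term {term!r} was fitted nonlinearly; no single slope")
    cols = fit.term_columns[term]
    if len(cols) != 1:
        raise ValueError(f"term {term!r} is not a single linear column")
    slope = float(fit.coef[cols[0]])
    se = float(np.sqrt(fit.cov.loc[cols[0], cols[0]]))
    return {
        "estimate": delta * slope,
        "lo": delta * (slope - Z975 * se),
        "hi": delta * (slope + Z975 * se),
        "delta": delta,
    }
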