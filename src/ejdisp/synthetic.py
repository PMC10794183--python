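"""Synthetic study generator: grids, county mosaics, demographics, outcomes.

Everything downstream of raw data acquisition can be exercised without any
download: this module fabricates (i) a planar county mosaic nested in states,
(ii) per-decade gridded emission-flux fields with sector-specific decade
trends, (iii) county × decade demographic/SES tables with realistic
cross-correlations, and (iv) relative-change outcomes drawn exactly from the
hierarchical generative model

    Y_tc = β0 + b_s + b_c|s + Σ_p f_p(X_p,tc) + ε_tc

with known ground truth, either directly ("table mode") or encoded into
gridded fields whose aggregation and differencing reproduce the table-mode
outcomes ("field mode", for end-to-end tests).

Default sector base fluxes and decade trend factors reproduce the nationwide
mean flux trajectories of the seven emission series studied (e.g. industry
SO2 falling 5.6 → 0.6 kg/km²/day over four decades). Geometry is planar
(Cartesian km) by design: it isolates the aggregation algorithm from
projection handling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .aggregation import intersect_weights
from .counties import CountyMosaic
from .covariates import CPISeries
from .grids import GridField

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "make_counties",
    "make_grid",
    "make_demographics",
    "make_outcomes",
    "outcomes_to_fields",
    "default_cpi_series",
    "SECTOR_SERIES",
]

# (sector, pollutant) -> (1970 base flux kg/km²/day, multiplicative decade factor)
# Base levels and 40-year endpoints follow the nationwide mean flux trajectories
# of the seven series analyzed; the factor is the constant per-decade multiplier
# consistent with those endpoints.
SECTOR_SERIES = {
    ("industry", "SO2"): (5.6, (0.6 / 5.6) ** 0.25),
    ("energy", "SO2"): (9.0, (3.0 / 9.0) ** 0.25),
    ("energy", "NOx"): (2.5, (1.5 / 2.5) ** 0.25),
    ("agriculture", "NH3"): (0.7, (1.3 / 0.7) ** 0.25),
    ("transportation", "NOx"): (5.2, (2.2 / 5.2) ** 0.25),
    ("residential", "OC"): (0.1, 1.0),
    ("commercial", "NOx"): (0.3, (0.2 / 0.3) ** 0.25),
}

_STAGE = {"counties": 0, "grid": 1, "demographics": 2, "outcomes": 3}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``sector_trend`` maps (sector, pollutant) to a per-decade multiplicative
    factor; ``effect_spec`` maps predictor column name to a true association,
    e.g. ``{"type": "linear", "slope": 1.5}``,
    ``{"type": "quadratic", "scale": 10}``, ``{"type": "cubic", "scale": 10}``,
    ``{"type": "hinge", "scale": 10}`` or ``{"type": "none"}``
    (scales in pp of relative change). σ values are standard deviations in pp
    of relative change.
    """

    n_states: int = 10
    counties_per_state: int = 50
    grid_resolution: float = 50.0  # cell edge, planar km
    decades: tuple = (1970, 1980, 1990, 2000, 2010)
    sector_trend: dict = field(default_factory=lambda: {
        k: v[1] for k, v in SECTOR_SERIES.items()
    })
    sector_base: dict = field(default_factory=lambda: {
        k: v[0] for k, v in SECTOR_SERIES.items()
    })
    decade_noise: float = 0.1  # lognormal sd of per-cell decade jitter
    spatial_sigma: float = 0.6  # lognormal sd of the smooth spatial base field
    spatial_range: float = 3.0  # Gaussian-kernel smoothing radius, in cells
    effect_spec: dict = field(default_factory=dict)
    beta0: float = 0.0
    sigma_state: float = 5.0
    sigma_county: float = 5.0
    sigma_eps: float = 10.0
    income_poverty_corr: float = -0.6
    split_fraction: float = 0.0  # fraction of counties that split after decade 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.counties_per_state < 1:
            raise ValueError("need at least one state and one county per state")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")
        if any(b <= a for a, b in zip(self.decades, self.decades[1:])):
            raise ValueError("decades must be strictly increasing")
        for name in ("sigma_state", "sigma_county", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1.0 < self.income_poverty_corr < 1.0:
            raise ValueError("income_poverty_corr must be in (-1, 1)")
        if not 0.0 <= self.split_fraction <= 0.5:
            raise ValueError("split_fraction must be in [0, 0.5]")

    def rng(self, stage: str, key: str | None = None) -> np.random.Generator:
        """Independent sub-stream per pipeline stage (and optional name key)."""
        spawn = (_STAGE[stage],)
        if key is not None:
            spawn = spawn + (zlib.crc32(key.encode()) % (2**31),)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=spawn)
        )


@dataclass
class TruthRecord:
    """Ground truth behind one generated outcome column."""

    beta0: float
    effects: dict  # predictor -> dict describing the true f_p
    state_intercepts: pd.Series
    county_intercepts: pd.Series
    eps: np.ndarray
    predictor_centers: dict  # predictor -> center used by f_p

    def true_function(self, predictor: str, x) -> np.ndarray:
        """Evaluate the true f_p at x (same parameterization used to simulate)."""
        return _eval_effect(
            self.effects[predictor], np.asarray(x, dtype=float),
            self.predictor_centers[predictor]["center"],
            self.predictor_centers[predictor]["scale"],
        )


_STATE_W, _STATE_H = 240.0, 200.0  # planar km per state rectangle


def make_counties(config: SyntheticConfig) -> CountyMosaic:
    """Tile a rectangular domain with states, each tiled by its counties.

    States sit on a near-square grid of 240 × 200 km rectangles; within a
    state, counties fill rows of random (Dirichlet) heights and widths, so
    the union of county polygons equals the domain exactly. With
    ``split_fraction > 0`` a random subset of counties splits in half in
    every decade after the first (ids suffixed ``/a`` and ``/b``).
    """
    rng = config.rng("counties")
    S, cps = config.n_states, config.counties_per_state
    s_cols = int(np.ceil(np.sqrt(S)))
    polys = []  # (county_id, state_id, geometry) for the first decade
    for s in range(S):
        sx, sy = s % s_cols, s // s_cols
        x0, y0 = sx * _STATE_W, sy * _STATE_H
        c_rows = int(np.ceil(np.sqrt(cps)))
        per_row = np.full(c_rows, cps // c_rows)
        per_row[: cps % c_rows] += 1
        per_row = per_row[per_row > 0]
        heights = rng.dirichlet(np.full(len(per_row), 8.0)) * _STATE_H
        yy = y0
        cid = 0
        for k, h in zip(per_row, heights):
            widths = rng.dirichlet(np.full(k, 8.0)) * _STATE_W
            xx = x0
            for w in widths:
                polys.append(
                    (f"S{s:03d}C{cid:03d}", f"S{s:03d}", box(xx, yy, xx + w, yy + h))
                )
                cid += 1
                xx += w
            yy += h
    rows = []
    n_split = int(round(config.split_fraction * len(polys)))
    split_ids = set(
        rng.choice([p[0] for p in polys], size=n_split, replace=False).tolist()
    ) if n_split else set()
    for decade in config.decades:
        first = decade == config.decades[0]
        for cid, sid, geom in polys:
            if not first and cid in split_ids:
                xmin, ymin, xmax, ymax = geom.bounds
                xm = 0.5 * (xmin + xmax)
                rows.append({"county_id": f"{cid}/a", "state_id": sid,
                             "decade": decade, "geometry": box(xmin, ymin, xm, ymax)})
                rows.append({"county_id": f"{cid}/b", "state_id": sid,
                             "decade": decade, "geometry": box(xm, ymin, xmax, ymax)})
            else:
                rows.append({"county_id": cid, "state_id": sid,
                             "decade": decade, "geometry": geom})
    return CountyMosaic(pd.DataFrame(rows))


def _grid_edges(config: SyntheticConfig, mosaic: CountyMosaic):
    xmin, ymin, xmax, ymax = mosaic.bounds()
    res = config.grid_resolution
    nx = int(np.ceil((xmax - xmin) / res - 1e-9))
    ny = int(np.ceil((ymax - ymin) / res - 1e-9))
    return xmin + res * np.arange(nx + 1), ymin + res * np.arange(ny + 1)


def make_grid(config: SyntheticConfig, mosaic: CountyMosaic) -> list[GridField]:
    """One flux field per decade × (sector, pollutant).

    Each series starts from a smooth lognormal spatial base field with the
    sector's nationwide base level, multiplied each decade by the sector's
    trend factor and (optionally) independent lognormal cell jitter of sd
    ``decade_noise``; both lognormals are mean-corrected so the expected
    national mean follows base × factor^k exactly.
    """
    rng = config.rng("grid")
    x_edges, y_edges = _grid_edges(config, mosaic)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    fields = []
    for (sector, pollutant), base in sorted(config.sector_base.items()):
        factor = config.sector_trend.get((sector, pollutant), 1.0)
        raw = rng.standard_normal((ny, nx))
        if config.spatial_sigma > 0:
            smooth = ndimage.gaussian_filter(raw, sigma=config.spatial_range,
                                             mode="wrap")
            sd = smooth.std()
            smooth = smooth / sd if sd > 0 else smooth
            base_field = base * np.exp(
                config.spatial_sigma * smooth - 0.5 * config.spatial_sigma**2
            )
        else:
            base_field = np.full((ny, nx), base)
        for k, decade in enumerate(config.decades):
            jitter = 1.0
            if config.decade_noise > 0:
                jitter = np.exp(
                    config.decade_noise * rng.standard_normal((ny, nx))
                    - 0.5 * config.decade_noise**2
                )
            fields.append(
                GridField(
                    x_edges=x_edges,
                    y_edges=y_edges,
                    flux=base_field * factor**k * jitter,
                    pollutant=pollutant,
                    sector=sector,
                    year=decade,
                )
            )
    return fields


# latent factors: white, black, asian, amindian, hispanic, income, poverty,
# unemployment, propval, population
_DEMO_VARS = ["pct_white", "pct_black", "pct_asian", "pct_amindian",
              "pct_hispanic", "median_income", "pct_poverty",
              "pct_unemployment", "property_value", "population"]


def _latent_correlation(income_poverty: float) -> np.ndarray:
    """Target correlation of the latent Gaussian factors (made PD by jitter)."""
    k = len(_DEMO_VARS)
    R = np.eye(k)

    def set_(a, b, v):
        i, j = _DEMO_VARS.index(a), _DEMO_VARS.index(b)
        R[i, j] = R[j, i] = v

    set_("pct_white", "pct_black", -0.70)
    set_("pct_white", "pct_hispanic", -0.35)
    set_("pct_white", "median_income", 0.20)
    set_("pct_black", "pct_poverty", 0.35)
    # transform attenuation for the lognormal income (sd 0.25) is ~1.6%;
    # inflate the latent correlation accordingly so the requested sample
    # correlation is met on the output scale
    set_("median_income", "pct_poverty", np.clip(income_poverty / 0.984, -0.99, 0.99))
    set_("median_income", "property_value", 0.60)
    set_("median_income", "population", 0.25)
    set_("pct_poverty", "pct_unemployment", 0.50)
    # ensure positive definiteness
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-6:
        w = np.maximum(w, 1e-6)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def make_demographics(config: SyntheticConfig, mosaic: CountyMosaic) -> pd.DataFrame:
    """County × decade demographic/SES table.

    Race/ethnicity percentages come from independent logistic-normal
    constructions (so their sum may exceed 100, as in census tables where
    racial groups include both Hispanic and non-Hispanic populations);
    income and property value are lognormal 2010 dollars; poverty and
    unemployment are near-Gaussian percentages clipped to [0, 100];
    population is lognormal. A persistent county-level latent factor plus a
    smaller decade-specific innovation gives within-county correlation over
    time. Demographic years are all decades except the last.
    """
    rng = config.rng("demographics")
    first = mosaic.for_decade(config.decades[0]).table
    counties = first[["county_id", "state_id"]]
    n = len(counties)
    years = list(config.decades[:-1])
    R = _latent_correlation(config.income_poverty_corr)
    L = np.linalg.cholesky(R)
    k = len(_DEMO_VARS)
    base = (L @ rng.standard_normal((k, n))).T  # persistent county factors
    rows = []
    rho = np.sqrt(0.85)
    for ti, year in enumerate(years):
        innov = (L @ rng.standard_normal((k, n))).T
        z = rho * base + np.sqrt(1 - rho**2) * innov
        zd = pd.DataFrame(z, columns=_DEMO_VARS)
        sig = lambda v: 100.0 / (1.0 + np.exp(-v))
        df = pd.DataFrame(
            {
                "county_id": counties["county_id"].to_numpy(),
                "state_id": counties["state_id"].to_numpy(),
                "year": year,
                "pct_white": sig(2.0 + 0.9 * zd["pct_white"] - 0.05 * ti),
                "pct_black": sig(-3.0 + 1.5 * zd["pct_black"]),
                "pct_asian": sig(-5.5 + 1.2 * zd["pct_asian"] + 0.25 * ti),
                "pct_amindian": sig(-5.2 + 1.3 * zd["pct_amindian"] + 0.1 * ti),
                "pct_hispanic": sig(-3.8 + 1.4 * zd["pct_hispanic"] + 0.2 * ti),
                "median_income": np.exp(
                    np.log(45_000) + 0.06 * ti + 0.25 * zd["median_income"]
                ),
                "pct_poverty": np.clip(16.5 - 0.5 * ti + 6.0 * zd["pct_poverty"],
                                       0.0, 100.0),
                "pct_unemployment": np.clip(
                    5.5 + 2.0 * zd["pct_unemployment"], 0.0, 100.0
                ),
                "property_value": np.exp(
                    np.log(70_000) + 0.12 * ti + 0.5 * zd["property_value"]
                ),
                "population": np.exp(10.0 + 1.3 * zd["population"]),
            }
        )
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _eval_effect(effect: dict, x: np.ndarray, center: float, scale: float) -> np.ndarray:
    kind = effect.get("type", "linear")
    if kind == "linear":
        return effect["slope"] * (x - center)
    if kind == "quadratic":
        z = (x - center) / scale
        return effect["scale"] * (z**2 - 1.0)
    if kind == "cubic":
        z = (x - center) / scale
        return effect["scale"] * (z**3 - 3.0 * z) / np.sqrt(6.0)
    if kind == "hinge":
        # tent: rises to a peak at the center then falls (positive/negative)
        z = np.abs(x - center) / scale
        return effect["scale"] * (1.0 - z)
    if kind == "none":
        return np.zeros_like(x)
    raise ValueError(f"unknown effect type {kind!r}")


def make_outcomes(
    config: SyntheticConfig,
    demographics: pd.DataFrame,
    effect_spec: dict | None = None,
    name: str = "rel_change",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw outcomes from the hierarchical generative model.

    Returns a copy of ``demographics`` with an added outcome column ``name``
    (pp of relative decennial change) plus the :class:`TruthRecord` with the
    realized intercepts and noise. Effects are centered at each predictor's
    sample mean and scaled by its sample standard deviation, so the
    ``scale`` of a nonlinear effect is in pp of relative change.
    """
    effects = dict(config.effect_spec if effect_spec is None else effect_spec)
    unknown = [p for p in effects if p not in demographics.columns]
    if unknown:
        raise KeyError(f"effect_spec names unknown predictors: {unknown}")
    rng = config.rng("outcomes", key=name)
    df = demographics.copy()
    states = np.sort(df["state_id"].unique())
    counties = df[["county_id", "state_id"]].drop_duplicates().sort_values(
        ["state_id", "county_id"]
    )
    b_s = pd.Series(
        config.sigma_state * rng.standard_normal(len(states)), index=states
    )
    b_c = pd.Series(
        config.sigma_county * rng.standard_normal(len(counties)),
        index=counties["county_id"].to_numpy(),
    )
    eps = config.sigma_eps * rng.standard_normal(len(df))
    y = np.full(len(df), config.beta0, dtype=float)
    centers = {}
    for pred, eff in effects.items():
        x = df[pred].to_numpy(dtype=float)
        center = float(eff.get("center", np.mean(x)))
        scale = float(eff.get("width", np.std(x))) or 1.0
        centers[pred] = {"center": center, "scale": scale}
        y += _eval_effect(eff, x, center, scale)
    y += b_s.loc[df["state_id"]].to_numpy()
    y += b_c.loc[df["county_id"]].to_numpy()
    y += eps
    df[name] = y
    truth = TruthRecord(
        beta0=config.beta0,
        effects=effects,
        state_intercepts=b_s,
        county_intercepts=b_c,
        eps=eps,
        predictor_centers=centers,
    )
    return df, truth


def outcomes_to_fields(
    config: SyntheticConfig,
    mosaic: CountyMosaic,
    outcomes: pd.DataFrame,
    outcome_col: str = "rel_change",
    sector: str = "synthetic",
    pollutant: str = "X",
    base_flux: float = 5.0,
) -> list[GridField]:
    """Encode table-mode outcomes into per-decade gridded fields.

    County target fluxes start at ``base_flux`` in the first decade and are
    multiplied by (1 + Y/100) each period, so aggregating the fields and
    computing relative changes recovers the table-mode outcomes. Cell values
    solve the (underdetermined, consistent) area-weighting system exactly: a
    first-guess field assigns each cell the weight-averaged target of the
    counties covering it, and a minimum-norm least-squares correction makes
    every county aggregate exact. Requires all outcomes > −100 and a mosaic
    without boundary changes.
    """
    if config.split_fraction > 0:
        raise ValueError("field mode requires a mosaic without boundary changes")
    first = mosaic.for_decade(config.decades[0])
    wide = outcomes.pivot(index="county_id", columns="year", values=outcome_col)
    wide = wide.reindex(first.table["county_id"].to_numpy())
    if wide.isna().any().any():
        raise ValueError("outcomes must cover every county and demographic year")
    if (wide.to_numpy() <= -100.0).any():
        raise ValueError("cannot encode relative changes <= -100% as fluxes")
    x_edges, y_edges = _grid_edges(config, mosaic)
    probe = GridField(
        x_edges=x_edges,
        y_edges=y_edges,
        flux=np.zeros((len(y_edges) - 1, len(x_edges) - 1)),
        pollutant=pollutant,
        sector=sector,
        year=config.decades[0],
    )
    weights = intersect_weights(first, probe)
    n_cells = probe.flux.size
    n_cty = len(weights.county_ids)
    Wmat = np.zeros((n_cty, n_cells))
    Wmat[weights.county_index, weights.cell_index] = weights.area
    Wmat /= Wmat.sum(axis=1, keepdims=True)  # row-normalized: aggregation operator

    targets = np.empty((len(config.decades), n_cty))
    targets[0] = base_flux
    for k, year in enumerate(config.decades[:-1]):
        targets[k + 1] = targets[k] * (1.0 + wide[year].to_numpy() / 100.0)

    covered = Wmat.sum(axis=0) > 0
    fields = []
    for k, decade in enumerate(config.decades):
        t = targets[k]
        # initial guess: each cell takes the weight-averaged county target
        col_tot = Wmat.sum(axis=0)
        f0 = np.full(n_cells, base_flux)
        f0[covered] = (Wmat.T @ t)[covered] / col_tot[covered]
        resid = t - Wmat @ f0
        corr, *_ = np.linalg.lstsq(Wmat, resid, rcond=None)
        f = f0 + corr
        if (f < 0).any():
            raise ValueError(
                "field encoding produced negative fluxes; increase base_flux or "
                "reduce outcome dispersion"
            )
        fields.append(
            GridField(
                x_edges=x_edges,
                y_edges=y_edges,
                flux=f.reshape(probe.flux.shape),
                pollutant=pollutant,
                sector=sector,
                year=decade,
            )
        )
    return fields


def default_cpi_series() -> CPISeries:
    """A synthetic CPI research series for pipeline runs.

    The values are fabricated (a smooth inflation path normalized to 100 in
    2010); real analyses should supply the published research series instead.
    """
    years = range(1970, 2011)
    vals = {y: 100.0 * np.exp(-0.045 * (2010 - y)) for y in years}
    return CPISeries({y: round(v, 3) for y, v in vals.items()})
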