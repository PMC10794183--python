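"""Model batteries, association labelling, and report export.

The main analysis fits one hierarchical model per (predictor of interest ×
emission-change series). Models for the Black, Asian and American Indian
population percentages additionally adjust for the White population
percentage, and the White estimates are extracted from the Black+White models
rather than fitted separately, so the default main battery comprises 48
fitted models: 8 fitted predictors × 6 outcome series (the energy sector's
second pollutant series can be enabled via ``series="full"``, giving 56).
The sensitivity battery refits the five race/ethnicity predictors per series
with four SES covariates added (35 models, penalized splines throughout);
the regional battery fits median income and %Black(+%White) for industry SO2
and transportation NOx separately in each of the 8 EPA region groups
(32 models).

Each fitted association is classified into one of four public labels —
positive, negative, none, positive_negative — from the sign of the linear
effect (when the 95% CI excludes zero) or from the significant increasing /
decreasing segments of the centered association curve over the inner 90% of
the predictor range. Failed fits carry a fifth internal status,
``insufficient_data``, distinct from the four public labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import aggregate_flux, filter_by_centroid, intersect_weights
from .changes import (
    ExclusionPolicy,
    apply_exclusions,
    build_change_table,
    match_demographics,
)
from .covariates import assign_region_group, classify_urbanicity, population_density
from .mixed_model import (
    FitResult,
    ModelSpec,
    association_curve,
    fit_hierarchical,
    linear_effect,
)
from .synthetic import SyntheticConfig, make_counties, make_demographics, make_grid, make_outcomes

__all__ = [
    "RACE_PREDICTORS",
    "SES_PREDICTORS",
    "MAIN_SERIES",
    "FULL_SERIES",
    "BatteryConfig",
    "ModelTask",
    "BatteryResult",
    "run_main_battery",
    "run_sensitivity",
    "run_regional",
    "classify_association",
    "export_report",
    "load_report",
    "attach_covariates",
    "build_analysis_table",
    "simulate_study",
]

log = logging.getLogger(__name__)

RACE_PREDICTORS = ["pct_white", "pct_black", "pct_asian", "pct_amindian", "pct_hispanic"]
SES_PREDICTORS = ["median_income", "property_value", "pct_poverty", "pct_unemployment"]
# race predictors that adjust for %White (White itself is extracted from the
# Black+White model)
_WHITE_ADJUSTED = ["pct_black", "pct_asian", "pct_amindian"]

MAIN_SERIES = [
    "chg_industry_SO2",
    "chg_energy_SO2",
    "chg_agriculture_NH3",
    "chg_transportation_NOx",
    "chg_residential_OC",
    "chg_commercial_NOx",
]
FULL_SERIES = MAIN_SERIES[:2] + ["chg_energy_NOx"] + MAIN_SERIES[2:]
REGIONAL_SERIES = ["chg_industry_SO2", "chg_transportation_NOx"]
BASE_CATEGORICAL = ["urbanicity", "region_group", "year"]
BASE_NUMERIC = ["pop_density"]


@dataclass(frozen=True)
class ModelTask:
    """One model to fit: predictor × outcome (+ covariates and extractions)."""

    outcome: str
    predictor: str
    covariates_numeric: tuple = ()
    extract: tuple = ()  # covariate terms whose linear estimates are reported
    region: str | None = None
    mode: str = "auto"


@dataclass
class BatteryConfig:
    """Enumeration of a model battery; counts are pure functions of config."""

    battery: str = "main"  # main | sensitivity | regional
    series: str = "default"  # default (paper count) | full (both energy series)
    outcomes: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    declared_count: int | None = None
    linearity_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.battery not in ("main", "sensitivity", "regional"):
            raise ValueError(f"unknown battery {self.battery!r}")
        if not self.outcomes:
            if self.battery == "regional":
                self.outcomes = list(REGIONAL_SERIES)
            else:
                self.outcomes = list(MAIN_SERIES if self.series == "default" else FULL_SERIES)
        if not self.regions and self.battery == "regional":
            self.regions = ["R1-3"] + [f"R{r}" for r in range(4, 11)]
        if self.declared_count is None:
            self.declared_count = len(self.enumerate_tasks())

    def enumerate_tasks(self) -> list[ModelTask]:
        tasks = []
        if self.battery == "main":
            for out in self.outcomes:
                for pred in _WHITE_ADJUSTED:
                    tasks.append(
                        ModelTask(
                            outcome=out,
                            predictor=pred,
                            covariates_numeric=("pct_white",),
                            extract=("pct_white",) if pred == "pct_black" else (),
                        )
                    )
                tasks.append(ModelTask(outcome=out, predictor="pct_hispanic"))
                for pred in SES_PREDICTORS:
                    tasks.append(ModelTask(outcome=out, predictor=pred))
        elif self.battery == "sensitivity":
            for out in self.outcomes:
                for pred in RACE_PREDICTORS:
                    covs = tuple(s for s in SES_PREDICTORS)
                    if pred in _WHITE_ADJUSTED:
                        covs = ("pct_white",) + covs
                    tasks.append(
                        ModelTask(
                            outcome=out,
                            predictor=pred,
                            covariates_numeric=covs,
                            mode="penalized_spline",
                        )
                    )
        else:  # regional
            for region in self.regions:
                for out in self.outcomes:
                    tasks.append(
                        ModelTask(
                            outcome=out,
                            predictor="median_income",
                            region=region,
                            mode="penalized_spline",
                        )
                    )
                    tasks.append(
                        ModelTask(
                            outcome=out,
                            predictor="pct_black",
                            covariates_numeric=("pct_white",),
                            extract=("pct_white",),
                            region=region,
                            mode="penalized_spline",
                        )
                    )
        return tasks

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "battery": self.battery,
                "series": self.series,
                "outcomes": self.outcomes,
                "regions": self.regions,
                "declared_count": self.declared_count,
                "linearity_tolerance": self.linearity_tolerance,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BatteryResult:
    config: BatteryConfig
    fits: dict  # (outcome, predictor, region) -> FitResult
    statuses: dict  # same key -> "ok" | "insufficient_data"
    labels: dict  # same key -> association label (only for ok fits)
    extracted: dict  # (outcome, covariate, region) -> per-10pp effect dict
    seed: int | None = None

    @property
    def n_fitted(self) -> int:
        return len(self.fits)


def classify_association(fit: FitResult, derivative_tol: float | None = None) -> str:
    """Four-way association label for a fitted model.

    Linear fits: the slope's sign when its 95% CI excludes zero, else
    ``none``. Nonlinear fits: the centered curve is evaluated on the inner
    90% of the predictor range; where the pointwise CI excludes zero the
    local derivative's sign is collected — only increasing segments →
    ``positive``, only decreasing → ``negative``, both → ``positive_negative``,
    no significant segment → ``none``.
    """
    if not fit.converged:
        raise ValueError("cannot classify an unconverged fit")
    if fit.mode == "linear":
        eff = linear_effect(fit)
        if eff["lo"] > 0:
            return "positive"
        if eff["hi"] < 0:
            return "negative"
        return "none"
    lo, hi = fit.x_inner
    grid = np.linspace(lo, hi, 201)
    curve = association_curve(fit, grid=grid)
    sig = (curve.lo > 0) | (curve.hi < 0)
    if not sig.any():
        return "none"
    deriv = np.gradient(curve.fit, grid)
    if derivative_tol is None:
        scale = (np.ptp(curve.fit) + 1e-12) / (hi - lo)
        derivative_tol = 1e-3 * scale
    inc = bool(np.any(deriv[sig] > derivative_tol))
    dec = bool(np.any(deriv[sig] < -derivative_tol))
    if inc and dec:
        return "positive_negative"
    if inc:
        return "positive"
    if dec:
        return "negative"
    return "none"


def _run_tasks(data: pd.DataFrame, config: BatteryConfig, seed: int | None) -> BatteryResult:
    tasks = config.enumerate_tasks()
    if config.declared_count != len(tasks):
        raise ValueError(
            f"config declares {config.declared_count} models but enumerates {len(tasks)}"
        )
    fits, statuses, labels, extracted = {}, {}, {}, {}
    for task in tasks:
        key = (task.outcome, task.predictor, task.region)
        sub = data if task.region is None else data[data["region_group"] == task.region]
        if task.outcome in sub.columns:
            sub = sub.dropna(subset=[task.outcome])
        spec = ModelSpec(
            outcome=task.outcome,
            predictor=task.predictor,
            mode=task.mode,
            covariates_numeric=BASE_NUMERIC + list(task.covariates_numeric),
            covariates_categorical=(
                [c for c in BASE_CATEGORICAL if c != "region_group"]
                if task.region is not None
                else list(BASE_CATEGORICAL)
            ),
            linearity_tolerance=config.linearity_tolerance,
        )
        try:
            fit = fit_hierarchical(sub, spec)
            fits[key] = fit
            statuses[key] = "ok"
            labels[key] = classify_association(fit)
            for cov in task.extract:
                extracted[(task.outcome, cov, task.region)] = linear_effect(fit, cov)
        except Exception as exc:  # failed fits are flagged, not fatal
            log.warning("fit failed for %s: %s", key, exc)
            fits.pop(key, None)
            labels.pop(key, None)
            statuses[key] = "insufficient_data"
    return BatteryResult(
        config=config, fits=fits, statuses=statuses, labels=labels,
        extracted=extracted, seed=seed,
    )


def run_main_battery(
    data: pd.DataFrame, config: BatteryConfig | None = None, seed: int | None = None
) -> BatteryResult:
    """Fit the main battery: two-stage (penalized screen → edf rule → final
    linear or natural-spline) model per predictor × outcome series."""
    config = config or BatteryConfig(battery="main")
    if config.battery != "main":
        raise ValueError("config is not a main-battery config")
    missing = [o for o in config.outcomes if o not in data.columns]
    if missing:
        raise KeyError(f"data lacks outcome series {missing}")
    return _run_tasks(data, config, seed)


def run_sensitivity(
    data: pd.DataFrame, config: BatteryConfig | None = None, seed: int | None = None
) -> BatteryResult:
    """Race/ethnicity models refit with the four SES covariates added;
    nonlinear terms kept as penalized splines."""
    config = config or BatteryConfig(battery="sensitivity", series="full")
    if config.battery != "sensitivity":
        raise ValueError("config is not a sensitivity-battery config")
    return _run_tasks(data, config, seed)


def run_regional(
    data: pd.DataFrame, config: BatteryConfig | None = None, seed: int | None = None
) -> BatteryResult:
    """Per-region models (median income; %Black with %White extracted) for
    industry SO2 and transportation NOx, penalized splines throughout."""
    config = config or BatteryConfig(battery="regional")
    if config.battery != "regional":
        raise ValueError("config is not a regional-battery config")
    if "region_group" not in data.columns:
        raise KeyError("data lacks a region_group column")
    return _run_tasks(data, config, seed)


def _key_str(key: tuple) -> str:
    out, pred, region = key
    return f"{out}::{pred}" + (f"::{region}" if region else "")


def export_report(result: BatteryResult, outdir) -> dict:
    """Write battery outputs: linear-effect table, per-curve CSVs, label grid,
    serialized fits, and a manifest carrying the config hash and seed."""
    if result.n_fitted == 0 and not result.statuses:
        raise ValueError("nothing to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "curves").mkdir(exist_ok=True)

    lin_rows = []
    for key, fit in result.fits.items():
        if fit.mode == "linear":
            eff = linear_effect(fit)
            lin_rows.append(
                {"outcome": key[0], "predictor": key[1], "region": key[2],
                 "per_10pp": eff["estimate"], "lo": eff["lo"], "hi": eff["hi"]}
            )
        curve = association_curve(fit)
        pd.DataFrame(
            {"x": curve.grid, "fit": curve.fit, "lo": curve.lo, "hi": curve.hi}
        ).to_csv(outdir / "curves" / (_key_str(key).replace("::", "__") + ".csv"),
                 index=False)
    for (out, cov, region), eff in result.extracted.items():
        lin_rows.append(
            {"outcome": out, "predictor": cov, "region": region,
             "per_10pp": eff["estimate"], "lo": eff["lo"], "hi": eff["hi"]}
        )
    pd.DataFrame(
        lin_rows, columns=["outcome", "predictor", "region", "per_10pp", "lo", "hi"]
    ).to_csv(outdir / "linear_effects.csv", index=False)

    grid_rows = [
        {"outcome": k[0], "predictor": k[1], "region": k[2],
         "status": result.statuses[k], "label": result.labels.get(k)}
        for k in sorted(result.statuses, key=_key_str)
    ]
    pd.DataFrame(grid_rows).to_csv(outdir / "label_grid.csv", index=False)

    fits_payload = {_key_str(k): f.to_dict() for k, f in sorted(
        result.fits.items(), key=lambda kv: _key_str(kv[0])
    )}
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits_payload, fh, indent=1, sort_keys=True)

    manifest = {
        "config_hash": result.config.config_hash(),
        "battery": result.config.battery,
        "declared_count": result.config.declared_count,
        "n_fitted": result.n_fitted,
        "seed": result.seed,
        "version": __version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_report(outdir) -> dict:
    """Reload a serialized report (manifest + fits) for round-trip checks."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    with open(outdir / "fits.json") as fh:
        fits = json.load(fh)
    return {"manifest": manifest, "fits": fits}


# ---------------------------------------------------------------------------
# synthetic end-to-end helpers


def attach_covariates(demographics: pd.DataFrame, mosaic) -> pd.DataFrame:
    """Add population density, urbanicity and EPA region group to a table.

    The synthetic EPA region of a state is its index modulo 10, plus one;
    regions 1–3 then merge into one group as in the covariate definition.
    """
    first = mosaic.for_decade(mosaic.decades[0]).table
    areas = first.set_index("county_id")["area"]
    df = demographics.copy()
    df["pop_density"] = population_density(
        df["population"].to_numpy(), areas.loc[df["county_id"]].to_numpy()
    )
    df["urbanicity"] = classify_urbanicity(df["population"].to_numpy())
    state_index = (
        df["state_id"].str.extract(r"(\d+)", expand=False).astype(int)
    )
    df["region_group"] = [(assign_region_group(i % 10 + 1)) for i in state_index]
    return df


def build_analysis_table(
    config: SyntheticConfig,
    planted_effects: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Table-mode analysis records with one planted outcome column per series.

    ``planted_effects`` maps outcome-series name (e.g. ``chg_industry_SO2``)
    to an effect_spec dict; unspecified series get the config's default
    effect_spec. Returns (analysis table, {series: TruthRecord}).
    """
    mosaic = make_counties(config)
    demo = make_demographics(config, mosaic)
    table = attach_covariates(demo, mosaic)
    planted_effects = planted_effects or {s: config.effect_spec for s in MAIN_SERIES}
    truths = {}
    for series, eff in planted_effects.items():
        out, truth = make_outcomes(config, table, effect_spec=eff, name=series)
        table[series] = out[series]
        truths[series] = truth
    return table, truths


def simulate_study(
    config: SyntheticConfig,
    policy: ExclusionPolicy | None = None,
) -> dict:
    """Full field-mode pipeline on synthetic inputs.

    Generates mosaic + grids + demographics, aggregates each series to
    counties, computes relative decennial changes, applies the exclusion
    policy (default: drop infinite-change counties in industry, trim the top
    5 percentile in energy), and matches decade-t demographics/covariates to
    the t → t+10 change. Returns the intermediate artifacts and a wide
    analysis table with one ``chg_<sector>_<pollutant>`` column per series.
    """
    mosaic = make_counties(config)
    grids = make_grid(config, mosaic)
    demo = make_demographics(config, mosaic)
    covs = attach_covariates(demo, mosaic)

    domain = mosaic.bounds()
    flux_frames = []
    weight_cache = {}
    for g in grids:
        key = g.year  # mosaic decade; grid geometry is shared
        if key not in weight_cache:
            decade_mosaic, _ = filter_by_centroid(mosaic.for_decade(g.year), domain)
            weight_cache[key] = (decade_mosaic, intersect_weights(decade_mosaic, g))
        decade_mosaic, weights = weight_cache[key]
        tab = aggregate_flux(g, weights)
        tab = tab.merge(
            decade_mosaic.table[["county_id", "state_id"]], on="county_id"
        )
        flux_frames.append(tab)
    fluxes = pd.concat(flux_frames, ignore_index=True)

    changes = build_change_table(fluxes)
    if policy is None:
        policy = ExclusionPolicy(
            rules={"industry": "drop_infinite_counties",
                   "energy": "trim_top_percentile"},
            percentile={"energy": 95.0},
        )
    kept, excl_log = apply_exclusions(changes, policy)

    wide = None
    for (sector, pollutant), g in kept.groupby(["sector", "pollutant"]):
        col = f"chg_{sector}_{pollutant}"
        part = g[["county_id", "year", "rel_change", "flag"]].copy()
        part = match_demographics(part, covs)
        part = part.rename(columns={"rel_change": col})
        if wide is None:
            wide = part
        else:
            wide = wide.merge(
                part[["county_id", "year", col]], on=["county_id", "year"], how="outer"
            )
    return {
        "mosaic": mosaic,
        "grids": grids,
        "demographics": demo,
        "covariates": covs,
        "fluxes": fluxes,
        "changes": changes,
        "exclusion_log": excl_log,
        "analysis": wide,
    }
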