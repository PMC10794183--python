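"""Relative decennial emission changes, exclusion rules, temporal matching.

The outcome of the analysis is the relative change in a county's emission flux
from one decennial year t to the next, expressed as a percentage:

    100 · (E_{t+10} − E_t) / E_t

A change from zero to a positive flux is flagged ``infinite``; a county/decade
missing a flux in either endpoint year is flagged ``missing``; the 0 → 0
transition is defined as 0% (and logged), since no change occurred.

Exclusion policies mirror the handling of extreme outcomes in emission-change
analyses: dropping the entire history (in a sector) of any county that ever
produced an infinite change, or trimming records above a pooled upper
percentile of the change distribution within a sector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_OK",
    "FLAG_INFINITE",
    "FLAG_MISSING",
    "ExclusionPolicy",
    "relative_change",
    "build_change_table",
    "apply_exclusions",
    "match_demographics",
]

log = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_INFINITE = "infinite"
FLAG_MISSING = "missing"


def relative_change(e_start: float, e_end: float) -> tuple[float, str]:
    """Relative change in percent from ``e_start`` to ``e_end``.

    Returns ``(value, flag)``. Flags: ``ok`` for a finite change, ``infinite``
    for a 0 → positive transition (value NaN). A 0 → 0 transition returns
    ``(0.0, "ok")`` by convention and is logged. Negative fluxes are rejected.
    """
    if e_start < 0 or e_end < 0:
        raise ValueError(f"fluxes must be nonnegative, got ({e_start}, {e_end})")
    if e_start == 0:
        if e_end == 0:
            log.info("0 -> 0 flux transition treated as 0%% change")
            return 0.0, FLAG_OK
        return float("nan"), FLAG_INFINITE
    return 100.0 * (e_end - e_start) / e_start, FLAG_OK


def build_change_table(county_fluxes: pd.DataFrame) -> pd.DataFrame:
    """One change record per county × sector × pollutant × consecutive-decade pair.

    ``county_fluxes`` needs columns county_id, year, sector, pollutant, flux
    (``state_id`` is carried through when present; a ``missing`` flag column
    marks fluxes to treat as absent). With D decades of fluxes each county
    gets D−1 period records; a county absent (or flagged missing) in either
    endpoint year yields a ``missing``-flag record for that period.
    """
    df = county_fluxes.copy()
    if "missing" in df.columns:
        df.loc[df["missing"].astype(bool), "flux"] = np.nan
    years = sorted(df["year"].unique())
    keys = ["county_id", "sector", "pollutant"]
    if "state_id" in df.columns:
        id_cols = ["county_id", "state_id", "sector", "pollutant"]
    else:
        id_cols = keys
    wide = df.pivot(index=id_cols, columns="year", values="flux").reindex(
        columns=years
    )
    records = []
    for idx, row in wide.iterrows():
        meta = dict(zip(wide.index.names, idx if isinstance(idx, tuple) else (idx,)))
        for t0, t1 in zip(years[:-1], years[1:]):
            e0 = row.get(t0, np.nan)
            e1 = row.get(t1, np.nan)
            if pd.isna(e0) or pd.isna(e1):
                value, flg = float("nan"), FLAG_MISSING
            else:
                value, flg = relative_change(float(e0), float(e1))
            records.append({**meta, "year": t0, "rel_change": value, "flag": flg})
    return pd.DataFrame(records)


@dataclass
class ExclusionPolicy:
    """Per-sector exclusion rules.

    ``rules`` maps sector name → one of ``"none"``,
    ``"drop_infinite_counties"`` or ``"trim_top_percentile"``;
    ``percentile`` maps sector name → p for the trimming rule (default 95).
    ``pool_pollutants`` controls whether the trimming percentile is computed
    jointly across a sector's pollutants or per pollutant (default).
    """

    rules: dict = field(default_factory=dict)
    percentile: dict = field(default_factory=dict)
    pool_pollutants: bool = False

    _KNOWN = ("none", "drop_infinite_counties", "trim_top_percentile")

    def rule_for(self, sector: str) -> str:
        rule = self.rules.get(sector, "none")
        if rule not in self._KNOWN:
            raise ValueError(f"unknown exclusion policy {rule!r} for sector {sector!r}")
        return rule

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExclusionPolicy":
        rules, pct = {}, {}
        for sector, entry in cfg.get("sectors", {}).items():
            if isinstance(entry, str):
                rules[sector] = entry
            else:
                rules[sector] = entry["rule"]
                if "percentile" in entry:
                    pct[sector] = float(entry["percentile"])
        return cls(rules=rules, percentile=pct,
                   pool_pollutants=bool(cfg.get("pool_pollutants", False)))


def apply_exclusions(
    records: pd.DataFrame, policy: ExclusionPolicy
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-sector exclusion rules to a change table.

    ``drop_infinite_counties`` removes *all* period records (in that sector)
    of any county with at least one infinite-flag record there.
    ``trim_top_percentile`` removes records with relative change strictly
    above the p-th percentile (linear-interpolation convention), pooled
    across periods within the sector; ties at the threshold are kept.

    Returns ``(filtered, exclusion_log)`` where the log has one row per
    sector rule with the count removed; counts reconcile exactly with the
    before/after sizes.
    """
    keep = np.ones(len(records), dtype=bool)
    log_rows = []
    for sector in sorted(records["sector"].unique()):
        rule = policy.rule_for(sector)
        in_sector = (records["sector"] == sector).to_numpy()
        removed = 0
        if rule == "drop_infinite_counties":
            bad = records.loc[
                in_sector & (records["flag"] == FLAG_INFINITE).to_numpy(), "county_id"
            ].unique()
            mask = in_sector & records["county_id"].isin(bad).to_numpy()
            removed = int(mask.sum())
            keep &= ~mask
            log_rows.append(
                {"sector": sector, "rule": rule, "n_counties": len(bad),
                 "n_removed": removed}
            )
        elif rule == "trim_top_percentile":
            p = policy.percentile.get(sector, 95.0)
            groups = (
                [records.loc[in_sector]]
                if policy.pool_pollutants
                else [g for _, g in records.loc[in_sector].groupby("pollutant")]
            )
            for g in groups:
                vals = g.loc[g["flag"] == FLAG_OK, "rel_change"]
                if vals.empty:
                    continue
                thresh = np.percentile(vals.to_numpy(), p)  # linear interpolation
                over = g.index[(g["flag"] == FLAG_OK) & (g["rel_change"] > thresh)]
                removed += len(over)
                keep[records.index.get_indexer(over)] = False
            log_rows.append(
                {"sector": sector, "rule": rule, "n_counties": np.nan,
                 "n_removed": removed}
            )
        else:
            log_rows.append(
                {"sector": sector, "rule": "none", "n_counties": 0, "n_removed": 0}
            )
    filtered = records.loc[keep].reset_index(drop=True)
    excl_log = pd.DataFrame(log_rows)
    assert len(filtered) + excl_log["n_removed"].sum() == len(records)
    return filtered, excl_log


def match_demographics(
    changes: pd.DataFrame,
    demographics: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join decade-t demographics to the t → t+10 emission change.

    Inner join on ``(county_id, year)``; change records that are not
    ``ok``-flagged, or that lack a demographic row, are dropped (counts
    logged). Duplicate demographic rows for a (county, year) are an error.
    ``covariates`` (same key) is merged the same way when given.
    """
    for name, tab in (("demographics", demographics), ("covariates", covariates)):
        if tab is None:
            continue
        if tab.duplicated(subset=["county_id", "year"]).any():
            raise ValueError(f"duplicate (county_id, year) rows in {name}")
    ok = changes[changes["flag"] == FLAG_OK].drop(columns=["flag"])
    n_dropped_flag = len(changes) - len(ok)
    merged = ok.merge(demographics, on=["county_id", "year"], how="inner",
                      suffixes=("", "_demo"))
    if covariates is not None:
        merged = merged.merge(covariates, on=["county_id", "year"], how="inner",
                              suffixes=("", "_cov"))
    log.info(
        "match_demographics: %d change records in, %d dropped by flag, "
        "%d lacked demographics, %d records out",
        len(changes), n_dropped_flag, len(ok) - len(merged) if covariates is None
        else len(ok) - len(merged), len(merged),
    )
    return merged.reset_index(drop=True)
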