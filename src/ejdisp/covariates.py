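"""Model covariates and descriptive summaries.

Inflation adjustment to 2010 dollars via a CPI research series, the
population-threshold urbanicity classification, EPA-region grouping (regions
1–3 merged, giving 8 groups), population density, and decade summary tables
(mean + IQR for continuous variables, counts + percent for categoricals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CPISeries",
    "adjust_inflation",
    "classify_urbanicity",
    "assign_region_group",
    "population_density",
    "summarize_decade",
    "URBANICITY_LEVELS",
    "REGION_GROUPS",
]

URBANICITY_LEVELS = ("metropolitan", "micropolitan", "non-urban")
REGION_GROUPS = ("R1-3", "R4", "R5", "R6", "R7", "R8", "R9", "R10")


@dataclass(frozen=True)
class CPISeries:
    """Year → CPI index map used to express dollars in 2010 terms."""

    values: dict

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("CPI index values must be positive")
        if 2010 not in self.values:
            raise ValueError("CPI series must contain the 2010 reference year")

    def __getitem__(self, year: int) -> float:
        try:
            return float(self.values[year])
        except KeyError:
            raise KeyError(f"year {year} not in CPI series") from None

    @classmethod
    def from_csv(cls, path) -> "CPISeries":
        df = pd.read_csv(path)
        year_col, idx_col = df.columns[:2]
        return cls({int(y): float(v) for y, v in zip(df[year_col], df[idx_col])})


def adjust_inflation(amount: float, year: int, cpi: CPISeries) -> float:
    """Convert ``amount`` dollars of ``year`` to 2010 dollars.

    2010 dollars = amount × CPI(2010) / CPI(year). Linear in the amount and
    multiplicative in the index ratio; works elementwise on arrays.
    """
    return amount * (cpi[2010] / cpi[year])


def classify_urbanicity(population) -> str | np.ndarray:
    """Three-level urbanicity from county population.

    metropolitan: population ≥ 50,000; micropolitan: 10,000 ≤ population
    < 50,000; non-urban: population < 10,000. Boundaries go to the upper
    class, i.e. exactly 50,000 is metropolitan and exactly 10,000 is
    micropolitan. Vectorized over array input.
    """
    pop = np.asarray(population)
    if np.any(pop < 0):
        raise ValueError("population must be nonnegative")
    out = np.where(
        pop >= 50_000, "metropolitan", np.where(pop >= 10_000, "micropolitan", "non-urban")
    )
    return out.item() if np.isscalar(population) else out


def assign_region_group(epa_region: int) -> str:
    """Map EPA region 1–10 to the 8-level grouping (1–3 merged)."""
    r = int(epa_region)
    if not 1 <= r <= 10:
        raise ValueError(f"EPA region must be in 1..10, got {epa_region}")
    return "R1-3" if r <= 3 else f"R{r}"


def population_density(population, area_km2) -> np.ndarray:
    """People per km², from county population and polygon area."""
    area = np.asarray(area_km2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("county area must be positive")
    return np.asarray(population, dtype=float) / area


def summarize_decade(
    table: pd.DataFrame,
    variables: list[str],
    categorical: list[str] | None = None,
    by: str = "year",
) -> pd.DataFrame:
    """Mean + IQR per continuous variable per decade; counts + percent for
    categoricals.

    Quantiles use the linear-interpolation convention. Returns a long frame
    with columns ``year``, ``variable``, ``level`` (categoricals only),
    ``mean``, ``q1``, ``q3``, ``count``, ``percent``.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    categorical = categorical or []
    unknown = [v for v in list(variables) + categorical if v not in table.columns]
    if unknown:
        raise KeyError(f"unknown variable(s): {unknown}")
    rows = []
    for year, g in table.groupby(by, sort=True):
        for v in variables:
            x = g[v].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "year": year,
                    "variable": v,
                    "level": None,
                    "mean": float(np.mean(x)),
                    "q1": float(np.percentile(x, 25)),
                    "q3": float(np.percentile(x, 75)),
                    "count": len(x),
                    "percent": np.nan,
                }
            )
        for v in categorical:
            counts = g[v].value_counts()
            total = int(counts.sum())
            for level, n in counts.items():
                rows.append(
                    {
                        "year": year,
                        "variable": v,
                        "level": level,
                        "mean": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                        "count": int(n),
                        "percent": 100.0 * n / total,
                    }
                )
    return pd.DataFrame(rows)
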