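"""County polygon mosaics with state membership and decade validity.

A :class:`CountyMosaic` is a table of county polygons valid for one or more
decades. Geometry is planar (km). Counties carry a ``county_id`` unique within
each decade, a ``state_id``, and precomputed area (km²) and centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

__all__ = ["CountyMosaic", "read_geojson", "write_geojson"]


@dataclass
class CountyMosaic:
    """County polygons for one or several decades.

    The backing ``table`` has one row per county × decade with columns
    ``county_id``, ``state_id``, ``decade``, ``geometry`` (shapely Polygon or
    MultiPolygon), ``area`` (km²), ``centroid_x``, ``centroid_y``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"county_id", "state_id", "decade", "geometry"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"mosaic table missing columns: {sorted(missing)}")
        tab = self.table.copy()
        if "area" not in tab.columns:
            tab["area"] = [g.area for g in tab["geometry"]]
        if "centroid_x" not in tab.columns:
            cents = [g.centroid for g in tab["geometry"]]
            tab["centroid_x"] = [c.x for c in cents]
            tab["centroid_y"] = [c.y for c in cents]
        if (tab["area"] <= 0).any():
            bad = tab.loc[tab["area"] <= 0, "county_id"].tolist()
            raise ValueError(f"counties with nonpositive area: {bad}")
        dup = tab.duplicated(subset=["county_id", "decade"])
        if dup.any():
            raise ValueError(
                "duplicate county_id within a decade: "
                f"{tab.loc[dup, ['county_id', 'decade']].to_dict('records')}"
            )
        self.table = tab.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def decades(self) -> list[int]:
        return sorted(self.table["decade"].unique().tolist())

    def for_decade(self, decade: int) -> "CountyMosaic":
        sub = self.table[self.table["decade"] == decade]
        if sub.empty:
            raise KeyError(f"no counties for decade {decade}")
        return CountyMosaic(sub.reset_index(drop=True))

    def total_area(self) -> float:
        return float(self.table["area"].sum())

    def bounds(self) -> tuple[float, float, float, float]:
        b = shapely.bounds(np.asarray(self.table["geometry"], dtype=object))
        b = np.atleast_2d(b)
        return (
            float(b[:, 0].min()),
            float(b[:, 1].min()),
            float(b[:, 2].max()),
            float(b[:, 3].max()),
        )


def write_geojson(mosaic: CountyMosaic, path) -> None:
    """Write a mosaic as a GeoJSON FeatureCollection.

    Properties per feature: county_id, state_id, decade.
    """
    features = []
    for _, row in mosaic.table.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(row["geometry"]),
                "properties": {
                    "county_id": row["county_id"],
                    "state_id": row["state_id"],
                    "decade": int(row["decade"]),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> CountyMosaic:
    """Read a FeatureCollection written by :func:`write_geojson` (or compatible)."""
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
        props = feat["properties"]
        rows.append(
            {
                "county_id": props["county_id"],
                "state_id": props["state_id"],
                "decade": int(props["decade"]),
                "geometry": geom,
            }
        )
    return CountyMosaic(pd.DataFrame(rows))
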