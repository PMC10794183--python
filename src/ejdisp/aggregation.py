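"""Area-weighted aggregation of gridded fluxes to county polygons.

Flux (kg/km²/day) is an intensive quantity, so a county value is the
intersection-area-weighted mean of the cell values overlapping the county.
The weights are exact polygon ∩ cell areas computed with shapely; a sparse
:class:`WeightMatrix` caches them per (mosaic, grid geometry) because county
boundaries change by decade while the grid mesh usually does not.

Counties are included or excluded by the position of their centroid relative
to the analysis domain (the rule used to trim coastal artefacts in gridded
inventories), never by grid coverage: a retained county only partially covered
by the grid is averaged over its covered portion, since the weighted mean
renormalizes automatically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree, box
from shapely.validation import explain_validity

from .counties import CountyMosaic
from .grids import GridField

__all__ = [
    "WeightMatrix",
    "filter_by_centroid",
    "intersect_weights",
    "aggregate_flux",
]

log = logging.getLogger(__name__)

# intersections below this area (km²) are numerical slivers and are dropped
SLIVER_AREA = 1e-12


def filter_by_centroid(
    mosaic: CountyMosaic, domain: tuple[float, float, float, float]
) -> tuple[CountyMosaic, list]:
    """Keep counties whose centroid lies inside ``domain``.

    Parameters
    ----------
    mosaic
        Counties to filter.
    domain
        ``(xmin, ymin, xmax, ymax)`` rectangle. Must be non-degenerate.

    Returns
    -------
    (kept, dropped_ids)
        The filtered mosaic and the list of dropped ``county_id`` values
        (for logging/audit). Boundary centroids count as inside.
    """
    xmin, ymin, xmax, ymax = domain
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate domain rectangle {domain}")
    tab = mosaic.table
    if tab.empty:
        warnings.warn("filter_by_centroid called on an empty mosaic", stacklevel=2)
        return mosaic, []
    inside = (
        (tab["centroid_x"] >= xmin)
        & (tab["centroid_x"] <= xmax)
        & (tab["centroid_y"] >= ymin)
        & (tab["centroid_y"] <= ymax)
    )
    dropped = tab.loc[~inside, "county_id"].tolist()
    if dropped:
        log.info("centroid filter dropped %d counties: %s", len(dropped), dropped)
    return CountyMosaic(tab[inside].reset_index(drop=True)), dropped


@dataclass
class WeightMatrix:
    """Sparse (county, cell) → intersection area map for one grid geometry.

    ``county_ids`` indexes rows; cells are flattened row-major over the grid
    shape ``(ny, nx)``. Only nonzero-area intersections are stored.
    """

    county_ids: list
    county_index: np.ndarray  # parallel arrays of the sparse entries
    cell_index: np.ndarray
    area: np.ndarray  # km²
    shape: tuple[int, int]  # (ny, nx) of the grid the weights were built on

    def weight_sums(self) -> np.ndarray:
        """Total intersected area per county, km² (order of county_ids)."""
        out = np.zeros(len(self.county_ids))
        np.add.at(out, self.county_index, self.area)
        return out


def intersect_weights(mosaic: CountyMosaic, grid: GridField) -> WeightMatrix:
    """Exact polygon ∩ cell intersection areas for every county in ``mosaic``.

    Warns (but proceeds) when the grid does not fully cover the mosaic: the
    uncovered part of a county simply receives no weight. Invalid polygons
    raise with the offending county named.
    """
    gxmin, gymin, gxmax, gymax = grid.bounds()
    mxmin, mymin, mxmax, mymax = mosaic.bounds()
    if mxmin < gxmin - 1e-9 or mymin < gymin - 1e-9 or mxmax > gxmax + 1e-9 or mymax > gymax + 1e-9:
        warnings.warn(
            "grid does not fully cover the county mosaic; counties are "
            "aggregated over the covered portion only",
            stacklevel=2,
        )
    cells = [
        box(grid.x_edges[j], grid.y_edges[i], grid.x_edges[j + 1], grid.y_edges[i + 1])
        for i in range(grid.ny)
        for j in range(grid.nx)
    ]
    tree = STRtree(cells)
    county_idx: list[int] = []
    cell_idx: list[int] = []
    areas: list[float] = []
    ids = mosaic.table["county_id"].tolist()
    for ci, geom in enumerate(mosaic.table["geometry"]):
        if not geom.is_valid:
            raise ValueError(
                f"invalid polygon for county {ids[ci]!r}: {explain_validity(geom)}"
            )
        for gi in tree.query(geom):
            a = cells[gi].intersection(geom).area
            if a > SLIVER_AREA:
                county_idx.append(ci)
                cell_idx.append(int(gi))
                areas.append(a)
    return WeightMatrix(
        county_ids=ids,
        county_index=np.asarray(county_idx, dtype=np.intp),
        cell_index=np.asarray(cell_idx, dtype=np.intp),
        area=np.asarray(areas, dtype=float),
        shape=(grid.ny, grid.nx),
    )


def aggregate_flux(grid: GridField, weights: WeightMatrix) -> pd.DataFrame:
    """Area-weighted mean flux per county: F_c = Σ_g w_cg F_g / Σ_g w_cg.

    Returns a frame with columns ``county_id``, ``year``, ``sector``,
    ``pollutant``, ``flux``; counties with zero total weight get NaN flux and
    ``missing=True``.
    """
    if (grid.ny, grid.nx) != weights.shape:
        raise ValueError(
            f"grid shape {(grid.ny, grid.nx)} does not match weights {weights.shape}"
        )
    flat = grid.flux.ravel()
    num = np.zeros(len(weights.county_ids))
    np.add.at(num, weights.county_index, weights.area * flat[weights.cell_index])
    den = weights.weight_sums()
    with np.errstate(invalid="ignore", divide="ignore"):
        flux = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return pd.DataFrame(
        {
            "county_id": weights.county_ids,
            "year": grid.year,
            "sector": grid.sector,
            "pollutant": grid.pollutant,
            "flux": flux,
            "missing": den <= 0,
        }
    )
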