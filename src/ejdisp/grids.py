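"""Gridded emission-flux fields.

A :class:`GridField` holds one raster of emission fluxes (kg/km²/day) for a
single year, source sector and pollutant, on a rectangular cell mesh defined
by its cell-edge coordinates. Coordinates are planar (km); callers working in
longitude/latitude must pre-project to an equal-area system before building a
field, because all downstream area weighting treats coordinates as Cartesian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GridField", "read_grid_csv", "write_grid_csv"]


@dataclass
class GridField:
    """One year × sector × pollutant raster of emission fluxes.

    Parameters
    ----------
    x_edges, y_edges
        Strictly increasing cell-edge coordinates in planar km. A mesh with
        ``nx`` columns has ``nx + 1`` x-edges.
    flux
        Array of shape ``(ny, nx)`` of nonnegative, finite fluxes in
        kg/km²/day. Row ``i`` spans ``y_edges[i]..y_edges[i+1]``.
    pollutant, sector
        Labels, e.g. ``"SO2"`` and ``"industry"``.
    year
        Calendar year of the field.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    flux: np.ndarray
    pollutant: str
    sector: str
    year: int

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.x_edges.ndim != 1 or self.y_edges.ndim != 1:
            raise ValueError("cell edges must be one-dimensional")
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ValueError("cell edges must be strictly increasing")
        expected = (self.y_edges.size - 1, self.x_edges.size - 1)
        if self.flux.shape != expected:
            raise ValueError(
                f"flux shape {self.flux.shape} does not match edges {expected}"
            )
        if not np.all(np.isfinite(self.flux)):
            raise ValueError("flux values must be finite")
        if np.any(self.flux < 0):
            raise ValueError("flux values must be nonnegative")

    @property
    def nx(self) -> int:
        return self.x_edges.size - 1

    @property
    def ny(self) -> int:
        return self.y_edges.size - 1

    @property
    def cell_areas(self) -> np.ndarray:
        """Cell areas in km², shape (ny, nx)."""
        dx = np.diff(self.x_edges)
        dy = np.diff(self.y_edges)
        return np.outer(dy, dx)

    def total_mass(self) -> float:
        """Domain-integrated emission mass rate, kg/day."""
        return float(np.sum(self.flux * self.cell_areas))

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded domain."""
        return (
            float(self.x_edges[0]),
            float(self.y_edges[0]),
            float(self.x_edges[-1]),
            float(self.y_edges[-1]),
        )


def write_grid_csv(fields: list[GridField], path) -> None:
    """Write fields to a single long-format CSV.

    Columns: year, sector, pollutant, row, col, x0, x1, y0, y1, flux.
    The per-cell edge coordinates make the file self-describing so a grid can
    be reconstructed without a sidecar geometry file.
    """
    frames = []
    for f in fields:
        ny, nx = f.flux.shape
        rows, cols = np.mgrid[0:ny, 0:nx]
        frames.append(
            pd.DataFrame(
                {
                    "year": f.year,
                    "sector": f.sector,
                    "pollutant": f.pollutant,
                    "row": rows.ravel(),
                    "col": cols.ravel(),
                    "x0": f.x_edges[cols.ravel()],
                    "x1": f.x_edges[cols.ravel() + 1],
                    "y0": f.y_edges[rows.ravel()],
                    "y1": f.y_edges[rows.ravel() + 1],
                    "flux": f.flux.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_grid_csv(path) -> list[GridField]:
    """Reconstruct :class:`GridField` objects from :func:`write_grid_csv` output."""
    df = pd.read_csv(path)
    fields = []
    for (year, sector, pollutant), g in df.groupby(
        ["year", "sector", "pollutant"], sort=True
    ):
        ny = int(g["row"].max()) + 1
        nx = int(g["col"].max()) + 1
        flux = np.full((ny, nx), np.nan)
        flux[g["row"].to_numpy(), g["col"].to_numpy()] = g["flux"].to_numpy()
        x_edges = np.empty(nx + 1)
        y_edges = np.empty(ny + 1)
        x_edges[g["col"].to_numpy()] = g["x0"].to_numpy()
        x_edges[nx] = g.loc[g["col"] == nx - 1, "x1"].iloc[0]
        y_edges[g["row"].to_numpy()] = g["y0"].to_numpy()
        y_edges[ny] = g.loc[g["row"] == ny - 1, "y1"].iloc[0]
        fields.append(
            GridField(
                x_edges=x_edges,
                y_edges=y_edges,
                flux=flux,
                pollutant=str(pollutant),
                sector=str(sector),
                year=int(year),
            )
        )
    return fields
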