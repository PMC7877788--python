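"""Assign survey points to 8-km grid cells and compute raw cell aggregates.

The cell-level quantities feeding the smoothing model, for a variable with
per-point values ``Y_i`` (zero where the point lacks the taxon) in cell
``s``:

* ``N(s)`` — number of survey points in the cell,
* ``n_p(s)`` — number of those points occupied by taxon p,
* ``Ybar_p(s) = (1/n_p) * sum_i Y_i`` — mean over the occupied points,
* raw cell mean ``= (1/N) * sum_i Y_i`` over *all* points (zeros included).

By construction the decomposition identity ``(n_p/N) * Ybar_p == cell mean``
holds to machine precision; averaging point-level density-times-size
products (rather than multiplying cell-mean density by cell-mean tree size)
avoids the classical overestimation caused by their negative correlation.

Cell assignment uses half-open intervals ``[x0 + i*h, x0 + (i+1)*h)``; empty
cells are retained (with ``N = 0``) as prediction targets for the smoothing
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GridSpec:
    """Regular grid in a projected equal-area coordinate system (meters).

    The survey products use 8-km cells; origin and projection are explicit
    configuration so a published grid definition can be reproduced exactly.
    """

    x0: float
    y0: float
    nx: int
    ny: int
    cell_size: float = 8000.0
    crs: str = "projected-equal-area"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid extent must be at least 1x1")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_index(self, x, y) -> np.ndarray:
        """Flat cell id ``iy*nx + ix`` per point; -1 for out-of-extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.x0) / self.cell_size).astype(int)
        iy = np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        out = np.where(inside, iy * self.nx + ix, -1)
        return out

    def centers(self) -> pd.DataFrame:
        """Cell centers for all cells, ordered by flat cell id."""
        ix = np.arange(self.nx)
        iy = np.arange(self.ny)
        xx, yy = np.meshgrid(ix, iy)
        return pd.DataFrame({
            "cell_id": (yy * self.nx + xx).ravel(),
            "x": self.x0 + (xx.ravel() + 0.5) * self.cell_size,
            "y": self.y0 + (yy.ravel() + 0.5) * self.cell_size,
        })


def assign_cells(
    df: pd.DataFrame, grid: GridSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach a ``cell_id`` column; drop and log out-of-extent points."""
    cell = grid.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
    inside = cell >= 0
    out = df.loc[inside].copy()
    out["cell_id"] = cell[inside]
    dropped = df.loc[~inside, ["point_id", "x", "y"]].copy() if "point_id" in df else df.loc[~inside].copy()
    return out, dropped


def aggregate_cells(
    points: pd.DataFrame,
    grid: GridSpec,
    value_cols: tuple[str, ...] = ("density", "basal_area", "biomass"),
    occupied_col: str = "occupied",
) -> pd.DataFrame:
    """Raw cell aggregates for total (all-taxa) variables.

    ``points`` must carry ``cell_id``, the value columns (zeros for treeless
    points), and a boolean occupancy indicator.  Rows with a NaN in any value
    column (upstream exclusions) are dropped before aggregation.  Returns one
    row per grid cell (empty cells included, ``N = 0`` and NaN aggregates)
    with, per variable ``v``: ``mean_v``, ``n_occ``, ``ybar_v``; plus ``N``
    and ``zero_proportion``.
    """
    ok = points[list(value_cols)].notna().all(axis=1)
    pts = points.loc[ok]
    g = pts.groupby("cell_id")
    out = pd.DataFrame({"N": g.size()})
    out["n_occ"] = g[occupied_col].sum().astype(int)
    out["zero_proportion"] = 1.0 - out["n_occ"] / out["N"]
    for v in value_cols:
        sums = pts.groupby("cell_id")[v].sum()
        out[f"mean_{v}"] = sums / out["N"]
        out[f"ybar_{v}"] = np.where(out["n_occ"] > 0, sums / out["n_occ"], np.nan)
    full = grid.centers().set_index("cell_id")
    out = full.join(out, how="left")
    out["N"] = out["N"].fillna(0).astype(int)
    out["n_occ"] = out["n_occ"].fillna(0).astype(int)
    return out.reset_index()


def aggregate_taxon(
    totals: pd.DataFrame,
    per_taxon: pd.DataFrame,
    grid: GridSpec,
    taxon: str,
    value_col: str = "biomass",
) -> pd.DataFrame:
    """Cell table ``(cell_id, x, y, N, n_p, ybar, raw_mean)`` for one taxon.

    ``totals`` provides the full point set (hence ``N``); ``per_taxon`` the
    point-level values for points occupied by the taxon.  Points excluded
    upstream (NaN totals) are removed from both numerator and denominator.
    """
    ok = totals[value_col].notna()
    pts = totals.loc[ok, ["point_id", "cell_id"]]
    N = pts.groupby("cell_id").size()
    tax = per_taxon[per_taxon["taxon"] == taxon].merge(pts, on="point_id", how="inner")
    n_p = tax.groupby("cell_id").size()
    sums = tax.groupby("cell_id")[value_col].sum()
    out = grid.centers().set_index("cell_id")
    out["N"] = N.reindex(out.index).fillna(0).astype(int)
    out["n_p"] = n_p.reindex(out.index).fillna(0).astype(int)
    s = sums.reindex(out.index).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ybar"] = np.where(out["n_p"] > 0, s / out["n_p"], np.nan)
        out["raw_mean"] = np.where(out["N"] > 0, s / out["N"], np.nan)
    return out.reset_index()


def occupancy_potential_table(
    cells: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Reshape an :func:`aggregate_cells` output into the smoothing-model
    input schema ``(cell_id, x, y, N, n_p, ybar, raw_mean)`` for one total
    variable."""
    return pd.DataFrame({
        "cell_id": cells["cell_id"],
        "x": cells["x"],
        "y": cells["y"],
        "N": cells["N"],
        "n_p": cells["n_occ"],
        "ybar": cells[f"ybar_{variable}"],
        "raw_mean": cells[f"mean_{variable}"],
    })


def write_raw_product(cells: pd.DataFrame, path: str | Path) -> None:
    """Write the raw gridded product (one row per cell) as CSV."""
    cells.to_csv(path, index=False)
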