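"""Synthetic survey data with the statistical structure the pipeline assumes.

Two levels of generation, each with its ground truth stored alongside:

* **tree level** — a homogeneous (or thinned inhomogeneous) Poisson forest
  with i.i.d. diameter and taxon marks, sampled by the PLS corner protocol:
  corners on a half-mile (805 m) lattice, and at each corner the nearest
  tree in each of two opposite semicircles (or four quadrants) becomes a
  witness tree.  This is exactly the sampling model under which the
  sector-based Morisita estimator is unbiased, so pooled density estimates
  over many corners are a simulation oracle for the estimator.

* **cell level** — gridded occupancy and log-potential surfaces with the
  model's own observation noise: n_p ~ Binomial(N, theta*(s)) and, where
  occupied, log Ybar ~ Normal(m*(s), sigma^2 / n_p).  Feeding these data to
  the smoothing stage is a parameter-recovery and calibration experiment
  with closed-form truth.

Default surfaces are sums of Gaussian bumps mapped through a logistic
(occupancy) or affine (log-potential) link — smooth, nontrivial, and exactly
known.  All generators are reproducible by seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .gridding import GridSpec

CORNER_SPACING_M = 805.0  # half-mile survey lattice


# ---------------------------------------------------------------------------
# tree-level simulation
# ---------------------------------------------------------------------------

@dataclass
class ForestSim:
    """A marked Poisson forest.

    ``intensity`` is stems/ha (constant, or a callable (x, y) -> stems/ha for
    an inhomogeneous process realized by thinning against ``max_intensity``).
    Diameters are log-normal in cm, left-truncated at ``dbh_min`` (surveyors
    rarely recorded saplings); taxon marks are i.i.d. from ``taxa``.
    """

    intensity: float | Callable = 200.0
    extent: tuple[float, float, float, float] = (0.0, 10_000.0, 0.0, 10_000.0)
    dbh_meanlog: float = 3.3      # median ~27 cm
    dbh_sdlog: float = 0.45
    dbh_min: float = 2.0          # cm
    taxa: dict[str, float] = field(default_factory=lambda: {
        "Oak": 0.35, "Maple": 0.25, "Pine": 0.2, "Hemlock": 0.2})
    max_intensity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.taxa.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"taxon mixture must sum to 1, got {total}")

    @property
    def area_ha(self) -> float:
        x0, x1, y0, y1 = self.extent
        return (x1 - x0) * (y1 - y0) / 1e4


def simulate_forest(sim: ForestSim) -> pd.DataFrame:
    """Realize the forest: DataFrame (x, y, dbh, taxon), dbh in cm."""
    rng = np.random.default_rng(sim.seed)
    x0, x1, y0, y1 = sim.extent
    lam_max = sim.intensity if not callable(sim.intensity) else sim.max_intensity
    if lam_max is None:
        raise ValueError("callable intensity requires max_intensity")
    if lam_max < 0:
        raise ValueError("intensity must be non-negative")
    n = rng.poisson(lam_max * sim.area_ha)
    x = rng.uniform(x0, x1, n)
    y = rng.uniform(y0, y1, n)
    if callable(sim.intensity):
        keep = rng.uniform(0, lam_max, n) < np.asarray(sim.intensity(x, y), dtype=float)
        x, y = x[keep], y[keep]
        n = x.size
    dbh = rng.lognormal(sim.dbh_meanlog, sim.dbh_sdlog, n)
    # resample the left tail instead of clipping, keeping the density shape
    for _ in range(100):
        small = dbh < sim.dbh_min
        if not small.any():
            break
        dbh[small] = rng.lognormal(sim.dbh_meanlog, sim.dbh_sdlog, int(small.sum()))
    names = list(sim.taxa)
    taxon = rng.choice(names, size=n, p=[sim.taxa[t] for t in names])
    return pd.DataFrame({"x": x, "y": y, "dbh": dbh, "taxon": taxon})


def corner_lattice(
    extent: tuple[float, float, float, float],
    spacing: float = CORNER_SPACING_M,
    margin: float = 50.0,
) -> np.ndarray:
    """Survey-corner coordinates on a regular lattice, inset by ``margin``
    to avoid edge truncation of nearest-tree distances."""
    x0, x1, y0, y1 = extent
    xs = np.arange(x0 + margin, x1 - margin, spacing)
    ys = np.arange(y0 + margin, y1 - margin, spacing)
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


def sample_corners(
    trees: pd.DataFrame,
    extent: tuple[float, float, float, float],
    spacing: float = CORNER_SPACING_M,
    protocol: str = "two-sector",
    record: str = "face",
    margin: float = 50.0,
    zone: str = "Z1",
    corner_type: str = "section",
    era: str = "E1",
) -> pd.DataFrame:
    """Sample the forest by the PLS corner protocol.

    At each lattice corner the nearest tree in each sector becomes a witness
    tree: ``"two-sector"`` uses the north/south semicircles (matching the
    density estimator's assumption), ``"four-quadrant"`` the four quadrants
    (emulating section-corner instructions).  Recorded distances are to the
    tree face (``record="face"``: center distance minus dbh/2, floored at
    1 cm) as surveyors measured, or ``"center"`` for exact stem-center
    distances.  A sector with no tree anywhere leaves its slot empty.

    Returns a table in the metric point-CSV schema consumed by
    :func:`plsforest.survey_points.parse_points` (round-trip guarantee).
    """
    if protocol not in ("two-sector", "four-quadrant"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if record not in ("face", "center"):
        raise ValueError(f"unknown record convention {record!r}")
    corners = corner_lattice(extent, spacing, margin)
    xy = trees[["x", "y"]].to_numpy()
    rows: list[dict] = []
    tree_ct = cKDTree(xy) if len(xy) else None
    n_sectors = 2 if protocol == "two-sector" else 4
    for pid, (cx, cy) in enumerate(corners):
        row: dict = {"point_id": f"c{pid:05d}", "x": cx, "y": cy,
                     "zone": zone, "corner_type": corner_type, "era": era}
        slot = 1
        if tree_ct is not None:
            picked = _nearest_per_sector(tree_ct, xy, cx, cy, n_sectors)
            for idx in picked:
                if idx is None:
                    continue
                t = trees.iloc[idx]
                d = float(np.hypot(t.x - cx, t.y - cy))
                if record == "face":
                    d = max(d - float(t.dbh) / 200.0, 0.01)
                dx, dy = float(t.x - cx), float(t.y - cy)
                row[f"taxon{slot}"] = t.taxon
                row[f"dbh{slot}"] = float(t.dbh)
                row[f"dist{slot}"] = d
                row[f"bearing{slot}"] = float(np.degrees(np.arctan2(dx, dy)) % 360.0)
                slot += 1
        rows.append(row)
    cols = ["point_id", "x", "y", "zone", "corner_type", "era"]
    for i in range(1, n_sectors + 1):
        cols += [f"taxon{i}", f"dbh{i}", f"dist{i}", f"bearing{i}"]
    return pd.DataFrame(rows).reindex(columns=cols)


def _nearest_per_sector(ct: cKDTree, xy: np.ndarray, cx: float, cy: float,
                        n_sectors: int) -> list[int | None]:
    """Nearest tree index per sector around (cx, cy); None if sector empty."""
    n = xy.shape[0]
    k = min(64, n)
    while True:
        dist, idx = ct.query([cx, cy], k=k)
        dist = np.atleast_1d(dist)
        idx = np.atleast_1d(idx)
        dx = xy[idx, 0] - cx
        dy = xy[idx, 1] - cy
        if n_sectors == 2:
            sector = (dy < 0).astype(int)  # north vs south semicircle
        else:
            sector = (dx < 0).astype(int) * 2 + (dy < 0).astype(int)
        picked: list[int | None] = []
        missing = False
        for s in range(n_sectors):
            hits = np.nonzero(sector == s)[0]
            if hits.size:
                picked.append(int(idx[hits[0]]))
            else:
                missing = True
                picked.append(None)
        if not missing or k >= n:
            return picked
        k = min(4 * k, n)  # a sector was empty in the neighborhood; widen


# ---------------------------------------------------------------------------
# cell-level simulation
# ---------------------------------------------------------------------------

def _bump(u, v, u0, v0, s):
    return np.exp(-((u - u0) ** 2 + (v - v0) ** 2) / (2 * s**2))


def default_theta_surface(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Default truth occupancy: logistic of a sum of Gaussian bumps over the
    unit square; spans roughly 0.1-0.9."""
    eta = (-0.5 + 2.2 * _bump(u, v, 0.30, 0.35, 0.25)
           + 1.8 * _bump(u, v, 0.75, 0.70, 0.20)
           - 1.5 * _bump(u, v, 0.80, 0.15, 0.18))
    return expit(eta)


def default_m_surface(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Default truth log-potential (log Mg/ha): affine in Gaussian bumps,
    exp(m) roughly 16-110 Mg/ha."""
    return (3.6 + 1.1 * _bump(u, v, 0.70, 0.30, 0.30)
            - 0.8 * _bump(u, v, 0.20, 0.80, 0.25))


@dataclass
class SurfaceSim:
    """Cell-level generative model matching the smoothing likelihoods.

    ``theta`` and ``m`` are arrays over cells or callables of unit-square
    coordinates; ``N`` is the points-per-cell (70 by default, the typical
    count for a fully-surveyed 8-km cell); ``sigma2`` the per-point
    log-scale observation variance.
    """

    grid: GridSpec
    theta: np.ndarray | Callable = default_theta_surface
    m: np.ndarray | Callable = default_m_surface
    sigma2: float = 0.25
    N: int | np.ndarray = 70
    seed: int = 0


def simulate_cells(sim: SurfaceSim) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample per-cell data (N, n_p, ybar, raw_mean) plus the truth table.

    n_p ~ Binomial(N, theta*); where n_p > 0,
    ybar = exp(m* + eps), eps ~ Normal(0, sigma^2 / n_p); raw_mean is the
    implied all-points cell mean (n_p/N) * ybar, zero for unoccupied cells.
    """
    rng = np.random.default_rng(sim.seed)
    centers = sim.grid.centers()
    u = (centers["x"].to_numpy() - sim.grid.x0) / (sim.grid.nx * sim.grid.cell_size)
    v = (centers["y"].to_numpy() - sim.grid.y0) / (sim.grid.ny * sim.grid.cell_size)
    theta = sim.theta(u, v) if callable(sim.theta) else np.asarray(sim.theta, dtype=float)
    m = sim.m(u, v) if callable(sim.m) else np.asarray(sim.m, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("truth occupancy must lie in [0, 1]")
    N = np.broadcast_to(np.asarray(sim.N, dtype=int), theta.shape).copy()
    n_p = rng.binomial(N, theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        noise_sd = np.where(n_p > 0, np.sqrt(sim.sigma2 / np.maximum(n_p, 1)), 0.0)
    ybar = np.where(n_p > 0, np.exp(m + noise_sd * rng.standard_normal(theta.shape)), np.nan)
    raw_mean = np.where(n_p > 0, (n_p / np.maximum(N, 1)) * np.nan_to_num(ybar), 0.0)
    cells = centers.assign(N=N, n_p=n_p, ybar=ybar, raw_mean=raw_mean)
    truth = centers.assign(theta_true=theta, m_true=m, b_true=theta * np.exp(m))
    return cells, truth


# ---------------------------------------------------------------------------
# deterministic bundled fixtures
# ---------------------------------------------------------------------------

def _fixture_cleaning10() -> pd.DataFrame:
    """Ten metric-dialect corner records, exactly three with a missing dbh
    (so default cleaning keeps seven)."""
    rng = np.random.default_rng(1234)
    rows = []
    taxa = ["Oak", "Maple", "Pine", "Hemlock"]
    for i in range(10):
        row = {"point_id": f"f{i}", "x": 100.0 * i, "y": 50.0 * i,
               "zone": "Z1", "corner_type": "section", "era": "E1"}
        for slot in (1, 2):
            row[f"taxon{slot}"] = taxa[(i + slot) % 4]
            row[f"dbh{slot}"] = round(float(rng.uniform(15, 60)), 1)
            row[f"dist{slot}"] = round(float(rng.uniform(2, 30)), 2)
            row[f"bearing{slot}"] = round(float(rng.uniform(0, 360)), 0)
        rows.append(row)
    for i in (1, 4, 8):  # drop one dbh at three points
        rows[i]["dbh2"] = ""
    return pd.DataFrame(rows)


def _fixture_grid3x3() -> dict:
    """A 3x3-cell grid with 70 point estimates per cell-row region; values
    chosen so every aggregation identity can be checked by hand."""
    grid = GridSpec(x0=0.0, y0=0.0, nx=3, ny=3, cell_size=1000.0)
    rng = np.random.default_rng(42)
    n = 70
    x = rng.uniform(0, 3000.0, n)
    y = rng.uniform(0, 3000.0, n)
    occupied = rng.uniform(size=n) < 0.6
    biomass = np.where(occupied, rng.lognormal(3.0, 0.6, n), 0.0)
    density = np.where(occupied, rng.lognormal(4.5, 0.7, n), 0.0)
    basal = np.where(occupied, rng.lognormal(1.5, 0.5, n), 0.0)
    points = pd.DataFrame({
        "point_id": [f"g{i}" for i in range(n)], "x": x, "y": y,
        "occupied": occupied, "density": density,
        "basal_area": basal, "biomass": biomass,
    })
    return {"grid": grid, "points": points}


_FIXTURES = {
    "cleaning10": _fixture_cleaning10,
    "grid3x3": _fixture_grid3x3,
}


def make_fixture(name: str):
    """Deterministic miniature datasets for tests; same name, same bytes."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}") from None
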