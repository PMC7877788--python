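"""Per-corner stem density, basal area, and biomass from witness trees.

Stem density comes from a Morisita sector-based plotless estimator applied
to the corner-to-tree distances: with one tree per sector in each of ``m``
sectors and stem-center distances ``r_j`` (m), the raw density is

    lambda = f_design * 1e4 * m (m - 1) / (pi * sum_j r_j^2)   [stems/ha]

``f_design`` is a survey-design correction factor (changing surveyor
instructions over zones/eras altered which trees were recorded); a second
factor ``f_size`` rescales the raw density — whose implicit diameter
threshold varies with surveyor behavior — to the density of trees at least
8 inches (20.32 cm) dbh.  Both factors are exogenous lookup-table inputs.

Biomass and basal area use the *raw* density deliberately: each tree's value
is converted with a taxon-specific log-log allometry (biomass) or the circle
area formula (basal area), and the per-point product is

    (density_raw / n_trees) * sum_over_trees(value)

assigned to each tree's taxon, so per-taxon values add exactly to the point
total.  For the standard two-tree corner this is one-half the stem density
times the summed tree values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_points import IN_TO_CM, SurveyPoint, effective_distance

#: Density threshold: 8 inches dbh, exactly 20.32 cm.
DBH_THRESHOLD_IN = 8.0
DBH_THRESHOLD_CM = DBH_THRESHOLD_IN * IN_TO_CM

M2_PER_HA = 1e4
KG_PER_MG = 1e3


class CorrectionTable:
    """Lookup of (zone, corner_type, era) -> (f_design, f_size).

    Factors must be positive; a missing key is an error — survey-design
    corrections cannot be silently defaulted.  The bundled example table is
    synthetic and illustrative only; real analyses supply their own CSV with
    columns ``zone, corner_type, era, f_design, f_size``.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"zone", "corner_type", "era", "f_design", "f_size"}
        if not required <= set(df.columns):
            raise ValueError(f"correction table needs columns {sorted(required)}")
        if (df["f_design"] <= 0).any() or (df["f_size"] <= 0).any():
            raise ValueError("correction factors must be positive")
        self._map = {
            (str(r.zone), str(r.corner_type), str(r.era)): (float(r.f_design), float(r.f_size))
            for r in df.itertuples(index=False)
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrectionTable":
        return cls(pd.read_csv(path, dtype={"zone": str, "corner_type": str, "era": str}))

    @classmethod
    def example(cls) -> "CorrectionTable":
        """Bundled illustrative (synthetic) factor table for tests and demos."""
        with resources.as_file(
            resources.files("plsforest.data") / "correction_factors_example.csv"
        ) as p:
            return cls.from_csv(p)

    def lookup(self, zone: str, corner_type: str, era: str) -> tuple[float, float]:
        key = (str(zone), str(corner_type), str(era))
        try:
            return self._map[key]
        except KeyError:
            raise KeyError(f"no correction factors configured for {key}") from None


class AllometryTable:
    """taxon -> (b0, b1) of the regression of log biomass (kg) on log dbh (cm).

    Natural logs; several taxa may share one equation.  Slopes must be
    positive (biomass increases with dbh).  The bundled table is synthetic
    and illustrative only.
    """

    def __init__(self, df: pd.DataFrame):
        if not {"taxon_std", "b0", "b1"} <= set(df.columns):
            raise ValueError("allometry table needs columns taxon_std, b0, b1")
        if (df["b1"] <= 0).any():
            raise ValueError("allometric slopes b1 must be positive")
        self._map = {str(r.taxon_std): (float(r.b0), float(r.b1)) for r in df.itertuples(index=False)}

    @classmethod
    def from_csv(cls, path: str | Path) -> "AllometryTable":
        return cls(pd.read_csv(path))

    @classmethod
    def example(cls) -> "AllometryTable":
        with resources.as_file(
            resources.files("plsforest.data") / "allometry_example.csv"
        ) as p:
            return cls.from_csv(p)

    def coeffs(self, taxon: str) -> tuple[float, float]:
        try:
            return self._map[str(taxon)]
        except KeyError:
            raise KeyError(f"no allometric coefficients assigned to taxon {taxon!r}") from None


def morisita_density(
    distances: Sequence[float], f_design: float | None = None
) -> float:
    """Raw stem density (stems/ha) from per-sector stem-center distances (m).

    ``distances`` holds one nearest-tree distance per sector (1-4 sectors;
    the standard PLS corner has two opposite semicircles).  One-tree corners
    are not identifiable without an explicit design correction, so
    ``f_design`` is then mandatory and the estimator is
    ``f * 1e4 / (pi r^2)``.
    """
    r = np.asarray(distances, dtype=float)
    m = r.size
    if m < 1 or m > 4:
        raise ValueError(f"number of sectors must be 1-4, got {m}")
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("all distances must be finite and > 0")
    if m == 1:
        if f_design is None:
            raise ValueError(
                "one-tree corner: density is not identifiable without an "
                "explicit f_design correction factor"
            )
        return f_design * M2_PER_HA / (math.pi * float(r[0]) ** 2)
    f = 1.0 if f_design is None else float(f_design)
    return f * M2_PER_HA * m * (m - 1) / (math.pi * float(np.sum(r**2)))


def correct_density_threshold(density_raw: float, f_size: float) -> float:
    """Scale raw density to the density of trees >= 20.32 cm (8 in) dbh."""
    if density_raw < 0:
        raise ValueError("density must be non-negative")
    if f_size <= 0:
        raise ValueError("f_size must be positive")
    return density_raw * f_size


def tree_biomass(dbh_cm: float, b0: float, b1: float) -> float:
    """Aboveground biomass (kg) of one tree: exp(b0 + b1 * ln dbh)."""
    if dbh_cm is None or not math.isfinite(dbh_cm):
        return math.nan
    if dbh_cm <= 0:
        raise ValueError("dbh must be positive for biomass")
    return math.exp(b0 + b1 * math.log(dbh_cm))


def tree_basal_area(dbh_cm: float) -> float:
    """Cross-sectional stem area (m^2): pi * (dbh/200)^2 with dbh in cm."""
    if dbh_cm is None or not math.isfinite(dbh_cm):
        return math.nan
    if dbh_cm < 0:
        raise ValueError("dbh must be non-negative")
    return math.pi * (dbh_cm / 200.0) ** 2


@dataclass
class PointEstimates:
    """Per-corner products: densities (stems/ha), basal area (m^2/ha),
    biomass (Mg/ha), total and per taxon.

    Per-taxon dictionaries sum to the totals exactly by construction.
    ``density_raw`` has no size threshold; ``density_corrected`` is for trees
    >= 20.32 cm dbh.  Per-taxon density splits the raw density by each
    taxon's share of trees at the point.
    """

    point_id: str
    n_trees: int
    density_raw: float = math.nan
    density_corrected: float = math.nan
    basal_area: float = math.nan
    biomass: float = math.nan
    density_by_taxon: dict[str, float] = field(default_factory=dict)
    basal_area_by_taxon: dict[str, float] = field(default_factory=dict)
    biomass_by_taxon: dict[str, float] = field(default_factory=dict)
    exclusion: str | None = None


def point_products(
    point: SurveyPoint, density_raw: float, allometry: AllometryTable
) -> PointEstimates:
    """Biomass/basal-area products at one corner from the raw density.

    With ``n`` trees the per-point quantity is ``(density_raw/n) * sum`` of
    the per-tree values, each term assigned to its tree's taxon; biomass is
    converted kg/ha -> Mg/ha.  Zero-tree points yield zeros.  Any tree with
    a missing dbh makes the point ineligible (handled by upstream cleaning);
    here it yields NaN products with an exclusion reason.
    """
    n = len(point.trees)
    est = PointEstimates(point_id=point.point_id, n_trees=n, density_raw=density_raw)
    if n == 0:
        est.basal_area = 0.0
        est.biomass = 0.0
        return est
    if any(t.missing_dbh for t in point.trees):
        est.exclusion = "missing-dbh"
        return est
    ba_tax: dict[str, float] = {}
    bio_tax: dict[str, float] = {}
    dens_tax: dict[str, float] = {}
    for t in point.trees:
        taxon = t.taxon_std if t.taxon_std is not None else t.taxon_raw
        b0, b1 = allometry.coeffs(taxon)
        ba = (density_raw / n) * tree_basal_area(t.dbh)
        bio = (density_raw / n) * tree_biomass(t.dbh, b0, b1) / KG_PER_MG
        ba_tax[taxon] = ba_tax.get(taxon, 0.0) + ba
        bio_tax[taxon] = bio_tax.get(taxon, 0.0) + bio
        dens_tax[taxon] = dens_tax.get(taxon, 0.0) + density_raw / n
    est.basal_area = float(sum(ba_tax.values()))
    est.biomass = float(sum(bio_tax.values()))
    est.basal_area_by_taxon = ba_tax
    est.biomass_by_taxon = bio_tax
    est.density_by_taxon = dens_tax
    return est


def estimate_points(
    points: Sequence[SurveyPoint],
    allometry: AllometryTable,
    corrections: CorrectionTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full point-level chain over cleaned survey points.

    Returns ``(totals, per_taxon)``:

    * ``totals`` — one row per point: coordinates, tree count, occupancy
      indicator, ``density_raw``, ``density`` (threshold-corrected),
      ``basal_area``, ``biomass``, and an ``exclusion`` reason where a value
      could not be computed (e.g. a one-tree corner with no configured
      design factor).
    * ``per_taxon`` — long table ``(point_id, taxon, density, basal_area,
      biomass)`` whose per-point sums equal the totals exactly.

    Zero-tree corners contribute zeros (density, basal area, biomass all 0);
    they are essential for occupancy denominators downstream.
    """
    rows: list[dict] = []
    taxon_rows: list[dict] = []
    for p in points:
        f_design: float | None = None
        f_size = 1.0
        if corrections is not None:
            f_design, f_size = corrections.lookup(p.zone, p.corner_type, p.era)
        n = len(p.trees)
        base = {
            "point_id": p.point_id, "x": p.x, "y": p.y, "n_trees": n,
            "occupied": n > 0,
        }
        if n == 0:
            rows.append({**base, "density_raw": 0.0, "density": 0.0,
                         "basal_area": 0.0, "biomass": 0.0, "exclusion": None})
            continue
        try:
            dists = [effective_distance(t) for t in p.trees]
            density_raw = morisita_density(dists, f_design)
        except ValueError as exc:
            rows.append({**base, "density_raw": math.nan, "density": math.nan,
                         "basal_area": math.nan, "biomass": math.nan,
                         "exclusion": str(exc)})
            continue
        est = point_products(p, density_raw, allometry)
        est.density_corrected = correct_density_threshold(density_raw, f_size)
        rows.append({**base, "density_raw": est.density_raw,
                     "density": est.density_corrected,
                     "basal_area": est.basal_area, "biomass": est.biomass,
                     "exclusion": est.exclusion})
        for taxon in est.biomass_by_taxon:
            taxon_rows.append({
                "point_id": p.point_id, "taxon": taxon,
                "density": est.density_by_taxon[taxon],
                "basal_area": est.basal_area_by_taxon[taxon],
                "biomass": est.biomass_by_taxon[taxon],
            })
    totals = pd.DataFrame(rows)
    per_taxon = pd.DataFrame(taxon_rows, columns=["point_id", "taxon", "density",
                                                  "basal_area", "biomass"])
    return totals, per_taxon
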