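"""Point-level witness-tree records: parsing, standardization, and cleaning.

Public Land Survey (PLS) surveyors marked section and quarter-section corners
on a half-mile (~805 m) lattice and recorded two to four "witness" trees at
each corner: a vernacular taxon name, the diameter at breast height (dbh),
and the distance and bearing from the corner to the tree.  This module turns
transcribed corner records into the canonical in-memory representation used
by the rest of the pipeline: :class:`SurveyPoint` objects holding
:class:`WitnessTree` entries, with all diameters in cm and distances in m.

Two input unit dialects are supported and must be declared explicitly in
:class:`CleaningConfig` (silent autodetection is deliberately not offered):

``metric``
    dbh in cm, distances in m.
``historical``
    dbh in inches, distances in links (or chains), the units surveyors used.

Treeless corners ("no tree" posts, water) are retained as zero-tree survey
points: they carry the zeros that the occupancy model downstream needs.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Exact unit conversions (international foot).
IN_TO_CM = 2.54
FT_TO_M = 0.3048
LINK_TO_M = 0.66 * FT_TO_M        # 1 link  = 0.66 ft = 0.201168 m
CHAIN_TO_M = 66.0 * FT_TO_M       # 1 chain = 66 ft   = 20.1168 m

#: The 20 genus-level taxon groups plus "Other hardwood" used throughout.
STANDARD_TAXA: tuple[str, ...] = (
    "Ash", "Basswood", "Beech", "Birch", "Black gum/sweet gum",
    "Cedar/juniper", "Cherry", "Dogwood", "Elm", "Fir", "Hemlock", "Hickory",
    "Ironwood", "Maple", "Oak", "Pine", "Poplar/tulip poplar", "Spruce",
    "Tamarack", "Walnut", "Other hardwood",
)

NO_TREE = "no-tree"
WATER = "water"
UNKNOWN = "unknown"
NON_TREE_SENTINELS: tuple[str, ...] = (NO_TREE, WATER, UNKNOWN)

#: Raw taxon strings that mark an empty tree slot already at parse time.
_EMPTY_SLOT = {"", "no tree", "notree", "no-tree", "none", "nan"}

_MAX_TREES = 4


def inches_to_cm(value):
    return np.asarray(value, dtype=float) * IN_TO_CM if np.ndim(value) else float(value) * IN_TO_CM


def cm_to_inches(value):
    return np.asarray(value, dtype=float) / IN_TO_CM if np.ndim(value) else float(value) / IN_TO_CM


def links_to_m(value):
    return float(value) * LINK_TO_M


def chains_to_m(value):
    return float(value) * CHAIN_TO_M


@dataclass
class WitnessTree:
    """One measured tree at a survey corner.

    dbh is in cm, distances in m.  ``dist_effective`` is the corner-to-stem-
    center distance used by the plotless density estimator: the recorded
    (face) distance plus half the diameter.  ``flags`` collects per-tree data
    issues (e.g. a missing dbh, which forces the effective distance to fall
    back to the recorded one).
    """

    taxon_raw: str
    taxon_std: str | None = None
    dbh: float | None = None
    dist_recorded: float | None = None
    dist_effective: float | None = None
    bearing: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def missing_dbh(self) -> bool:
        return self.dbh is None or not math.isfinite(self.dbh)


@dataclass
class SurveyPoint:
    """One survey corner with its 0-4 witness trees.

    Coordinates are projected (equal-area) in meters; no geodesy is performed
    here.  ``zone``, ``corner_type`` and ``era`` key into the correction-
    factor table used by density estimation.
    """

    point_id: str
    x: float
    y: float
    zone: str = ""
    corner_type: str = "section"
    era: str = ""
    trees: list[WitnessTree] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point {self.point_id}: non-finite coordinates")
        if len(self.trees) > _MAX_TREES:
            raise ValueError(f"point {self.point_id}: more than {_MAX_TREES} trees")


@dataclass
class CleaningConfig:
    """Unit dialect of the input file plus individually toggleable cleaning rules.

    Every enabled rule that removes a point is logged with an exclusion-reason
    code, so ``kept + excluded`` always reconstructs the input.
    """

    dbh_unit: str = "cm"          # "cm" | "in"
    dist_unit: str = "m"          # "m" | "links" | "chains"
    drop_missing_dbh: bool = True    # biomass rule: any tree lacking dbh
    drop_short_distance: bool = True  # density rule: distance below min_distance
    min_distance: float = 1e-3       # m; avoids division blow-up in the estimator

    _DBH_FACTORS = {"cm": 1.0, "in": IN_TO_CM}
    _DIST_FACTORS = {"m": 1.0, "links": LINK_TO_M, "chains": CHAIN_TO_M}

    def __post_init__(self) -> None:
        if self.dbh_unit not in self._DBH_FACTORS:
            raise ValueError(f"unknown dbh unit {self.dbh_unit!r}")
        if self.dist_unit not in self._DIST_FACTORS:
            raise ValueError(f"unknown distance unit {self.dist_unit!r}")

    @classmethod
    def metric(cls, **kw) -> "CleaningConfig":
        return cls(dbh_unit="cm", dist_unit="m", **kw)

    @classmethod
    def historical(cls, dist_unit: str = "links", **kw) -> "CleaningConfig":
        """Surveyor units: dbh in inches, distances in links (or chains)."""
        return cls(dbh_unit="in", dist_unit=dist_unit, **kw)

    @property
    def dbh_factor(self) -> float:
        return self._DBH_FACTORS[self.dbh_unit]

    @property
    def dist_factor(self) -> float:
        return self._DIST_FACTORS[self.dist_unit]


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name)).strip().casefold()


class TaxonTable:
    """Translation table from surveyor vernacular names to standard taxa.

    Lookup is total after case/whitespace normalization; unmatched names map
    to ``"unknown"`` and are tallied by the caller.  Every standardized value
    must be one of the 21 groups or a non-tree sentinel.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        valid = set(STANDARD_TAXA) | set(NON_TREE_SENTINELS)
        self._map: dict[str, str] = {}
        for vernacular, std in pairs:
            if std not in valid:
                raise ValueError(f"standardized taxon {std!r} is not in the closed vocabulary")
            self._map[_normalize_name(vernacular)] = std

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaxonTable":
        df = pd.read_csv(path, dtype=str)
        if not {"vernacular", "taxon_std"} <= set(df.columns):
            raise ValueError("taxon table must have columns 'vernacular' and 'taxon_std'")
        return cls(zip(df["vernacular"], df["taxon_std"]))

    @classmethod
    def example(cls) -> "TaxonTable":
        """The bundled illustrative table (synthetic; not the study's own)."""
        with resources.as_file(
            resources.files("plsforest.data") / "taxon_translation_example.csv"
        ) as p:
            return cls.from_csv(p)

    def lookup(self, name: str) -> str:
        return self._map.get(_normalize_name(name), UNKNOWN)

    def __contains__(self, name: str) -> bool:
        return _normalize_name(name) in self._map


def _parse_float(raw) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        return float(s)
    except ValueError:
        raise


REQUIRED_COLUMNS = ("point_id", "x", "y")
OPTIONAL_COLUMNS = ("zone", "corner_type", "era")


def parse_points(
    src: str | Path | pd.DataFrame, config: CleaningConfig
) -> tuple[list[SurveyPoint], pd.DataFrame]:
    """Parse a wide one-row-per-corner table into :class:`SurveyPoint` objects.

    The schema has columns ``point_id, x, y[, zone, corner_type, era]`` and,
    for tree slots i = 1..4, ``taxon{i}, dbh{i}, dist{i}[, bearing{i}]``.
    Units are converted according to ``config``.  A malformed header is a hard
    error; an unparseable row is skipped and logged.

    Returns ``(points, log)`` where ``log`` has columns ``row, point_id,
    reason`` for every rejected row.
    """
    if isinstance(src, pd.DataFrame):
        df = src.astype(str)
    else:
        df = pd.read_csv(src, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header: missing required columns {missing}")

    points: list[SurveyPoint] = []
    rejected: list[dict] = []
    for irow, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        pid = str(rec["point_id"]).strip()
        try:
            x = _parse_float(rec["x"])
            y = _parse_float(rec["y"])
            if x is None or y is None:
                raise ValueError("missing coordinate")
            trees: list[WitnessTree] = []
            for i in range(1, _MAX_TREES + 1):
                raw_taxon = str(rec.get(f"taxon{i}", "") or "").strip()
                if _normalize_name(raw_taxon) in _EMPTY_SLOT:
                    continue
                dbh = _parse_float(rec.get(f"dbh{i}"))
                dist = _parse_float(rec.get(f"dist{i}"))
                bearing = None
                try:
                    bearing = _parse_float(rec.get(f"bearing{i}"))
                except ValueError:
                    bearing = None  # free-text bearings are tolerated, not parsed
                tree = WitnessTree(
                    taxon_raw=raw_taxon,
                    dbh=None if dbh is None else dbh * config.dbh_factor,
                    dist_recorded=None if dist is None else dist * config.dist_factor,
                    bearing=bearing,
                )
                if tree.dist_recorded is not None:
                    tree.dist_effective = effective_distance(tree)
                trees.append(tree)
            points.append(
                SurveyPoint(
                    point_id=pid,
                    x=x,
                    y=y,
                    zone=str(rec.get("zone", "") or ""),
                    corner_type=str(rec.get("corner_type", "section") or "section"),
                    era=str(rec.get("era", "") or ""),
                    trees=trees,
                )
            )
        except (ValueError, TypeError) as exc:
            rejected.append({"row": irow, "point_id": pid, "reason": str(exc)})
    log = pd.DataFrame(rejected, columns=["row", "point_id", "reason"])
    return points, log


def effective_distance(tree: WitnessTree) -> float:
    """Corner-to-stem-center distance: recorded distance plus half the dbh.

    Surveyors measured to the face of the tree; the plotless estimator wants
    the distance to the stem center, hence ``dist + dbh/2`` (dbh in cm,
    distance in m, so the correction is ``dbh/200``).  A missing dbh flags the
    tree and falls back to the recorded distance.
    """
    if tree.dist_recorded is None:
        raise ValueError("recorded distance is missing")
    if tree.dist_recorded < 0:
        raise ValueError(f"negative recorded distance {tree.dist_recorded}")
    if tree.missing_dbh:
        if "missing-dbh-distance" not in tree.flags:
            tree.flags.append("missing-dbh-distance")
        return tree.dist_recorded
    return tree.dist_recorded + tree.dbh / 200.0


def standardize_taxa(
    points: Sequence[SurveyPoint], table: TaxonTable
) -> tuple[list[SurveyPoint], Counter]:
    """Fill ``taxon_std`` on every tree; return the points and unmatched tally.

    Trees whose standardized taxon is a non-tree sentinel ("no-tree",
    "water") are removed from the point's tree list — they are marker posts,
    not measurable trees — leaving a zero-tree point that still contributes
    to occupancy denominators.
    """
    unmatched: Counter = Counter()
    for p in points:
        kept: list[WitnessTree] = []
        for t in p.trees:
            std = table.lookup(t.taxon_raw)
            if std == UNKNOWN and t.taxon_raw not in table:
                unmatched[t.taxon_raw] += 1
            t.taxon_std = std
            if std in (NO_TREE, WATER):
                continue
            kept.append(t)
        p.trees = kept
    return list(points), unmatched


# Exclusion-rule registry: code -> predicate on a SurveyPoint, evaluated in
# order.  Real state-specific rules can be registered by downstream users.
def _rule_missing_dbh(point: SurveyPoint, config: CleaningConfig) -> bool:
    return len(point.trees) > 0 and any(t.missing_dbh for t in point.trees)


def _rule_short_distance(point: SurveyPoint, config: CleaningConfig) -> bool:
    return any(
        t.dist_recorded is not None and t.dist_recorded < config.min_distance
        for t in point.trees
    )


CLEANING_RULES: list[tuple[str, str, object]] = [
    # (code, config switch attribute, predicate)
    ("missing-dbh", "drop_missing_dbh", _rule_missing_dbh),
    ("short-distance", "drop_short_distance", _rule_short_distance),
]


def apply_cleaning(
    points: Sequence[SurveyPoint], config: CleaningConfig
) -> tuple[list[SurveyPoint], pd.DataFrame]:
    """Drop points violating enabled rules; return (kept, exclusion ledger).

    The ledger has one row per removed point, ``point_id`` and the code of
    the first rule it violated, so the removals are partitioned by rule and
    ``kept + removed`` equals the input.  With all rules off this is the
    identity, and the operation is idempotent.
    """
    kept: list[SurveyPoint] = []
    ledger_rows: list[dict] = []
    for p in points:
        code = None
        for rule_code, switch, predicate in CLEANING_RULES:
            if getattr(config, switch) and predicate(p, config):
                code = rule_code
                break
        if code is None:
            kept.append(p)
        else:
            ledger_rows.append({"point_id": p.point_id, "rule": code})
    ledger = pd.DataFrame(ledger_rows, columns=["point_id", "rule"])
    return kept, ledger


def write_exclusion_ledger(ledger: pd.DataFrame, path: str | Path) -> None:
    ledger.to_csv(path, index=False)
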