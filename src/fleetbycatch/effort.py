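"""Harmonization of gillnet effort records into the vessel-day-rectangle table.

The analysis unit throughout the package is one fishing day of one vessel
in one ICES statistical rectangle.  Raw logbook/sales-note style records
(one line per landing) are collapsed to that unit, covariates are binned
into the model's factor levels, missing soak-time/net-length are imputed
from an electronically monitored (EM) reference fleet, depth is assigned
per rectangle, monthly declarations without positions are allocated to
the home-harbour rectangle, and rows where acoustic-deterrent (pinger)
use is mandatory can be filtered out.

ICES statistical rectangles are 1 deg longitude x 0.5 deg latitude cells
coded as two digits (latitude band, band 01 starting at 36N) followed by
a letter (10-degree longitude block, 'I' skipped, block F spanning
0-10E) and a digit (degree within block), e.g. "37F7".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "haversine_km",
    "MESH_CLASSES",
    "VESSEL_CLASSES",
    "ICES_AREAS",
    "AREA_TO_POPULATION",
    "PingerRule",
    "rectangle_geometry",
    "encode_rectangle",
    "mesh_class",
    "vessel_class",
    "quarter_of_month",
    "population_of_area",
    "collapse_to_strata",
    "impute_effort_covariates",
    "assign_depth",
    "allocate_home_harbour",
    "filter_pinger_mandatory",
    "validate_effort_table",
]

MESH_CLASSES = ("<120 mm", "120-200", ">200 mm")
VESSEL_CLASSES = ("<8 m", "8-10 m", "10-12 m", "12-15 m", ">15 m")
ICES_AREAS = ("IVb", "IIIa20", "IIIa21", "IIIc22", "IIIb23")

#: Assessment-unit membership is a deterministic function of ICES area:
#: the North Sea + Skagerrak belong to the North Sea population, the
#: Kattegat, Belt Seas and Sound to the Western Baltic population.
AREA_TO_POPULATION = {
    "IVb": "North Sea Population",
    "IIIa20": "North Sea Population",
    "IIIa21": "Western Baltic Population",
    "IIIc22": "Western Baltic Population",
    "IIIb23": "Western Baltic Population",
}

#: Columns every harmonized effort table must carry.
EFFORT_COLUMNS = [
    "vessel_id",
    "year",
    "quarter",
    "rectangle_code",
    "lon",
    "lat",
    "ices_area",
    "mesh_class",
    "vessel_class",
    "population",
    "soak_time_h",
    "net_length_m",
    "depth_m",
    "fishing_days",
    "pinger_mandatory",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lonlat: np.ndarray, lonlat2: np.ndarray | None = None) -> np.ndarray:
    """Great-circle distance matrix (km) between (lon, lat) degree positions."""
    from sklearn.metrics.pairwise import haversine_distances

    a = np.radians(np.asarray(lonlat, dtype=float)[:, ::-1])  # -> (lat, lon)
    b = a if lonlat2 is None else np.radians(np.asarray(lonlat2, dtype=float)[:, ::-1])
    return haversine_distances(a, b) * EARTH_RADIUS_KM


# -- ICES rectangle geometry -------------------------------------------------

# Longitude block letters, 10 degrees each, 'I' skipped; 'F' is 0-10E.
_LON_LETTERS = "ABCDEFGHJKLM"
_LON_BASE = {ch: (i - _LON_LETTERS.index("F")) * 10 for i, ch in enumerate(_LON_LETTERS)}
_RECT_RE = re.compile(r"^(\d{2})([A-HJ-M])(\d)$")


def rectangle_geometry(code: str) -> dict[str, float]:
    """Centroid and bounds of an ICES statistical rectangle.

    Returns a dict with ``lon``, ``lat`` (centroid), ``lon_min``,
    ``lon_max``, ``lat_min``, ``lat_max``.  Raises ``ValueError`` for a
    malformed or out-of-range code.
    """
    m = _RECT_RE.match(str(code).strip().upper())
    if not m:
        raise ValueError(f"malformed ICES rectangle code: {code!r}")
    band = int(m.group(1))
    if band < 1:
        raise ValueError(f"latitude band out of range in code {code!r}")
    lat_min = 36.0 + 0.5 * (band - 1)
    lon_min = float(_LON_BASE[m.group(2)] + int(m.group(3)))
    return {
        "lon": lon_min + 0.5,
        "lat": lat_min + 0.25,
        "lon_min": lon_min,
        "lon_max": lon_min + 1.0,
        "lat_min": lat_min,
        "lat_max": lat_min + 0.5,
    }


def encode_rectangle(lon: float, lat: float) -> str:
    """Inverse of :func:`rectangle_geometry`: code of the cell containing
    (lon, lat)."""
    band = int(np.floor((lat - 36.0) / 0.5)) + 1
    if band < 1 or band > 99:
        raise ValueError(f"latitude {lat} outside the ICES rectangle grid")
    block_idx = int(np.floor(lon / 10.0)) + _LON_LETTERS.index("F")
    if not 0 <= block_idx < len(_LON_LETTERS):
        raise ValueError(f"longitude {lon} outside the ICES rectangle grid")
    digit = int(np.floor(lon - 10.0 * np.floor(lon / 10.0)))
    return f"{band:02d}{_LON_LETTERS[block_idx]}{digit}"


# -- covariate binning -------------------------------------------------------


def mesh_class(mesh_mm: float) -> str:
    """Mesh-size class: [0,120) -> '<120 mm'; [120,200] -> '120-200';
    (200,inf) -> '>200 mm'.  Endpoint membership of the middle class is a
    package convention; the class labels themselves print no bounds."""
    if not np.isfinite(mesh_mm) or mesh_mm <= 0:
        raise ValueError(f"mesh size must be positive, got {mesh_mm}")
    if mesh_mm < 120:
        return MESH_CLASSES[0]
    if mesh_mm <= 200:
        return MESH_CLASSES[1]
    return MESH_CLASSES[2]


def vessel_class(length_m: float) -> str:
    """Vessel length class with half-open bins [8,10), [10,12), [12,15)."""
    if not np.isfinite(length_m) or length_m <= 0:
        raise ValueError(f"vessel length must be positive, got {length_m}")
    if length_m < 8:
        return VESSEL_CLASSES[0]
    if length_m < 10:
        return VESSEL_CLASSES[1]
    if length_m < 12:
        return VESSEL_CLASSES[2]
    if length_m < 15:
        return VESSEL_CLASSES[3]
    return VESSEL_CLASSES[4]


def quarter_of_month(month: int) -> int:
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month out of range: {month}")
    return (int(month) - 1) // 3 + 1


def population_of_area(ices_area: str) -> str:
    try:
        return AREA_TO_POPULATION[ices_area]
    except KeyError:
        raise ValueError(f"unknown ICES area: {ices_area!r}") from None


# -- collapsing raw records --------------------------------------------------


def collapse_to_strata(
    raw: pd.DataFrame, area_of_rectangle: dict[str, str] | None = None
) -> pd.DataFrame:
    """Collapse per-landing raw records to one row per vessel-day-rectangle.

    Rules applied within each (vessel_id, date, rectangle_code) stratum:

    * mesh class is that of the mesh with the largest summed landed
      weight (ties broken toward the larger mesh);
    * soak-time is the mean of reported soak-times;
    * net-length is the sum of all reported net-fleet lengths.

    Expects columns ``vessel_id, date, rectangle_code, mesh_size_mm,
    landed_weight_kg, vessel_length_m`` and optionally ``soak_time_h,
    net_length_m``.  ``area_of_rectangle`` maps rectangle codes to ICES
    areas; rows in unmapped rectangles raise.
    """
    req = ["vessel_id", "date", "rectangle_code", "mesh_size_mm", "landed_weight_kg", "vessel_length_m"]
    missing = [c for c in req if c not in raw.columns]
    if missing:
        raise ValueError(f"raw effort table missing columns: {missing}")
    if len(raw) == 0:
        return pd.DataFrame(columns=EFFORT_COLUMNS)

    df = raw.copy()
    df["date"] = pd.to_datetime(df["date"])
    if (df["mesh_size_mm"] <= 0).any():
        bad = df.index[df["mesh_size_mm"] <= 0].tolist()
        raise ValueError(f"non-positive mesh sizes at rows {bad}")
    if (df["landed_weight_kg"] < 0).any():
        bad = df.index[df["landed_weight_kg"] < 0].tolist()
        raise ValueError(f"negative landed weights at rows {bad}")

    keys = ["vessel_id", "date", "rectangle_code"]
    rows = []
    for (vessel, date, rect), grp in df.groupby(keys, sort=True):
        # dominant mesh: max summed landings, tie -> larger mesh
        wt = grp.groupby("mesh_size_mm")["landed_weight_kg"].sum()
        best_w = wt.max()
        dominant_mesh = max(wt.index[wt == best_w])
        soak = grp["soak_time_h"].mean() if "soak_time_h" in grp else np.nan
        net = grp["net_length_m"].sum(min_count=1) if "net_length_m" in grp else np.nan
        geom = rectangle_geometry(rect)
        area = None
        if area_of_rectangle is not None:
            if rect not in area_of_rectangle:
                raise ValueError(f"rectangle {rect!r} missing from area map")
            area = area_of_rectangle[rect]
        rows.append(
            {
                "vessel_id": vessel,
                "year": date.year,
                "quarter": quarter_of_month(date.month),
                "rectangle_code": rect,
                "lon": geom["lon"],
                "lat": geom["lat"],
                "ices_area": area,
                "mesh_class": mesh_class(dominant_mesh),
                "vessel_class": vessel_class(grp["vessel_length_m"].iloc[0]),
                "population": population_of_area(area) if area else None,
                "soak_time_h": soak,
                "net_length_m": net,
                "depth_m": np.nan,
                "fishing_days": 1,
                "pinger_mandatory": False,
            }
        )
    return pd.DataFrame(rows, columns=EFFORT_COLUMNS)


def impute_effort_covariates(
    effort: pd.DataFrame,
    reference_em: pd.DataFrame,
    fallback: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fill missing soak-time / net-length from an EM reference fleet.

    The reference value is the stratum mean (stratum = mesh_class x
    vessel_class) computed from the EM table.  Strata absent from the
    reference fall back to an expert table with columns ``mesh_class,
    vessel_class, soak_time_h, net_length_m``.  Provenance columns
    ``soak_source`` / ``net_source`` record observed / reference /
    fallback per row.  Rows that cannot be filled raise, listing strata.
    """
    if len(reference_em) == 0:
        raise ValueError("reference EM table is empty")
    strata = ["mesh_class", "vessel_class"]
    ref_means = reference_em.groupby(strata)[["soak_time_h", "net_length_m"]].mean()

    fb: dict[tuple[str, str], dict[str, float]] = {}
    if fallback is not None:
        for _, r in fallback.iterrows():
            fb[(r["mesh_class"], r["vessel_class"])] = {
                "soak_time_h": r["soak_time_h"],
                "net_length_m": r["net_length_m"],
            }

    out = effort.copy()
    for col, src_col in (("soak_time_h", "soak_source"), ("net_length_m", "net_source")):
        out[src_col] = "observed"
        missing_mask = out[col].isna()
        unresolved: set[tuple[str, str]] = set()
        for idx in out.index[missing_mask]:
            key = (out.at[idx, "mesh_class"], out.at[idx, "vessel_class"])
            if key in ref_means.index and np.isfinite(ref_means.loc[key, col]):
                out.at[idx, col] = ref_means.loc[key, col]
                out.at[idx, src_col] = "reference"
            elif key in fb and np.isfinite(fb[key][col]):
                out.at[idx, col] = fb[key][col]
                out.at[idx, src_col] = "fallback"
            else:
                unresolved.add(key)
        if unresolved:
            raise ValueError(
                f"missing {col} with no reference or fallback for strata: "
                f"{sorted(unresolved)}"
            )
        n_filled = int(missing_mask.sum())
        if n_filled:
            logger.info("imputed %d missing %s values", n_filled, col)
    return out


def assign_depth(effort: pd.DataFrame, bathymetry: dict[str, float]) -> pd.DataFrame:
    """Set ``depth_m`` to the mean rectangle depth from ``bathymetry``."""
    missing = sorted(set(effort["rectangle_code"]) - set(bathymetry))
    if missing:
        raise KeyError(f"rectangles missing from bathymetry map: {missing}")
    bad = sorted(k for k, v in bathymetry.items() if not v > 0)
    if bad:
        raise ValueError(
            f"non-positive depths (log-depth undefined) for rectangles: {bad}"
        )
    out = effort.copy()
    out["depth_m"] = out["rectangle_code"].map(bathymetry).astype(float)
    return out


def allocate_home_harbour(monthly: pd.DataFrame) -> pd.DataFrame:
    """Expand monthly declarations into daily rows in the home-harbour
    rectangle.

    ``monthly`` needs columns ``vessel_id, year, month, fishing_days,
    home_harbour_rectangle`` plus any covariate columns, which are copied
    onto every expanded row.  Total fishing days are conserved.
    """
    req = ["vessel_id", "year", "month", "fishing_days", "home_harbour_rectangle"]
    missing = [c for c in req if c not in monthly.columns]
    if missing:
        raise ValueError(f"monthly table missing columns: {missing}")
    if monthly["home_harbour_rectangle"].isna().any():
        bad = monthly.index[monthly["home_harbour_rectangle"].isna()].tolist()
        raise ValueError(f"missing home harbour for rows {bad}")
    rows = []
    for _, rec in monthly.iterrows():
        rect = rec["home_harbour_rectangle"]
        geom = rectangle_geometry(rect)
        n_days = int(rec["fishing_days"])
        base = {
            k: rec[k]
            for k in monthly.columns
            if k not in ("month", "fishing_days", "home_harbour_rectangle")
        }
        base.update(
            rectangle_code=rect,
            lon=geom["lon"],
            lat=geom["lat"],
            quarter=quarter_of_month(int(rec["month"])),
            fishing_days=1,
        )
        rows.extend([dict(base) for _ in range(n_days)])
    return pd.DataFrame(rows)


# -- pinger filter -----------------------------------------------------------


@dataclass(frozen=True)
class PingerRule:
    """One scope tuple of the acoustic-deterrent regulation.

    A row is removed when its area is in ``ices_areas``, its vessel class
    is in ``vessel_classes``, its mesh class is in ``mesh_classes`` (empty
    tuple = any) and its quarter is in ``quarters`` (empty = any).
    """

    ices_areas: tuple[str, ...]
    vessel_classes: tuple[str, ...]
    mesh_classes: tuple[str, ...] = ()
    quarters: tuple[int, ...] = ()

    def matches(self, df: pd.DataFrame) -> pd.Series:
        m = df["ices_area"].isin(self.ices_areas)
        m &= df["vessel_class"].isin(self.vessel_classes)
        if self.mesh_classes:
            m &= df["mesh_class"].isin(self.mesh_classes)
        if self.quarters:
            m &= df["quarter"].isin(self.quarters)
        return m


def filter_pinger_mandatory(
    effort: pd.DataFrame, rules: list[PingerRule]
) -> pd.DataFrame:
    """Remove rows where pinger use is mandatory under ``rules``.

    Models the "full compliance, 100% effective pingers" scenario: the
    retained subset is the effort assumed to carry bycatch risk.
    """
    if not rules:
        return effort.copy()
    removed = pd.Series(False, index=effort.index)
    for rule in rules:
        removed |= rule.matches(effort)
    logger.info(
        "pinger filter removed %d of %d rows", int(removed.sum()), len(effort)
    )
    return effort.loc[~removed].copy()


def validate_effort_table(effort: pd.DataFrame, em: bool = False) -> None:
    """Re-validate the harmonized-table invariants; raise on violation."""
    missing = [c for c in EFFORT_COLUMNS if c not in effort.columns]
    if missing:
        raise ValueError(f"effort table missing columns: {missing}")
    if len(effort) == 0:
        return
    if not effort["mesh_class"].isin(MESH_CLASSES).all():
        raise ValueError("mesh_class outside enumerated levels")
    if not effort["vessel_class"].isin(VESSEL_CLASSES).all():
        raise ValueError("vessel_class outside enumerated levels")
    if not effort["ices_area"].isin(ICES_AREAS).all():
        raise ValueError("ices_area outside enumerated levels")
    expected_pop = effort["ices_area"].map(AREA_TO_POPULATION)
    if not (effort["population"] == expected_pop).all():
        raise ValueError("population inconsistent with ices_area")
    for col in ("soak_time_h", "net_length_m", "depth_m"):
        vals = effort[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals) & (vals > 0)):
            raise ValueError(f"{col} must be strictly positive and finite")
    if not effort["quarter"].isin([1, 2, 3, 4]).all():
        raise ValueError("quarter outside 1..4")
    if em:
        y = effort["bycatch_count"].to_numpy()
        if not np.all((y >= 0) & (y == np.round(y))):
            raise ValueError("bycatch_count must be non-negative integers")
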