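"""Removal limits for the Western Baltic harbour-porpoise assessment unit.

Implements the Potential Biological Removal (PBR) framework of the US
Marine Mammal Protection Act and its conservation-objective retuning
("modified" PBR, mPBR):

    PBR = N_min * (1/2) * R_max * F_r

where ``N_min`` is the 20th-percentile minimum population estimate

    N_min = N / exp(z * sqrt(ln(1 + CV^2))),   z = 0.842,

``R_max`` is the maximum net recruitment rate (default 0.04 for
cetaceans) and ``F_r`` a recovery factor.  PBR conventionally uses
F_r = 0.5 or 1.0; mPBR uses retuned values (0.15 or 0.35) derived from
population-projection robustness trials, which are taken as given
constants here.

Survey densities (individuals/km^2) are converted to abundance over the
assessment-unit area, by default the Kattegat + Sound + Belt Seas
surfaces actually sampled for bycatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DEFAULT_AREAS_KM2",
    "DEFAULT_FR_SCHEMES",
    "AbundanceEstimate",
    "RemovalLimits",
    "area_corrected_abundance",
    "n_min",
    "removal_limit",
    "removal_limits_table",
    "assess_sustainability",
]

#: Surface areas (km^2) of the Western Baltic assessment unit components
#: over which bycatch was estimated: Kattegat, the Sound, the Belt Seas.
DEFAULT_AREAS_KM2: dict[str, float] = {
    "Kattegat": 20_536.0,
    "Sound": 2_281.0,
    "Belt Seas": 17_862.0,
}

#: (scheme, F_r) pairs reported by convention: PBR with 0.5/1.0 and the
#: retuned mPBR with 0.15/0.35.
DEFAULT_FR_SCHEMES: tuple[tuple[str, float], ...] = (
    ("PBR", 0.5),
    ("mPBR", 0.15),
    ("PBR", 1.0),
    ("mPBR", 0.35),
)


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class AbundanceEstimate:
    """Area-corrected abundance for one survey year."""

    year: int
    density: float  # individuals / km^2
    cv: float
    areas_km2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREAS_KM2)
    )

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        if self.cv <= 0:
            raise ValueError(f"CV must be > 0, got {self.cv}")
        bad = {k: v for k, v in self.areas_km2.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive areas: {bad}")

    @property
    def n(self) -> int:
        return area_corrected_abundance(self.density, self.areas_km2)


@dataclass
class RemovalLimits:
    """The four PBR/mPBR limits for one year."""

    year: int
    n_abundance: int
    cv: float
    n_min: int
    r_max: float = 0.04
    z_score: float = 0.842
    limits: dict[tuple[str, float], int] = field(default_factory=dict)


def area_corrected_abundance(density: float, areas_km2: dict[str, float]) -> int:
    """Abundance N = round(density * total area).

    Parameters
    ----------
    density
        Survey density in individuals/km^2 (>= 0).
    areas_km2
        Named component surfaces in km^2, all positive.
    """
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    total = 0.0
    for name, a in areas_km2.items():
        if a <= 0:
            raise ValueError(f"area {name!r} must be positive, got {a}")
        total += a
    return _round_half_away(density * total)


def n_min(n: float, cv: float, z: float = 0.842) -> int:
    """Minimum population estimate: the 20th percentile of a log-normal
    abundance estimate, N / exp(z * sqrt(ln(1 + CV^2)))."""
    if n < 0:
        raise ValueError(f"N must be >= 0, got {n}")
    if cv <= 0:
        raise ValueError(f"CV must be > 0, got {cv}")
    return _round_half_away(n / math.exp(z * math.sqrt(math.log(1.0 + cv * cv))))


def removal_limit(nmin: float, r_max: float, f_r: float) -> int:
    """One removal limit: round(N_min * 0.5 * R_max * F_r)."""
    if nmin <= 0 or r_max <= 0 or f_r <= 0:
        raise ValueError("N_min, R_max and F_r must all be positive")
    if f_r > 1.0:
        import warnings

        warnings.warn(f"recovery factor F_r={f_r} outside (0, 1]", stacklevel=2)
    return _round_half_away(nmin * 0.5 * r_max * f_r)


def removal_limits_table(
    estimates: list[AbundanceEstimate],
    r_max: float = 0.04,
    z: float = 0.842,
    schemes: tuple[tuple[str, float], ...] = DEFAULT_FR_SCHEMES,
    n_override: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Limits for several survey years, one row per year.

    ``n_override`` replaces the computed abundance for given years (used
    when an externally reported N should be carried through unchanged).
    """
    rows = []
    for est in estimates:
        n = est.n
        if n_override and est.year in n_override:
            n = n_override[est.year]
        nm = n_min(n, est.cv, z)
        row: dict[str, object] = {
            "year": est.year,
            "density": est.density,
            "abundance": n,
            "cv": est.cv,
            "n_min": nm,
            "r_max": r_max,
        }
        for scheme, fr in schemes:
            row[f"{scheme}_Fr_{fr}"] = removal_limit(nm, r_max, fr)
        rows.append(row)
    return pd.DataFrame(rows)


def assess_sustainability(
    estimate_point: float,
    ci_low: float,
    ci_high: float,
    limits: RemovalLimits | dict[tuple[str, float], int],
    year: int | None = None,
    estimate_year: int | None = None,
) -> pd.DataFrame:
    """Compare a predicted bycatch total (with CI) to removal limits.

    Returns one row per limit with the verdict ``exceeds_point`` (the
    point estimate is above the limit) and ``limit_in_ci`` (the limit
    falls inside the estimate's confidence interval).
    """
    if isinstance(limits, RemovalLimits):
        if estimate_year is not None and estimate_year != limits.year:
            raise ValueError(
                f"estimate year {estimate_year} does not match "
                f"limits year {limits.year}"
            )
        year = limits.year
        limit_map = limits.limits
    else:
        limit_map = limits
    if ci_low > ci_high:
        raise ValueError("ci_low must be <= ci_high")
    rows = []
    for (scheme, fr), lim in limit_map.items():
        rows.append(
            {
                "year": year,
                "scheme": scheme,
                "f_r": fr,
                "limit": lim,
                "estimate": estimate_point,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "exceeds_point": estimate_point > lim,
                "limit_in_ci": ci_low <= lim <= ci_high,
                "limit_below_ci": lim < ci_low,
            }
        )
    return pd.DataFrame(rows)
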