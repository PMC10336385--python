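"""Stratified BPUE raising: the classical scaling-up comparator.

Bycatch per unit effort (porpoises per fishing day) is estimated per
stratum (quarter x ICES area) from the EM-monitored fishing days and
multiplied by the fleet's fishing days in the same strata.  Confidence
intervals come from a non-parametric bootstrap that resamples EM
fishing-day rows with replacement within stratum (optionally blocking
by vessel) and reports percentile intervals of the raised total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RaisedEstimate", "compute_bpue", "raise_to_fleet", "bootstrap_ci"]

STRATUM = ["quarter", "ices_area"]


@dataclass
class RaisedEstimate:
    """Raised fleet-total bycatch with optional bootstrap interval."""

    point: float
    per_stratum: pd.DataFrame
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low must be <= ci_high")


def compute_bpue(em: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum bycatch rate: summed counts over summed fishing days.

    Returns columns ``quarter, ices_area, observed_days,
    observed_bycatch, bpue``.  Strata present but with zero fishing days
    get NaN and a warning.
    """
    for col in STRATUM + ["bycatch_count", "fishing_days"]:
        if col not in em.columns:
            raise ValueError(f"EM table missing column {col!r}")
    g = (
        em.groupby(STRATUM, sort=True)
        .agg(
            observed_days=("fishing_days", "sum"),
            observed_bycatch=("bycatch_count", "sum"),
        )
        .reset_index()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        g["bpue"] = np.where(
            g["observed_days"] > 0,
            g["observed_bycatch"] / g["observed_days"],
            np.nan,
        )
    if g["bpue"].isna().any():
        empty = g.loc[g["bpue"].isna(), STRATUM].to_records(index=False).tolist()
        warnings.warn(f"strata with zero observed days: {empty}", stacklevel=2)
    return g


def raise_to_fleet(
    bpue: pd.DataFrame,
    effort: pd.DataFrame,
    on_missing: str = "error",
) -> RaisedEstimate:
    """Total bycatch = sum over strata of BPUE x fleet fishing days.

    Fleet strata without a defined BPUE raise by default;
    ``on_missing="zero"`` treats them as zero-rate (logged loudly).
    """
    if on_missing not in ("error", "zero"):
        raise ValueError("on_missing must be 'error' or 'zero'")
    fleet = (
        effort.groupby(STRATUM, sort=True)
        .agg(fleet_days=("fishing_days", "sum"))
        .reset_index()
    )
    merged = fleet.merge(bpue[STRATUM + ["bpue"]], on=STRATUM, how="left")
    undefined = merged["bpue"].isna() & (merged["fleet_days"] > 0)
    if undefined.any():
        strata = merged.loc[undefined, STRATUM].to_records(index=False).tolist()
        if on_missing == "error":
            raise ValueError(
                f"fleet strata without an EM-observed BPUE: {strata}; "
                "pass on_missing='zero' to zero-fill"
            )
        logger.warning("zero-filling BPUE for unobserved strata: %s", strata)
        merged["bpue"] = merged["bpue"].fillna(0.0)
    merged["raised"] = merged["bpue"].fillna(0.0) * merged["fleet_days"]
    return RaisedEstimate(point=float(merged["raised"].sum()), per_stratum=merged)


def bootstrap_ci(
    em: pd.DataFrame,
    effort: pd.DataFrame,
    B: int = 100_000,
    seed: int = 0,
    block_by_vessel: bool = False,
    on_missing: str = "error",
    alpha: float = 0.05,
) -> RaisedEstimate:
    """Percentile bootstrap interval for the raised fleet total.

    Resamples EM rows (or whole vessels when ``block_by_vessel``) with
    replacement within each stratum, recomputes the stratum BPUE and the
    raised total ``B`` times, and reports the alpha/2 and 1-alpha/2
    percentiles.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    point_est = raise_to_fleet(compute_bpue(em), effort, on_missing=on_missing)
    fleet = point_est.per_stratum
    rng = np.random.default_rng(seed)

    totals = np.zeros(B)
    for _, row in fleet.iterrows():
        key = (row["quarter"], row["ices_area"])
        fleet_days = row["fleet_days"]
        if fleet_days == 0:
            continue
        sub = em[(em["quarter"] == key[0]) & (em["ices_area"] == key[1])]
        if len(sub) == 0:
            continue  # zero-filled stratum contributes nothing
        counts = sub["bycatch_count"].to_numpy(dtype=float)
        days = sub["fishing_days"].to_numpy(dtype=float)
        if len(sub) < 2:
            warnings.warn(
                f"stratum {key} has {len(sub)} EM row(s); resampling is "
                "degenerate there",
                stacklevel=2,
            )
        if block_by_vessel:
            vessels, v_idx = np.unique(
                sub["vessel_id"].to_numpy(), return_inverse=True
            )
            vc = np.vstack(
                [np.bincount(v_idx, weights=counts, minlength=len(vessels)),
                 np.bincount(v_idx, weights=days, minlength=len(vessels))]
            )
            idx = rng.integers(0, len(vessels), size=(B, len(vessels)))
            boot_counts = vc[0][idx].sum(axis=1)
            boot_days = vc[1][idx].sum(axis=1)
        else:
            m = len(sub)
            idx = rng.integers(0, m, size=(B, m))
            boot_counts = counts[idx].sum(axis=1)
            boot_days = days[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bpue_b = np.where(boot_days > 0, boot_counts / boot_days, 0.0)
        totals += bpue_b * fleet_days

    lo, hi = np.percentile(totals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return RaisedEstimate(
        point=point_est.point,
        per_stratum=fleet,
        ci_low=float(lo),
        ci_high=float(hi),
        n_bootstrap=B,
    )
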