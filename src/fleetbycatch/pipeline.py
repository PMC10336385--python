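"""End-to-end orchestration: data -> stratified estimate -> model
selection -> prediction/standardization -> removal limits.

A run is driven by a single config mapping (YAML on disk), works on
either synthetic data or user-supplied effort/EM CSVs, writes tidy CSV
and JSON outputs into one directory, and records every seed, the config
hash and convergence flags in a run manifest.  Input files are never
mutated; all randomness flows from named seeds in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, glmm, predict, stratified, sustainability, synthetic
from .effort import PingerRule, validate_effort_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "demo_config"]

#: Survey inputs for the Western Baltic removal limits: (year, density
#: individuals/km^2, CV) from the three dedicated abundance surveys.
DEFAULT_SURVEYS = [
    {"year": 2012, "density": 0.795, "cv": 0.24},
    {"year": 2016, "density": 1.04, "cv": 0.30},
    {"year": 2020, "density": 0.41, "cv": 0.20},
]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    outdir: str
    seed: int = 1
    sim: dict[str, Any] | None = None
    true_params: dict[str, Any] = field(default_factory=dict)
    effort_csv: str | None = None
    em_csv: str | None = None
    candidates: list[dict[str, Any]] = field(
        default_factory=lambda: [
            {"random_terms": ["year"], "spatial_grouping": "quarter_within_year"},
            {"random_terms": ["year"], "spatial_grouping": "none"},
        ]
    )
    stratified_B: int = 5000
    prediction_B: int = 0  # 0 -> delta-method SEs only
    stratified_on_missing: str = "error"
    pinger_rules: list[dict[str, Any]] = field(default_factory=list)
    surveys: list[dict[str, Any]] = field(
        default_factory=lambda: [dict(s) for s in DEFAULT_SURVEYS]
    )
    n_override: dict[int, int] = field(default_factory=lambda: {2012: 32136})

    def __post_init__(self) -> None:
        synthetic_in = self.sim is not None
        files_in = self.effort_csv is not None or self.em_csv is not None
        if synthetic_in == files_in:
            raise ConfigError(
                "exactly one of a 'sim' block or input CSV paths must be given"
            )
        if files_in and (self.effort_csv is None or self.em_csv is None):
            raise ConfigError("both effort_csv and em_csv are required")
        if not self.candidates:
            raise ConfigError("at least one candidate model is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        raw.setdefault("outdir", str(Path(path).with_suffix("")) + "_out")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "n_override" in raw and raw["n_override"]:
            raw["n_override"] = {int(k): int(v) for k, v in raw["n_override"].items()}
        return cls(**raw)

    def rules(self) -> list[PingerRule]:
        return [
            PingerRule(
                ices_areas=tuple(r.get("ices_areas", ())),
                vessel_classes=tuple(r.get("vessel_classes", ())),
                mesh_classes=tuple(r.get("mesh_classes", ())),
                quarters=tuple(r.get("quarters", ())),
            )
            for r in self.pinger_rules
        ]

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # where results land does not define the run
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def demo_config(outdir: str = "demo_out") -> RunConfig:
    """A small synthetic run that exercises every stage in seconds."""
    return RunConfig(
        outdir=outdir,
        seed=20101,
        sim={
            "n_vessels": 40,
            "years": [2017, 2018, 2019, 2020],
            "n_days_per_vessel_year": 25,
            "em_fraction": 0.3,
        },
        true_params={},
        candidates=[
            {"random_terms": ["year"], "spatial_grouping": "quarter_within_year"},
            {"random_terms": ["year"], "spatial_grouping": "none"},
        ],
        stratified_B=2000,
        stratified_on_missing="zero",
        pinger_rules=[
            {
                "ices_areas": ["IVb", "IIIa20"],
                "vessel_classes": ["12-15 m", ">15 m"],
            }
        ],
    )


def _spec_from_dict(d: dict[str, Any]) -> glmm.ModelSpec:
    kwargs: dict[str, Any] = {}
    if "fixed_terms" in d:
        kwargs["fixed_terms"] = tuple(d["fixed_terms"])
    if "random_terms" in d:
        kwargs["random_terms"] = tuple(d["random_terms"])
    if "spatial_grouping" in d:
        kwargs["spatial_grouping"] = d["spatial_grouping"]
    return glmm.ModelSpec(**kwargs)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "data"
    try:
        if config.sim is not None:
            sim_cfg = synthetic.SimConfig(seed=config.seed, **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in config.sim.items()
            })
            params = synthetic.TrueParams(**config.true_params)
            effort, em = synthetic.simulate_dataset(sim_cfg, params)
        else:
            effort = pd.read_csv(config.effort_csv)
            em = pd.read_csv(config.em_csv)
        validate_effort_table(effort)
        validate_effort_table(em, em=True)
        effort.to_csv(out / "effort.csv", index=False)
        em.to_csv(out / "em.csv", index=False)
        manifest["stages"][stage] = {
            "n_effort_rows": len(effort),
            "n_em_rows": len(em),
            "em_bycatch_total": int(em["bycatch_count"].sum()),
        }

        stage = "stratified"
        bpue = stratified.compute_bpue(em)
        bpue.to_csv(out / "bpue.csv", index=False)
        raised = stratified.bootstrap_ci(
            em,
            effort,
            B=config.stratified_B,
            seed=config.seed + 1,
            on_missing=config.stratified_on_missing,
        )
        raised.per_stratum.to_csv(out / "stratified_strata.csv", index=False)
        manifest["stages"][stage] = {
            "point": raised.point,
            "ci_low": raised.ci_low,
            "ci_high": raised.ci_high,
            "B": raised.n_bootstrap,
            "seed": config.seed + 1,
        }

        stage = "model_selection"
        candidates = [_spec_from_dict(d) for d in config.candidates]
        opts = glmm.FitOptions(
            seed=config.seed + 2, compute_param_cov=config.prediction_B > 0
        )
        ranking = glmm.select_model(em, candidates, opts)
        ranking.to_csv(out / "model_selection.csv", index=False)
        best_idx = int(ranking.loc[ranking["ok"]].iloc[0]["candidate"])
        best = ranking.attrs["fits"][best_idx]
        (out / "fit.json").write_text(best.to_json())
        manifest["stages"][stage] = {
            "best_candidate": best_idx,
            "aicc": best.aicc,
            "converged": bool(best.converged),
        }
        if not best.converged:
            logger.warning("selected model did not fully converge")

        stage = "residuals"
        resid = glmm.quantile_residuals(best, seed=config.seed + 3)
        manifest["stages"][stage] = {
            "ks_p": resid["ks_p"],
            "dispersion_ratio": resid["dispersion_ratio"],
            "dispersion_p": resid["dispersion_p"],
            "seed": config.seed + 3,
        }

        stage = "prediction"
        grouping = ["year", "ices_area"]
        rules = config.rules()
        scen = predict.pinger_scenarios(
            best, effort, rules, grouping=grouping, compute_se=True
        )
        if config.prediction_B > 0:
            ci_all = predict.bootstrap_prediction_ci(
                best, effort, grouping, B=config.prediction_B,
                seed=config.seed + 4,
            )
            scen = scen.merge(
                ci_all[grouping + ["ci_low", "ci_high"]], on=grouping, how="left"
            )
        scen.to_csv(out / "totals.csv", index=False)
        model_total = float(
            scen.loc[scen["scenario"] == "all_effort", "bias_corrected"].sum()
        )
        manifest["stages"][stage] = {
            "model_total_all_effort": model_total,
            "stratified_total": raised.point,
            "seed": config.seed + 4,
        }

        stage = "standardization"
        se_idx = predict.standardized_effort(best, effort)
        sb_idx = predict.standardized_bpue(best, effort)
        se_idx.to_csv(out / "standardized_effort.csv", index=False)
        sb_idx.to_csv(out / "standardized_bpue.csv", index=False)
        manifest["stages"][stage] = {
            "effort_constant": se_idx.attrs["frozen_constant"],
            "bpue_constant": sb_idx.attrs["frozen_constant"],
        }

        stage = "sustainability"
        estimates = [
            sustainability.AbundanceEstimate(
                year=int(s["year"]), density=float(s["density"]), cv=float(s["cv"])
            )
            for s in config.surveys
        ]
        pbr_tab = sustainability.removal_limits_table(
            estimates, n_override=config.n_override
        )
        pbr_tab.to_csv(out / "pbr.csv", index=False)

        wb = scen[
            (scen["scenario"] == "pinger_removed")
            & scen["ices_area"].isin(["IIIa21", "IIIc22", "IIIb23"])
        ]
        verdicts = []
        for year in sorted(set(pbr_tab["year"]) & set(wb["year"])):
            est = float(wb.loc[wb["year"] == year, "bias_corrected"].sum())
            row = pbr_tab[pbr_tab["year"] == year].iloc[0]
            limits = {
                (s, fr): int(row[f"{s}_Fr_{fr}"])
                for s, fr in sustainability.DEFAULT_FR_SCHEMES
            }
            v = sustainability.assess_sustainability(
                est, est, est, limits, year=year
            )
            verdicts.append(v)
        if verdicts:
            pd.concat(verdicts, ignore_index=True).to_csv(
                out / "assessment.csv", index=False
            )
        manifest["stages"][stage] = {"years": pbr_tab["year"].tolist()}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
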