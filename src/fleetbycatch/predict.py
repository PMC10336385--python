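"""Fleet-level prediction from a fitted bycatch model.

Natural-scale means per effort row, bias-corrected sums over strata,
parametric-bootstrap confidence intervals, standardized effort / BPUE
indices, and pinger-regulation scenario contrasts.

Because the expected total is a sum of exponentials of Gaussian random
effects, the plug-in sum exp(x'beta + z'u-hat) underestimates the
expectation; each row is corrected with half its Laplace-posterior
linear-predictor variance,

    T = sum_i exp(x_i'beta + z_i'u-hat + z_i'Q z_i / 2 + sigma_new^2 / 2),

where Q is the Gaussian posterior covariance of the random effects and
sigma_new^2 covers random-effect levels absent from the fitted data
(new vessels, years outside the fit, rectangles without a fitted field
value).  By convexity the corrected total is never below the plug-in
total.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from . import glmm
from .effort import filter_pinger_mandatory

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EFFORT_TERMS",
    "DEFAULT_PORPOISE_TERMS",
    "predict_mean",
    "aggregate_biascorrected",
    "bootstrap_prediction_ci",
    "link_scale_parts",
    "standardized_effort",
    "standardized_bpue",
    "pinger_scenarios",
]

#: Term grouping for standardization.  Effort-related terms describe how
#: the fishing operation filters porpoises out of the water column;
#: porpoise-related terms proxy local density.  Depth's placement is
#: debatable (it is both an operational choice and a habitat variable);
#: it defaults to the porpoise-density group.  The intercept is carried
#: in the effort part: only ratios of index values are meaningful, so a
#: constant's placement cancels.
DEFAULT_EFFORT_TERMS: tuple[str, ...] = (
    "intercept",
    "mesh_class",
    "vessel_class",
    "log_net_length",
    "log_soak_time",
    "mesh_class:log_soak_time",
)
DEFAULT_PORPOISE_TERMS: tuple[str, ...] = ("population", "log_depth")

#: Random terms in each group: vessel behaviour is effort-related; the
#: year intercept and the spatial field track porpoise availability.
_EFFORT_RANDOM = ("vessel_id",)
_PORPOISE_RANDOM = ("year", "spatial")


# ---------------------------------------------------------------------------
# mapping new data onto the fitted random-effect layout
# ---------------------------------------------------------------------------


class _NewDataMap:
    """Per-row random-effect coordinates for prediction data.

    ``coords`` is (n, m) with -1 marking levels unseen at fit time;
    ``var_new`` accumulates the prior variance of those unseen levels;
    ``comp_names`` labels each component column.
    """

    def __init__(self, fitted: glmm.FittedModel, newdata: pd.DataFrame):
        design = fitted.design
        n = len(newdata)
        cols, names, var_new = [], [], np.zeros(n)
        for t in design.re_terms:
            lookup = {lev: i for i, lev in enumerate(t.levels)}
            idx = np.array(
                [lookup.get(v, -1) for v in newdata[t.name].to_numpy()]
            )
            unseen = idx < 0
            var_new[unseen] += fitted.sd[t.name] ** 2
            cols.append(np.where(unseen, -1, t.offset + idx))
            names.append(t.name)
        self.spatial_rows: dict[int, np.ndarray] = {}
        if design.spatial is not None:
            sp = design.spatial
            keys = glmm._spatial_key(newdata, sp.grouping)
            key_index = {k: i for i, k in enumerate(sp.group_keys)}
            lonlat = newdata[["lon", "lat"]].to_numpy(dtype=float)
            idx = np.full(n, -1)
            row_group = np.full(n, -1)
            row_pos = np.full(n, -1)
            for i, k in enumerate(keys):
                gi = key_index.get(k)
                if gi is None:
                    continue
                pos = sp.positions[gi]
                match = np.flatnonzero(
                    (pos[:, 0] == lonlat[i, 0]) & (pos[:, 1] == lonlat[i, 1])
                )
                if len(match):
                    idx[i] = sp.offsets[gi] + match[0]
                    row_group[i] = gi
                    row_pos[i] = match[0]
            var_new[idx < 0] += (fitted.sigma_s or 0.0) ** 2
            cols.append(idx)
            names.append("spatial")
            self.row_group = row_group
            self.row_pos = row_pos
        self.coords = (
            np.column_stack(cols) if cols else np.empty((n, 0), dtype=int)
        )
        self.comp_names = names
        self.var_new = var_new
        self.n = n

    def any_unseen(self) -> bool:
        return bool((self.coords < 0).any()) if self.coords.size else False

    def u_contribution(self, u: np.ndarray) -> np.ndarray:
        """Sum of random effects over known components (unseen -> 0)."""
        if not self.coords.size:
            return np.zeros(self.n)
        safe = np.maximum(self.coords, 0)
        vals = u[safe]
        vals[self.coords < 0] = 0.0
        return vals.sum(axis=1)

    def quad_form(self, Q: np.ndarray) -> np.ndarray:
        """z_i' Q z_i over known coordinates, per row."""
        m = self.coords.shape[1]
        out = np.zeros(self.n)
        for a in range(m):
            for b in range(m):
                ca, cb = self.coords[:, a], self.coords[:, b]
                ok = (ca >= 0) & (cb >= 0)
                if ok.any():
                    out[ok] += Q[ca[ok], cb[ok]]
        return out


def _fixed_eta(fitted: glmm.FittedModel, newdata: pd.DataFrame) -> np.ndarray:
    X, names = glmm.build_fixed_design(newdata, fitted.spec.fixed_terms)
    if names != fitted.colnames:
        raise ValueError(
            "prediction design columns do not match the fitted model: "
            f"{names} vs {fitted.colnames}"
        )
    return fitted.transform_X(X) @ fitted.beta


def predict_mean(
    fitted: glmm.FittedModel,
    newdata: pd.DataFrame,
    re_mode: str = "conditional",
) -> np.ndarray:
    """Natural-scale mean per row.

    ``conditional`` uses the estimated random effects and requires every
    random-effect level to have been seen at fit time; ``marginal``
    additionally averages over unseen levels, adding half their prior
    variance on the link scale (the log-normal mean).
    """
    if re_mode not in ("conditional", "marginal"):
        raise ValueError("re_mode must be 'conditional' or 'marginal'")
    eta = _fixed_eta(fitted, newdata)
    mapping = _NewDataMap(fitted, newdata)
    if mapping.any_unseen() and re_mode == "conditional":
        raise ValueError(
            "newdata contains random-effect levels unseen at fit time; "
            "use re_mode='marginal'"
        )
    eta = eta + mapping.u_contribution(fitted.u_hat)
    if re_mode == "marginal":
        eta = eta + 0.5 * mapping.var_new
    return np.exp(eta)


# ---------------------------------------------------------------------------
# bias-corrected aggregation
# ---------------------------------------------------------------------------


def _delta_se(
    fitted: glmm.FittedModel,
    newdata: pd.DataFrame,
    mapping: _NewDataMap,
    m_rows: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
) -> np.ndarray:
    """Delta-method SEs of group totals over the joint (beta, v)
    Gaussian approximation; variance parameters held fixed."""
    design = fitted.design
    X, _ = glmm.build_fixed_design(newdata, fitted.spec.fixed_terms)
    X = fitted.transform_X(X)
    p, q = X.shape[1], design.q
    C = fitted.joint_cov()
    ses = np.zeros(n_groups)
    ev = fitted._evaluator
    post_blocks = ev._blocks(
        [fitted.sd[t.name] for t in design.re_terms],
        fitted.sigma_s,
        fitted.rho,
    )
    for g in range(n_groups):
        rows = np.flatnonzero(group_idx == g)
        m = m_rows[rows]
        grad = np.zeros(p + q)
        grad[:p] = X[rows].T @ m
        gv = np.zeros(q)
        for j, name in enumerate(mapping.comp_names):
            cj = mapping.coords[rows, j]
            ok = cj >= 0
            if not ok.any():
                continue
            if name == "spatial":
                sp = design.spatial
                rg = mapping.row_group[rows]
                for gi in np.unique(rg[ok]):
                    sel = ok & (rg == gi)
                    w = np.bincount(
                        mapping.row_pos[rows][sel],
                        weights=m[sel],
                        minlength=len(sp.positions[gi]),
                    )
                    sl, f = post_blocks[len(design.re_terms) + gi]
                    gv[sl] += f.T @ w
            else:
                t = design.re_terms[j]
                gv_part = np.bincount(
                    cj[ok] - t.offset, weights=m[ok], minlength=t.size
                )
                gv[t.offset : t.offset + t.size] += fitted.sd[t.name] * gv_part
        grad[p:] = gv
        ses[g] = float(np.sqrt(max(grad @ C @ grad, 0.0)))
    return ses


def aggregate_biascorrected(
    fitted: glmm.FittedModel,
    newdata: pd.DataFrame,
    grouping: Sequence[str],
    scenario: str = "all_effort",
    compute_se: bool = True,
) -> pd.DataFrame:
    """Bias-corrected expected bycatch totals per group.

    Returns one row per group with ``plugin`` (sum of conditional
    means), ``bias_corrected`` (posterior-variance corrected sum, the
    reporting value), and a delta-method ``se``.
    """
    grouping = list(grouping)
    eta = _fixed_eta(fitted, newdata)
    mapping = _NewDataMap(fitted, newdata)
    eta = eta + mapping.u_contribution(fitted.u_hat)
    quad = (
        mapping.quad_form(fitted.Q) if fitted.design.q else np.zeros(len(newdata))
    )
    plugin_rows = np.exp(eta)
    corrected_rows = np.exp(eta + 0.5 * quad + 0.5 * mapping.var_new)

    keys, group_idx = np.unique(
        newdata[grouping].astype(str).agg("|".join, axis=1), return_inverse=True
    )
    tab = (
        newdata[grouping]
        .assign(_g=group_idx, plugin=plugin_rows, bias_corrected=corrected_rows)
        .groupby(grouping, sort=True)
        .agg(
            _g=("_g", "first"),
            plugin=("plugin", "sum"),
            bias_corrected=("bias_corrected", "sum"),
        )
        .reset_index()
    )
    if compute_se and fitted.design.q:
        ses = _delta_se(
            fitted, newdata, mapping, corrected_rows, group_idx, len(keys)
        )
        tab["se"] = ses[tab["_g"].to_numpy()]
    else:
        tab["se"] = 0.0
    tab = tab.drop(columns="_g")
    tab["scenario"] = scenario
    return tab


def bootstrap_prediction_ci(
    fitted: glmm.FittedModel,
    newdata: pd.DataFrame,
    grouping: Sequence[str],
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    scenario: str = "all_effort",
    chunk: int = 200,
) -> pd.DataFrame:
    """Parametric-bootstrap percentile intervals for group totals.

    Draws B parameter vectors from the Gaussian approximation to the
    sampling distribution of (beta, log-dispersion, log-variance
    parameters), combines each with a conditional random-effect draw
    from the Laplace posterior (unseen levels drawn from their prior at
    the sampled variances), and recomputes the total per draw.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if fitted.param_cov is None:
        raise ValueError(
            "fitted model lacks a parameter covariance; refit with "
            "FitOptions(compute_param_cov=True)"
        )
    grouping = list(grouping)
    design = fitted.design
    X, names = glmm.build_fixed_design(newdata, fitted.spec.fixed_terms)
    if names != fitted.colnames:
        raise ValueError("prediction design does not match the fitted model")
    X = fitted.transform_X(X)
    mapping = _NewDataMap(fitted, newdata)
    rng = np.random.default_rng(seed)

    cov = np.asarray(fitted.param_cov)
    try:
        Lp = cholesky(cov + 1e-12 * np.eye(len(cov)), lower=True)
    except np.linalg.LinAlgError:
        logger.warning("parameter covariance not PD; adding jitter")
        w, V = np.linalg.eigh(cov)
        Lp = V @ np.diag(np.sqrt(np.maximum(w, 1e-10)))
    q = design.q
    Lv = None
    if q:
        try:
            Lv = cholesky(fitted.cov_v + 1e-10 * np.eye(q), lower=True)
        except np.linalg.LinAlgError:
            logger.warning("posterior covariance not PD; adding jitter")
            w, V = np.linalg.eigh(fitted.cov_v)
            Lv = V @ np.diag(np.sqrt(np.maximum(w, 1e-10)))

    keys, group_idx = np.unique(
        newdata[grouping].astype(str).agg("|".join, axis=1), return_inverse=True
    )
    G = len(keys)
    totals = np.zeros((G, B))
    ev = fitted._evaluator
    p = len(fitted.beta)
    n = len(newdata)

    blocks = (
        ev._blocks(
            [fitted.sd[t.name] for t in design.re_terms],
            fitted.sigma_s,
            fitted.rho,
        )
        if q
        else None
    )
    done = 0
    while done < B:
        b = min(chunk, B - done)
        phi = fitted.params_vec[:, None] + Lp @ rng.standard_normal((len(cov), b))
        eta = X @ phi[:p, :]  # (n, b)
        if q:
            v_draw = fitted.v_hat[:, None] + Lv @ rng.standard_normal((q, b))
        for k in range(b):
            _, _, sds_k, sig_s_k, _ = ev.unpack(phi[:, k])
            eta_k = eta[:, k].copy()
            if q:
                u_k = ev._L_vec(blocks, v_draw[:, k])
                safe = np.maximum(mapping.coords, 0)
                vals = u_k[safe]
                vals[mapping.coords < 0] = 0.0
                eta_k += vals.sum(axis=1)
            # unseen levels: fresh draws from the prior at sampled variances
            for j, name in enumerate(mapping.comp_names):
                unseen = mapping.coords[:, j] < 0
                if not unseen.any():
                    continue
                sd_new = (
                    sig_s_k
                    if name == "spatial"
                    else sds_k[[t.name for t in design.re_terms].index(name)]
                )
                if name == "spatial":
                    eta_k[unseen] += sd_new * rng.standard_normal(int(unseen.sum()))
                else:
                    levels, lev_idx = np.unique(
                        newdata.loc[unseen, name].to_numpy(), return_inverse=True
                    )
                    draws = sd_new * rng.standard_normal(len(levels))
                    eta_k[unseen] += draws[lev_idx]
            mu_k = np.exp(np.clip(eta_k, -700, 700))
            totals[:, done + k] = np.bincount(group_idx, weights=mu_k, minlength=G)
        done += b

    lo, hi = np.percentile(totals, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=1)
    base = aggregate_biascorrected(
        fitted, newdata, grouping, scenario=scenario, compute_se=False
    )
    order = {k: i for i, k in enumerate(keys)}
    base_keys = base[grouping].astype(str).agg("|".join, axis=1).map(order).to_numpy()
    base["ci_low"] = lo[base_keys]
    base["ci_high"] = hi[base_keys]
    base["n_bootstrap"] = B
    return base


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def _column_term(colname: str) -> str:
    if colname == "intercept":
        return "intercept"
    if ":" in colname:
        base = colname.split("[")[0]
        cont = colname.split(":")[1]
        return f"{base}:{cont}"
    return colname.split("[")[0]


def link_scale_parts(
    fitted: glmm.FittedModel,
    newdata: pd.DataFrame,
    effort_terms: Sequence[str] = DEFAULT_EFFORT_TERMS,
    porpoise_terms: Sequence[str] = DEFAULT_PORPOISE_TERMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Split each row's link-scale prediction into its effort-related
    and porpoise-density-related parts (their sum is the full linear
    predictor; unseen random-effect levels contribute zero).

    The split works on the raw treatment-coded columns with the
    back-transformed coefficients: the orthonormalized fitting basis
    mixes terms and cannot be partitioned."""
    X, names = glmm.build_fixed_design(newdata, fitted.spec.fixed_terms)
    beta = fitted.coef_vector
    effort_terms, porpoise_terms = set(effort_terms), set(porpoise_terms)
    both = effort_terms & porpoise_terms
    if both:
        raise ValueError(f"terms in both groups: {sorted(both)}")
    uncovered = {
        _column_term(c) for c in names
    } - effort_terms - porpoise_terms
    if uncovered:
        raise ValueError(f"fixed terms not assigned to a group: {sorted(uncovered)}")
    in_effort = np.array([_column_term(c) in effort_terms for c in names])
    eta_e = X[:, in_effort] @ beta[in_effort]
    eta_p = X[:, ~in_effort] @ beta[~in_effort]

    mapping = _NewDataMap(fitted, newdata)
    u = fitted.u_hat
    for j, name in enumerate(mapping.comp_names):
        cj = mapping.coords[:, j]
        ok = cj >= 0
        contrib = np.where(ok, u[np.maximum(cj, 0)], 0.0)
        if name in _EFFORT_RANDOM:
            eta_e = eta_e + contrib
        else:  # year intercept and spatial field track porpoise density
            eta_p = eta_p + contrib
    return eta_e, eta_p


def standardized_effort(
    fitted: glmm.FittedModel,
    effort: pd.DataFrame,
    constants: float | None = None,
    by: Sequence[str] = ("year",),
    effort_terms: Sequence[str] = DEFAULT_EFFORT_TERMS,
    porpoise_terms: Sequence[str] = DEFAULT_PORPOISE_TERMS,
) -> pd.DataFrame:
    """Relative index of effort-driven bycatch pressure.

    All porpoise-density terms are frozen at a constant (default: the
    median of their link-scale values over ``effort``) and predictions
    are summed per axis.  Only ratios between index values carry
    information.
    """
    eta_e, eta_p = link_scale_parts(fitted, effort, effort_terms, porpoise_terms)
    c = float(np.median(eta_p)) if constants is None else float(constants)
    vals = np.exp(eta_e + c)
    out = (
        effort[list(by)]
        .assign(value=vals)
        .groupby(list(by), sort=True)["value"]
        .sum()
        .reset_index()
    )
    out["kind"] = "standardized_effort"
    out.attrs["frozen_constant"] = c
    return out


def standardized_bpue(
    fitted: glmm.FittedModel,
    grid: pd.DataFrame,
    constants: float | None = None,
    by: Sequence[str] = ("year", "rectangle_code"),
    effort_terms: Sequence[str] = DEFAULT_EFFORT_TERMS,
    porpoise_terms: Sequence[str] = DEFAULT_PORPOISE_TERMS,
) -> pd.DataFrame:
    """Relative porpoise-density index over space/time: the mirror image
    of :func:`standardized_effort`, freezing the effort-related terms."""
    eta_e, eta_p = link_scale_parts(fitted, grid, effort_terms, porpoise_terms)
    c = float(np.median(eta_e)) if constants is None else float(constants)
    vals = np.exp(c + eta_p)
    out = (
        grid[list(by)]
        .assign(value=vals)
        .groupby(list(by), sort=True)["value"]
        .sum()
        .reset_index()
    )
    out["kind"] = "standardized_bpue"
    out.attrs["frozen_constant"] = c
    return out


# ---------------------------------------------------------------------------
# pinger scenarios
# ---------------------------------------------------------------------------


def pinger_scenarios(
    fitted: glmm.FittedModel,
    effort: pd.DataFrame,
    rules,
    grouping: Sequence[str] = ("year", "ices_area"),
    compute_se: bool = False,
) -> pd.DataFrame:
    """Paired totals: all effort vs effort with mandatory-pinger rows
    removed (full compliance, 100% effective deterrents).

    The removed-effort scenario can never exceed the all-effort scenario
    in any group; groups whose rows are all removed appear with zero.
    """
    grouping = list(grouping)
    all_eff = aggregate_biascorrected(
        fitted, effort, grouping, scenario="all_effort", compute_se=compute_se
    )
    kept = filter_pinger_mandatory(effort, rules)
    if len(kept):
        removed = aggregate_biascorrected(
            fitted, kept, grouping, scenario="pinger_removed",
            compute_se=compute_se,
        )
    else:
        removed = all_eff.iloc[0:0].copy()
    removed = (
        all_eff[grouping]
        .merge(removed, on=grouping, how="left")
        .fillna({"plugin": 0.0, "bias_corrected": 0.0, "se": 0.0})
    )
    removed["scenario"] = "pinger_removed"
    return pd.concat([all_eff, removed], ignore_index=True)
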