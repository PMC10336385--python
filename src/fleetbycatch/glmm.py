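"""Spatially correlated negative-binomial mixed model for bycatch counts.

The response is the number of porpoises bycaught per vessel-day-rectangle,
modelled as NB2 (variance mu + mu^2/theta) on a log link with

* fixed effects: mesh-size class, vessel-length class, porpoise
  population, log net-length, log soak-time, log depth, and the
  mesh-class x log-soak-time interaction (treatment coding against
  documented reference levels);
* iid Gaussian random intercepts for vessel and/or year;
* zero-mean Gaussian spatial fields with exponential covariance
  sigma_s^2 * exp(-d/rho) (great-circle km between rectangle centroids),
  drawn independently per grouping (none, year, quarter, or
  quarter-within-year) with shared (sigma_s, rho).

The marginal likelihood integrates the latent effects out with a Laplace
approximation: latent vectors are parameterized as u = L(phi) v with
v ~ N(0, I), the conditional mode v-hat is found by damped Newton
iterations (the conditional Hessian I + L'Z'WZL is always positive
definite because the NB2 working weights are non-negative), and

    log L(beta, phi) ~= loglik(y | u-hat) - v-hat'v-hat / 2
                        - log det(I + L'Z'WZL) / 2.

This reduces exactly to the fixed-effects NB likelihood when all
variance components are zero.  The outer optimization is bounded
quasi-Newton (L-BFGS-B) over beta and log-scale dispersion / variance /
range parameters with finite-difference gradients.

A Gaussian response family is also provided; for it the Laplace
approximation is exact, which gives an analytically checkable special
case (the closed-form linear-mixed-model marginal likelihood).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .effort import haversine_km

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FittedModel",
    "FitOptions",
    "REFERENCE_LEVELS",
    "CATEGORY_LEVELS",
    "build_fixed_design",
    "build_design",
    "nb2_loglik",
    "laplace_nll",
    "fit",
    "aicc",
    "select_model",
    "simulate_response",
    "quantile_residuals",
]

# Canonical factor levels; first level of each is the treatment-coding
# reference ("<120 mm", "<8 m", "North Sea Population").
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "mesh_class": ("<120 mm", "120-200", ">200 mm"),
    "vessel_class": ("<8 m", "8-10 m", "10-12 m", "12-15 m", ">15 m"),
    "population": ("North Sea Population", "Western Baltic Population"),
}
REFERENCE_LEVELS = {k: v[0] for k, v in CATEGORY_LEVELS.items()}

_LOG_TERMS = {
    "log_net_length": "net_length_m",
    "log_soak_time": "soak_time_h",
    "log_depth": "depth_m",
}

DEFAULT_FIXED_TERMS: tuple[str, ...] = (
    "mesh_class",
    "vessel_class",
    "population",
    "log_net_length",
    "log_soak_time",
    "log_depth",
    "mesh_class:log_soak_time",
)

_SPATIAL_GROUPINGS = ("none", "year", "quarter", "quarter_within_year")

#: Diagonal jitter added to exponential correlation matrices before
#: Cholesky factorization.
SPATIAL_JITTER = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the model.

    ``random_terms`` may contain ``"vessel_id"`` and/or ``"year"`` (iid
    intercepts); ``spatial_grouping`` selects how many independent
    spatial fields are drawn.  The default structure is the year
    intercept plus quarter-within-year spatial fields.
    """

    fixed_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    random_terms: tuple[str, ...] = ("year",)
    spatial_grouping: str = "quarter_within_year"
    family: str = "nb2"

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ValueError(
                        f"interaction {t!r} requires both main effects"
                    )
            elif t not in CATEGORY_LEVELS and t not in _LOG_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random_terms:
            if t not in ("vessel_id", "year"):
                raise ValueError(f"unknown random term {t!r}")
        if self.spatial_grouping not in _SPATIAL_GROUPINGS:
            raise ValueError(
                f"spatial_grouping must be one of {_SPATIAL_GROUPINGS}"
            )
        if self.family not in ("nb2", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_fixed_design(
    df: pd.DataFrame,
    fixed_terms: Sequence[str] = DEFAULT_FIXED_TERMS,
    check_rank: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects matrix with treatment coding and log transforms.

    Returns ``(X, column_names)``; the first column is the intercept.
    Unseen factor levels and non-positive logged covariates raise.
    ``check_rank`` rejects rank-deficient matrices (required when
    fitting; irrelevant when computing predictions for a few rows).
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    def contrast_cols(term: str) -> list[tuple[str, np.ndarray]]:
        levels = CATEGORY_LEVELS[term]
        observed = set(df[term].unique())
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"unseen {term} level(s): {sorted(unknown)}")
        return [
            (f"{term}[{lev}]", (df[term] == lev).to_numpy(dtype=float))
            for lev in levels[1:]
        ]

    def log_col(term: str) -> np.ndarray:
        raw = df[_LOG_TERMS[term]].to_numpy(dtype=float)
        if not np.all(np.isfinite(raw) & (raw > 0)):
            bad = np.flatnonzero(~(np.isfinite(raw) & (raw > 0)))[:5]
            raise ValueError(
                f"{_LOG_TERMS[term]} must be positive to enter as a log "
                f"(first offending rows: {bad.tolist()})"
            )
        return np.log(raw)

    for term in fixed_terms:
        if ":" in term:
            a, b = term.split(":")
            # categorical x continuous is the only interaction shape used
            for cname, cvals in contrast_cols(a):
                cols.append(cvals * log_col(b))
                names.append(f"{cname}:{b}")
        elif term in CATEGORY_LEVELS:
            for cname, cvals in contrast_cols(term):
                cols.append(cvals)
                names.append(cname)
        else:
            cols.append(log_col(term))
            names.append(term)

    X = np.column_stack(cols)
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design matrix is rank deficient")
    return X, names


@dataclass
class _RETerm:
    name: str
    levels: np.ndarray  # level labels, sorted
    row_idx: np.ndarray  # (n,) level index per row
    offset: int = 0  # filled by layout

    @property
    def size(self) -> int:
        return len(self.levels)


@dataclass
class _SpatialStructure:
    grouping: str
    group_keys: list[Any]
    positions: list[np.ndarray]  # per group, (k_g, 2) lon/lat
    dist: list[np.ndarray]  # per group, (k_g, k_g) km
    row_group: np.ndarray  # (n,)
    row_pos: np.ndarray  # (n,) position index within group
    offsets: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(len(p) for p in self.positions)


@dataclass
class DesignMatrices:
    """All matrices/indices needed to evaluate the marginal likelihood."""

    X: np.ndarray
    colnames: list[str]
    y: np.ndarray
    re_terms: list[_RETerm]
    spatial: _SpatialStructure | None
    spec: ModelSpec

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def q(self) -> int:
        q = sum(t.size for t in self.re_terms)
        if self.spatial is not None:
            q += self.spatial.size
        return q

    def row_coords(self) -> np.ndarray:
        """(n, m) global random-effect coordinate per active component."""
        cols = []
        for t in self.re_terms:
            cols.append(t.offset + t.row_idx)
        if self.spatial is not None:
            sp = self.spatial
            off = np.asarray(sp.offsets)[sp.row_group]
            cols.append(off + sp.row_pos)
        if not cols:
            return np.empty((self.n, 0), dtype=int)
        return np.column_stack(cols)


def _spatial_key(df: pd.DataFrame, grouping: str):
    if grouping == "year":
        return list(zip(df["year"].to_numpy()))
    if grouping == "quarter":
        return list(zip(df["quarter"].to_numpy()))
    return list(zip(df["year"].to_numpy(), df["quarter"].to_numpy()))


def build_design(
    em: pd.DataFrame, spec: ModelSpec, response: str = "bycatch_count"
) -> DesignMatrices:
    """Assemble design matrices from a harmonized EM table."""
    X, names = build_fixed_design(em, spec.fixed_terms, check_rank=True)
    if spec.family == "nb2":
        y = em[response].to_numpy(dtype=float)
        if not np.all((y >= 0) & (y == np.round(y))):
            raise ValueError(f"{response} must be non-negative integer counts")
    else:
        y = em[response].to_numpy(dtype=float)

    re_terms = []
    offset = 0
    for name in spec.random_terms:
        labels, idx = np.unique(em[name].to_numpy(), return_inverse=True)
        term = _RETerm(name=name, levels=labels, row_idx=idx, offset=offset)
        re_terms.append(term)
        offset += term.size

    spatial = None
    if spec.spatial_grouping != "none":
        keys = _spatial_key(em, spec.spatial_grouping)
        uniq_keys = sorted(set(keys))
        key_index = {k: i for i, k in enumerate(uniq_keys)}
        row_group = np.array([key_index[k] for k in keys])
        lonlat = em[["lon", "lat"]].to_numpy(dtype=float)
        positions, dists, offsets = [], [], []
        row_pos = np.zeros(len(em), dtype=int)
        for gi in range(len(uniq_keys)):
            mask = row_group == gi
            pos, inv = np.unique(lonlat[mask], axis=0, return_inverse=True)
            positions.append(pos)
            dists.append(haversine_km(pos))
            row_pos[mask] = inv
            offsets.append(offset)
            offset += len(pos)
        spatial = _SpatialStructure(
            grouping=spec.spatial_grouping,
            group_keys=uniq_keys,
            positions=positions,
            dist=dists,
            row_group=row_group,
            row_pos=row_pos,
            offsets=offsets,
        )
    return DesignMatrices(
        X=X, colnames=names, y=y, re_terms=re_terms, spatial=spatial, spec=spec
    )


# ---------------------------------------------------------------------------
# response families
# ---------------------------------------------------------------------------


def nb2_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Sum of NB2 log-probabilities, Var(y) = mu + mu^2/theta."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be positive and finite")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must be non-negative integers")
    return float(np.sum(_nb2_logpmf(y, mu, theta)))


def _nb2_logpmf(y, mu, theta):
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


class _NB2:
    """Log-density and eta-derivatives for the NB2 family (eta = log mu)."""

    n_disp = 1  # one dispersion parameter: log theta

    @staticmethod
    def loglik(y, eta, theta):
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            mu = np.exp(eta)
            return float(np.sum(_nb2_logpmf(y, mu, theta)))

    @staticmethod
    def score(y, eta, theta):
        with np.errstate(over="ignore", invalid="ignore"):
            mu = np.exp(eta)
            r = y - (y + theta) * mu / (mu + theta)
        return np.where(np.isfinite(r), r, y - (y + theta))

    @staticmethod
    def weights(y, eta, theta):
        with np.errstate(over="ignore", invalid="ignore"):
            mu = np.exp(eta)
            w = (y + theta) * theta * mu / (mu + theta) ** 2
        return np.where(np.isfinite(w), w, 0.0)


class _Gaussian:
    """Gaussian response with identity link; Laplace is exact here."""

    n_disp = 1  # log residual SD

    @staticmethod
    def loglik(y, eta, sigma):
        return float(
            -0.5 * np.sum(((y - eta) / sigma) ** 2)
            - len(y) * (np.log(sigma) + 0.5 * np.log(2.0 * np.pi))
        )

    @staticmethod
    def score(y, eta, sigma):
        return (y - eta) / sigma**2

    @staticmethod
    def weights(y, eta, sigma):
        return np.full(len(y), 1.0 / sigma**2)


_FAMILIES = {"nb2": _NB2, "gaussian": _Gaussian}


# ---------------------------------------------------------------------------
# Laplace-approximated marginal likelihood
# ---------------------------------------------------------------------------


class _HFactor:
    """Cholesky factorization of H = I + L'Z'WZ L in block form.

    With iid intercept coordinates first and spatial-field coordinates
    after, the spatial part of Z'WZ is diagonal (a row loads exactly one
    field value), so H has one dense block per spatial group, a small
    dense iid block, and their coupling.  Factorization cost is a sum of
    per-group Cholesky factors plus a Schur complement the size of the
    iid block, instead of one dense q x q factorization; same-size
    groups are factorized in one batched numpy call.
    """

    def __init__(self, ev: "_LaplaceEvaluator", w: np.ndarray,
                 scale_f: np.ndarray, sp_stacks):
        qf, qs = ev.qf, ev.qs
        self.qf, self.qs = qf, qs
        self.q = qf + qs
        logdet = 0.0

        if qf:
            Mff = np.bincount(
                ev._ff_idx,
                weights=np.tile(w, ev.m_iid * ev.m_iid),
                minlength=qf * qf,
            ).reshape(qf, qf)
            Hff = Mff * np.outer(scale_f, scale_f)
            Hff[np.diag_indices(qf)] += 1.0
        else:
            Hff = np.zeros((0, 0))

        # per size class: (coords (G,b), chol factors (G,b,b), Y (G,b,qf))
        self.classes: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        if qs:
            dss = np.bincount(ev.sp_col, weights=w, minlength=qs)
            Msf = (
                np.bincount(
                    ev._sf_idx, weights=np.tile(w, ev.m_iid),
                    minlength=qs * qf,
                ).reshape(qs, qf)
                if qf
                else np.zeros((qs, 0))
            )
            for (b, gidx, coords), Lstack in sp_stacks:
                dg = dss[coords]  # (G, b)
                Ag = np.einsum("gji,gj,gjk->gik", Lstack, dg, Lstack,
                               optimize=True)
                Ag[:, np.arange(b), np.arange(b)] += 1.0
                Pg = np.linalg.cholesky(Ag)
                logdet += 2.0 * float(
                    np.sum(np.log(Pg[:, np.arange(b), np.arange(b)]))
                )
                if qf:
                    Bg = np.einsum(
                        "gji,gjk->gik", Lstack,
                        Msf[coords] * scale_f[None, None, :],
                    )
                    Yg = np.linalg.solve(Pg, Bg)  # (G, b, qf)
                    Hff = Hff - np.einsum("gij,gik->jk", Yg, Yg)
                else:
                    Yg = np.zeros((len(gidx), b, 0))
                self.classes.append((coords, Pg, Yg))
        if qf:
            self.Pf = np.linalg.cholesky(Hff)
            logdet += 2.0 * float(np.sum(np.log(np.diag(self.Pf))))
        else:
            self.Pf = None
        self.logdet = logdet

    def solve(self, r: np.ndarray) -> np.ndarray:
        """Solve H x = r for a vector or matrix right-hand side."""
        r = np.asarray(r, dtype=float)
        vec = r.ndim == 1
        R = r[:, None] if vec else r
        qf = self.qf
        rf = R[:qf].copy()
        rs = R[qf:]
        ts = []
        for coords, Pg, Yg in self.classes:
            t = np.linalg.solve(Pg, rs[coords])  # (G, b, k)
            ts.append(t)
            if qf:
                rf -= np.einsum("gij,gik->jk", Yg, t)
        if qf:
            xf = solve_triangular(
                self.Pf.T,
                solve_triangular(self.Pf, rf, lower=True, check_finite=False),
                lower=False,
                check_finite=False,
            )
        else:
            xf = rf
        xs = np.zeros_like(rs)
        for (coords, Pg, Yg), t in zip(self.classes, ts):
            z = t - (Yg @ xf if qf else 0.0)
            xs[coords] = np.linalg.solve(np.swapaxes(Pg, 1, 2), z)
        x = np.vstack([xf, xs])
        return x[:, 0] if vec else x


class _LaplaceEvaluator:
    """Evaluates the negative Laplace marginal log-likelihood.

    Parameter vector layout: [beta (p), log dispersion, log sd per iid
    random term, (log sigma_s, log rho) if spatial].  Caches the
    per-group correlation Cholesky factors by rho and warm-starts the
    inner Newton solve between calls.
    """

    def __init__(self, design: DesignMatrices, inner_tol: float = 1e-11,
                 max_inner: int = 100):
        self.design = design
        self.family = _FAMILIES[design.spec.family]
        self.inner_tol = inner_tol
        self.max_inner = max_inner
        self.coords = design.row_coords()
        self.q = design.q
        self.p = design.X.shape[1]
        self._v = np.zeros(self.q)
        self._rho_cache: tuple[float, list[np.ndarray]] | None = None
        self.param_names = self._param_names()
        self._setup_structure()

    def _setup_structure(self) -> None:
        """Index arrays for the block-structured conditional Hessian.

        Global random-effect layout: iid intercept coordinates first
        ([0, qf)), then the spatial-field coordinates group by group.
        Each data row loads at most one coordinate per component, so
        Z'WZ restricted to the spatial block is diagonal; all density
        lives in small per-group blocks plus the iid coupling.
        """
        design = self.design
        self.qf = sum(t.size for t in design.re_terms)
        self.qs = self.q - self.qf
        m_iid = len(design.re_terms)
        self.m_iid = m_iid
        self.iid_cols = self.coords[:, :m_iid] if m_iid else None
        self.sp_col = (
            self.coords[:, m_iid] - self.qf
            if design.spatial is not None
            else None
        )
        qf = self.qf
        self._ff_idx = self._sf_idx = None
        if qf and m_iid:
            self._ff_idx = np.concatenate(
                [
                    self.iid_cols[:, j] * qf + self.iid_cols[:, k]
                    for j in range(m_iid)
                    for k in range(m_iid)
                ]
            )
        if design.spatial is not None and qf:
            self._sf_idx = np.concatenate(
                [self.sp_col * qf + self.iid_cols[:, j] for j in range(m_iid)]
            )
        if design.spatial is not None:
            offs = [o - qf for o in design.spatial.offsets]
            sizes = [len(p) for p in design.spatial.positions]
            self.sp_slices = [
                slice(o, o + s) for o, s in zip(offs, sizes)
            ]
            # same-size groups are batched through numpy's stacked linalg
            by_size: dict[int, list[int]] = {}
            for gi, b in enumerate(sizes):
                by_size.setdefault(b, []).append(gi)
            self.sp_size_classes = [
                (
                    b,
                    np.asarray(gis),
                    np.stack(
                        [offs[gi] + np.arange(b) for gi in gis]
                    ),  # (G_b, b) local spatial coords
                )
                for b, gis in sorted(by_size.items())
            ]
        else:
            self.sp_slices = []
            self.sp_size_classes = []

    def _param_names(self) -> list[str]:
        names = list(self.design.colnames)
        names.append("log_theta" if self.design.spec.family == "nb2"
                     else "log_sigma_resid")
        for t in self.design.re_terms:
            names.append(f"log_sd_{t.name}")
        if self.design.spatial is not None:
            names += ["log_sigma_s", "log_rho"]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def unpack(self, params: np.ndarray):
        p = self.p
        beta = params[:p]
        disp = float(np.exp(params[p]))
        k = p + 1
        sds = []
        for _ in self.design.re_terms:
            sds.append(float(np.exp(params[k])))
            k += 1
        sigma_s = rho = None
        if self.design.spatial is not None:
            sigma_s = float(np.exp(params[k]))
            rho = float(np.exp(params[k + 1]))
        return beta, disp, sds, sigma_s, rho

    def corr_chols(self, rho: float) -> list[np.ndarray]:
        if self._rho_cache is not None and self._rho_cache[0] == rho:
            return self._rho_cache[1]
        chols = []
        for D in self.design.spatial.dist:
            R = np.exp(-D / rho)
            R[np.diag_indices_from(R)] += SPATIAL_JITTER
            try:
                chols.append(cholesky(R, lower=True))
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise np.linalg.LinAlgError(
                    f"exponential correlation matrix not positive definite "
                    f"after {SPATIAL_JITTER} jitter (rho={rho}, "
                    f"size={len(D)})"
                ) from exc
        self._rho_cache = (rho, chols)
        return chols

    # -- block-diagonal L = chol(Cov(u)) operations -------------------------

    def _blocks(self, sds, sigma_s, rho):
        """(slice, factor) pairs; factor is a scalar or a dense lower
        Cholesky block."""
        blocks: list[tuple[slice, Any]] = []
        for sd, t in zip(sds, self.design.re_terms):
            blocks.append((slice(t.offset, t.offset + t.size), sd))
        if self.design.spatial is not None:
            chols = self.corr_chols(rho)
            for off, pos, C in zip(
                self.design.spatial.offsets, self.design.spatial.positions, chols
            ):
                blocks.append((slice(off, off + len(pos)), sigma_s * C))
        return blocks

    @staticmethod
    def _L_vec(blocks, v):
        u = np.zeros_like(v)
        for sl, f in blocks:
            u[sl] = f * v[sl] if np.isscalar(f) else f @ v[sl]
        return u

    @staticmethod
    def _Lt_vec(blocks, w):
        out = np.zeros_like(w)
        for sl, f in blocks:
            out[sl] = f * w[sl] if np.isscalar(f) else f.T @ w[sl]
        return out

    @staticmethod
    def _Lt_M_L(blocks, M):
        B = M.copy()
        for sl, f in blocks:
            B[sl, :] = f * B[sl, :] if np.isscalar(f) else f.T @ B[sl, :]
        for sl, f in blocks:
            B[:, sl] = B[:, sl] * f if np.isscalar(f) else B[:, sl] @ f
        return B

    def _zt_vec(self, r: np.ndarray) -> np.ndarray:
        out = np.zeros(self.q)
        for j in range(self.coords.shape[1]):
            out += np.bincount(self.coords[:, j], weights=r, minlength=self.q)
        return out

    def _eta(self, beta, blocks, v):
        eta = self.design.X @ beta
        if self.q:
            u = self._L_vec(blocks, v)
            eta = eta + u[self.coords].sum(axis=1)
        return eta

    # -- inner Newton --------------------------------------------------------

    def _split_blocks(self, blocks):
        """Per-coordinate iid scales and per-size-class stacked spatial
        Cholesky blocks for :class:`_HFactor`."""
        scale_f = (
            np.concatenate(
                [
                    np.full(t.size, f)
                    for (sl, f), t in zip(blocks, self.design.re_terms)
                ]
            )
            if self.m_iid
            else np.zeros(0)
        )
        sp_stacks = [
            (
                (b, gidx, coords),
                np.stack([blocks[self.m_iid + gi][1] for gi in gidx]),
            )
            for b, gidx, coords in self.sp_size_classes
        ]
        return scale_f, sp_stacks

    def _inner_mode(self, beta, disp, blocks):
        """Maximize loglik(y|Lv) - v'v/2 over v; returns (v, factor,
        logdet, eta, objective)."""
        y, fam = self.design.y, self.family
        scale_f, sp_blocks = self._split_blocks(blocks)
        v = self._v.copy()
        eta = self._eta(beta, blocks, v)
        g = fam.loglik(y, eta, disp) - 0.5 * v @ v
        if not np.isfinite(g):
            v = np.zeros(self.q)
            eta = self._eta(beta, blocks, v)
            g = fam.loglik(y, eta, disp) - 0.5 * v @ v
        converged = False
        fac = None
        gnorm = np.inf
        for _ in range(self.max_inner):
            r = fam.score(y, eta, disp)
            grad = self._Lt_vec(blocks, self._zt_vec(r)) - v
            gnorm = np.max(np.abs(grad)) if self.q else 0.0
            w = fam.weights(y, eta, disp)
            fac = _HFactor(self, w, scale_f, sp_blocks)
            if gnorm < self.inner_tol * max(1.0, abs(g)):
                converged = True
                break
            step = fac.solve(grad)
            t = 1.0
            for _ls in range(40):
                v_new = v + t * step
                eta_new = self._eta(beta, blocks, v_new)
                g_new = fam.loglik(y, eta_new, disp) - 0.5 * v_new @ v_new
                if np.isfinite(g_new) and g_new >= g - 1e-12 * abs(g):
                    break
                t *= 0.5
            else:
                converged = True  # no further improvement possible
                break
            if abs(g_new - g) <= 1e-12 * max(1.0, abs(g)) and t == 1.0:
                converged = True  # objective plateau at full step
                break
            v, eta, g = v_new, eta_new, g_new
        if not converged:
            raise RuntimeError(
                f"inner Newton failed to converge in {self.max_inner} "
                f"iterations (last |grad|={gnorm:.3g}, obj={g:.6g})"
            )
        self._v = v.copy()
        return v, fac, fac.logdet, eta, g

    # -- public objective ----------------------------------------------------

    def nll(self, params: np.ndarray) -> float:
        try:
            beta, disp, sds, sigma_s, rho = self.unpack(params)
            if self.q == 0:
                eta = self.design.X @ beta
                return -self.family.loglik(self.design.y, eta, disp)
            blocks = self._blocks(sds, sigma_s, rho)
            v, _, logdet, eta, _ = self._inner_mode(beta, disp, blocks)
            ll = (
                self.family.loglik(self.design.y, eta, disp)
                - 0.5 * v @ v
                - 0.5 * logdet
            )
            return -ll if np.isfinite(ll) else 1e12
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e12

    def posterior(self, params: np.ndarray):
        """At given params: mode u-hat, v-hat, and the Laplace posterior
        covariance of v, Cov(v|y) = (I+A)^{-1}."""
        beta, disp, sds, sigma_s, rho = self.unpack(params)
        blocks = self._blocks(sds, sigma_s, rho)
        v, fac, logdet, eta, _ = self._inner_mode(beta, disp, blocks)
        u = self._L_vec(blocks, v)
        cov_v = fac.solve(np.eye(self.q))
        cov_v = 0.5 * (cov_v + cov_v.T)
        # map to the u scale: Q = L (I+A)^-1 L'
        Q = self._Lt_M_L(
            [(sl, f.T if not np.isscalar(f) else f) for sl, f in blocks], cov_v
        )
        w = self.family.weights(self.design.y, eta, disp)
        return {
            "v_hat": v,
            "u_hat": u,
            "cov_v": cov_v,
            "Q": 0.5 * (Q + Q.T),
            "eta": eta,
            "weights": w,
            "blocks": blocks,
        }


def laplace_nll(params: Mapping[str, Any] | np.ndarray,
                design: DesignMatrices) -> float:
    """Negative Laplace marginal log-likelihood at ``params``.

    ``params`` is either a packed vector (see ``_LaplaceEvaluator``) or a
    mapping with keys ``beta`` (array aligned to ``design.colnames`` or a
    name->value dict), ``theta`` (or ``sigma_resid`` for the Gaussian
    family), one ``sd_<term>`` per iid random term, and ``sigma_s`` /
    ``rho`` when the spec has a spatial component.
    """
    ev = _LaplaceEvaluator(design)
    if isinstance(params, Mapping):
        params = pack_params(params, design)
    return ev.nll(np.asarray(params, dtype=float))


def pack_params(d: Mapping[str, Any], design: DesignMatrices) -> np.ndarray:
    beta = d["beta"]
    if isinstance(beta, Mapping):
        missing = [c for c in design.colnames if c not in beta]
        if missing:
            raise ValueError(f"beta missing coefficients: {missing}")
        beta = [beta[c] for c in design.colnames]
    beta = np.asarray(beta, dtype=float)
    if len(beta) != len(design.colnames):
        raise ValueError(
            f"beta has {len(beta)} entries, design has {len(design.colnames)}"
        )
    disp = d["theta"] if design.spec.family == "nb2" else d["sigma_resid"]
    parts = [beta, [np.log(disp)]]
    for t in design.re_terms:
        parts.append([np.log(d[f"sd_{t.name}"])])
    if design.spatial is not None:
        parts.append([np.log(d["sigma_s"]), np.log(d["rho"])])
    return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    maxiter: int = 300
    restarts: int = 3  # random restarts when a variance hits its bound
    compute_param_cov: bool = False
    gtol: float = 1e-3  # scaled outer gradient tolerance (reported)
    fd_step: float = 1e-5  # central-difference step for the outer gradient
    log_sd_bounds: tuple[float, float] = (-6.0, 3.0)
    log_disp_bounds: tuple[float, float] = (-6.0, 14.0)
    seed: int = 0


@dataclass
class FittedModel:
    """A fitted bycatch GLMM with everything prediction needs."""

    spec: ModelSpec
    colnames: list[str]
    #: coefficients in the orthonormalized column basis used for
    #: fitting (X is QR-rotated so its columns are uncorrelated, which
    #: the quasi-Newton outer optimizer needs for a well-conditioned
    #: surface); ``coef`` returns conventional coefficients on the raw
    #: treatment-coded design.
    beta: np.ndarray
    beta_transform: np.ndarray
    theta: float | None
    sigma_resid: float | None
    sd: dict[str, float]
    sigma_s: float | None
    rho: float | None
    u_hat: np.ndarray
    v_hat: np.ndarray
    Q: np.ndarray  # Laplace posterior covariance of u
    cov_v: np.ndarray
    loglik: float
    n_obs: int
    n_params: int
    aicc: float
    converged: bool
    max_grad: float
    params_vec: np.ndarray
    param_names: list[str]
    param_cov: np.ndarray | None
    design: DesignMatrices
    _evaluator: _LaplaceEvaluator | None = None
    _eta_hat: np.ndarray | None = None
    _joint_cov: np.ndarray | None = None

    @property
    def coef_vector(self) -> np.ndarray:
        """Coefficients on the conventional treatment-coded design."""
        return self.beta_transform @ self.beta

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.colnames, self.coef_vector))

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        """Map a raw design matrix into the fitting-time basis."""
        return X @ self.beta_transform

    def re_levels(self, name: str) -> np.ndarray:
        for t in self.design.re_terms:
            if t.name == name:
                return t.levels
        raise KeyError(name)

    def eta_hat(self) -> np.ndarray:
        if self._eta_hat is None:
            eta = self.design.X @ self.beta
            if self.design.q:
                eta = eta + self.u_hat[self.design.row_coords()].sum(axis=1)
            self._eta_hat = eta
        return self._eta_hat

    def mu_hat(self) -> np.ndarray:
        return np.exp(self.eta_hat())

    def joint_cov(self) -> np.ndarray:
        """Gaussian covariance of (beta, v) from the joint negative
        Hessian at the optimum (variance parameters held fixed)."""
        if self._joint_cov is None:
            ev = self._evaluator
            post = ev.posterior(self.params_vec)
            X, w = self.design.X, post["weights"]
            S = _scaled_loading_matrix(ev, post["blocks"])
            top = X.T @ (w[:, None] * X)
            cross = X.T @ (w[:, None] * S)
            low = S.T @ (w[:, None] * S)
            low[np.diag_indices_from(low)] += 1.0
            H = np.block([[top, cross], [cross.T, low]])
            Hc = cho_factor(H, lower=True)
            C = cho_solve(Hc, np.eye(H.shape[0]))
            self._joint_cov = 0.5 * (C + C.T)
        return self._joint_cov

    def to_json(self) -> str:
        data_hash = hashlib.sha256(
            np.ascontiguousarray(self.design.y).tobytes()
            + np.ascontiguousarray(self.design.X).tobytes()
        ).hexdigest()[:16]
        fnum = lambda x: None if x is None else float(x)  # noqa: E731
        payload = {
            "family": self.spec.family,
            "fixed_terms": list(self.spec.fixed_terms),
            "random_terms": list(self.spec.random_terms),
            "spatial_grouping": self.spec.spatial_grouping,
            "coefficients": {k: float(v) for k, v in self.coef.items()},
            "theta": fnum(self.theta),
            "sigma_resid": fnum(self.sigma_resid),
            "sd": {k: float(v) for k, v in self.sd.items()},
            "sigma_s": fnum(self.sigma_s),
            "rho_km": fnum(self.rho),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "aicc": float(self.aicc),
            "converged": bool(self.converged),
            "max_grad": float(self.max_grad),
            "data_hash": data_hash,
        }
        return json.dumps(payload, indent=2)


def _scaled_loading_matrix(ev: _LaplaceEvaluator, blocks) -> np.ndarray:
    """Dense S = Z L (n x q): row i carries L' z_i."""
    n, q = ev.design.n, ev.q
    S = np.zeros((n, q))
    coords = ev.coords
    col = 0
    for sd_block, t in zip(blocks[: len(ev.design.re_terms)], ev.design.re_terms):
        sl, f = sd_block
        S[np.arange(n), coords[:, col]] = f
        col += 1
    if ev.design.spatial is not None:
        sp = ev.design.spatial
        for gi, (off, pos) in enumerate(zip(sp.offsets, sp.positions)):
            sl, f = blocks[len(ev.design.re_terms) + gi]
            mask = sp.row_group == gi
            rows = np.flatnonzero(mask)
            S[rows, off : off + len(pos)] = f[sp.row_pos[rows], :]
    return S


def _initial_values(design: DesignMatrices, opts: FitOptions) -> np.ndarray:
    """Poisson-GLM start for beta; log dispersion 0; SDs 0.1; rho at the
    median pairwise distance."""
    import statsmodels.api as sm

    X, y = design.X, design.y
    if design.spec.family == "nb2":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
            beta0 = np.asarray(res.params, dtype=float)
            if not np.all(np.isfinite(beta0)):
                raise ValueError
        except Exception:
            beta0 = np.zeros(X.shape[1])
            beta0[0] = np.log(max(np.mean(y), 1e-3))
        disp0 = 0.0
    else:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        disp0 = float(np.log(max(np.std(resid), 1e-3)))
    parts = [beta0, [disp0]]
    for _ in design.re_terms:
        parts.append([np.log(0.1)])
    if design.spatial is not None:
        alld = np.concatenate([D[np.triu_indices(len(D), 1)] for D in design.spatial.dist if len(D) > 1])
        med = float(np.median(alld)) if len(alld) else 50.0
        parts.append([np.log(0.1), np.log(max(med, 1.0))])
    return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])


def _bounds(ev: _LaplaceEvaluator, opts: FitOptions, x0: np.ndarray):
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * ev.p
    bounds.append(opts.log_disp_bounds)
    for _ in ev.design.re_terms:
        bounds.append(opts.log_sd_bounds)
    if ev.design.spatial is not None:
        bounds.append(opts.log_sd_bounds)
        rho0 = x0[-1]
        bounds.append((rho0 - 6.0, rho0 + 5.0))
    return bounds


def fit(em: pd.DataFrame, spec: ModelSpec, options: FitOptions | None = None,
        response: str = "bycatch_count") -> FittedModel:
    """Fit the mixed model by maximizing the Laplace marginal likelihood."""
    opts = options or FitOptions()
    design = build_design(em, spec, response=response)
    # rotate the fixed-effects columns to an orthonormal basis
    # (X -> Q sqrt(n) from a QR decomposition): treatment-coded designs
    # with raw log covariates are badly conditioned, which stalls the
    # finite-difference quasi-Newton outer optimization
    n_rows = len(design.y)
    _, Rmat = np.linalg.qr(design.X)
    transform = np.linalg.solve(Rmat, np.eye(design.X.shape[1])) * np.sqrt(
        n_rows
    )
    design.X = design.X @ transform
    ev = _LaplaceEvaluator(design)
    x0 = _initial_values(design, opts)
    bounds = _bounds(ev, opts, x0)

    rng = np.random.default_rng(opts.seed)

    def jac(x, h=opts.fd_step):
        # central differences: one-sided steps are not accurate enough
        # for the flat, correlated directions of this surface
        g = np.zeros(len(x))
        e = np.zeros(len(x))
        for i in range(len(x)):
            e[i] = h
            g[i] = (ev.nll(x + e) - ev.nll(x - e)) / (2.0 * h)
            e[i] = 0.0
        return g

    best = None
    attempt_x0 = x0
    for attempt in range(opts.restarts + 1):
        res = optimize.minimize(
            ev.nll,
            attempt_x0,
            jac=jac,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": opts.maxiter,
                "maxfun": 20 * opts.maxiter * ev.n_params,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        at_bound = _variances_at_bound(ev, res.x, bounds)
        if not at_bound:
            break
        logger.warning(
            "variance component(s) at boundary (%s); restart %d",
            ", ".join(at_bound), attempt + 1,
        )
        if attempt < opts.restarts:
            attempt_x0 = x0.copy()
            k = ev.p
            attempt_x0[k:] = x0[k:] + rng.normal(0, 0.7, size=len(x0) - k)
            attempt_x0[k:] = np.clip(
                attempt_x0[k:],
                [b[0] + 0.1 for b in bounds[k:]],
                [b[1] - 0.1 for b in bounds[k:]],
            )
    res = best

    grad = np.asarray(res.jac, dtype=float)
    max_grad = float(np.max(np.abs(grad))) if grad.size else 0.0
    converged = bool(res.success) and max_grad < opts.gtol * max(1.0, abs(res.fun))
    if not converged:
        logger.warning(
            "outer optimization: success=%s max|grad|=%.3g nll=%.6g",
            res.success, max_grad, res.fun,
        )

    params = res.x
    beta, disp, sds, sigma_s, rho = ev.unpack(params)
    if ev.q:
        post = ev.posterior(params)
        u_hat, v_hat = post["u_hat"], post["v_hat"]
        Q, cov_v = post["Q"], post["cov_v"]
        eta = post["eta"]
    else:
        u_hat = v_hat = np.zeros(0)
        Q = cov_v = np.zeros((0, 0))
        eta = design.X @ beta

    loglik = -float(res.fun)
    k = ev.n_params
    n = design.n
    model = FittedModel(
        spec=spec,
        colnames=design.colnames,
        beta=beta,
        beta_transform=transform,
        theta=disp if spec.family == "nb2" else None,
        sigma_resid=disp if spec.family == "gaussian" else None,
        sd={t.name: s for t, s in zip(design.re_terms, sds)},
        sigma_s=sigma_s,
        rho=rho,
        u_hat=u_hat,
        v_hat=v_hat,
        Q=Q,
        cov_v=cov_v,
        loglik=loglik,
        n_obs=n,
        n_params=k,
        aicc=_aicc_value(loglik, k, n),
        converged=converged,
        max_grad=max_grad,
        params_vec=params,
        param_names=ev.param_names,
        param_cov=None,
        design=design,
        _evaluator=ev,
        _eta_hat=eta,
    )
    if opts.compute_param_cov:
        model.param_cov = _fd_param_cov(ev, params)
    return model


def _variances_at_bound(ev, x, bounds, tol=1e-4) -> list[str]:
    names = []
    for i in range(ev.p + 1, ev.n_params):
        lo, hi = bounds[i]
        if lo is not None and x[i] < lo + tol:
            names.append(ev.param_names[i])
        if hi is not None and x[i] > hi - tol:
            names.append(ev.param_names[i])
    return names


def _fd_param_cov(ev: _LaplaceEvaluator, params: np.ndarray,
                  eps: float = 1e-4) -> np.ndarray:
    """Covariance of the parameter estimates from a central-difference
    Hessian of the negative log-likelihood, PD-repaired if needed."""
    k = len(params)
    H = np.zeros((k, k))
    steps = eps * np.maximum(1.0, np.abs(params))
    f0 = ev.nll(params)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                fpp = ev.nll(params + ei)
                fmm = ev.nll(params - ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
            else:
                fpp = ev.nll(params + ei + ej)
                fpm = ev.nll(params + ei - ej)
                fmp = ev.nll(params - ei + ej)
                fmm = ev.nll(params - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * steps[i] * steps[j]
                )
    # repair to positive definite if the FD Hessian is slightly indefinite
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.maximum(w, 1e-8 * max(np.max(np.abs(w)), 1.0))
    cov = (V / w) @ V.T
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# model comparison and diagnostics
# ---------------------------------------------------------------------------


def _aicc_value(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(fitted: FittedModel) -> float:
    """Small-sample-corrected AIC of a fitted model."""
    return _aicc_value(fitted.loglik, fitted.n_params, fitted.n_obs)


def select_model(
    em: pd.DataFrame,
    candidates: Sequence[ModelSpec],
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Fit all candidate specs and rank them by AICc.

    Failed fits are kept in the table with ``ok = False`` rather than
    silently dropped; if every candidate fails an error is raised.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate spec")
    rows = []
    fits = []
    for i, spec in enumerate(candidates):
        try:
            m = fit(em, spec, options)
            rows.append(
                {
                    "candidate": i,
                    "spatial_grouping": spec.spatial_grouping,
                    "random_terms": "+".join(spec.random_terms) or "none",
                    "n_params": m.n_params,
                    "loglik": m.loglik,
                    "aicc": m.aicc,
                    "converged": m.converged,
                    "ok": True,
                }
            )
            fits.append(m)
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            logger.warning("candidate %d failed: %s", i, exc)
            rows.append(
                {
                    "candidate": i,
                    "spatial_grouping": spec.spatial_grouping,
                    "random_terms": "+".join(spec.random_terms) or "none",
                    "n_params": np.nan,
                    "loglik": np.nan,
                    "aicc": np.nan,
                    "converged": False,
                    "ok": False,
                }
            )
            fits.append(None)
    tab = pd.DataFrame(rows)
    if not tab["ok"].any():
        raise RuntimeError("all candidate models failed to fit")
    tab = tab.sort_values(
        "aicc", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    tab.attrs["fits"] = fits
    return tab


def simulate_response(
    fitted: FittedModel, rng: np.random.Generator, n_sim: int = 1
) -> np.ndarray:
    """Draw response vectors from the fitted model, conditional on the
    estimated random effects.  Returns an (n_sim, n) array."""
    mu = fitted.mu_hat()
    if fitted.spec.family == "nb2":
        theta = fitted.theta
        p = theta / (theta + mu)
        return rng.negative_binomial(theta, p, size=(n_sim, len(mu))).astype(float)
    return rng.normal(mu, fitted.sigma_resid, size=(n_sim, len(mu)))


def quantile_residuals(
    fitted: FittedModel,
    n_sim: int = 250,
    seed: int = 0,
    y: np.ndarray | None = None,
) -> dict[str, Any]:
    """Simulation-based randomized quantile residuals and GOF summaries.

    Per observation the residual is the rank of the observed count among
    ``n_sim`` simulated responses, randomized uniformly within ties and
    scaled to (0, 1); for a correctly specified model these are standard
    uniform.  Also reports a Kolmogorov-Smirnov uniformity test and a
    simulation-based dispersion test (observed Pearson statistic against
    its simulated distribution).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable residuals")
    rng = np.random.default_rng(seed)
    obs = fitted.design.y if y is None else np.asarray(y, dtype=float)
    sims = simulate_response(fitted, rng, n_sim)
    below = (sims < obs).sum(axis=0)
    ties = (sims == obs).sum(axis=0)
    u = rng.uniform(size=len(obs))
    resid = (below + u * (ties + 1.0)) / (n_sim + 1.0)
    ks = stats.kstest(resid, "uniform")

    mu = fitted.mu_hat()
    var = (
        mu + mu**2 / fitted.theta
        if fitted.spec.family == "nb2"
        else np.full_like(mu, fitted.sigma_resid**2)
    )
    pearson_obs = float(np.sum((obs - mu) ** 2 / var))
    pearson_sim = ((sims - mu) ** 2 / var).sum(axis=1)
    p_lower = (np.sum(pearson_sim <= pearson_obs) + 1) / (n_sim + 1)
    p_upper = (np.sum(pearson_sim >= pearson_obs) + 1) / (n_sim + 1)
    return {
        "residuals": resid,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "dispersion_ratio": pearson_obs / float(np.mean(pearson_sim)),
        "dispersion_p": float(min(1.0, 2.0 * min(p_lower, p_upper))),
    }
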