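"""Mixed-model core: design coding, NB2 likelihood identities, the
Laplace marginal against closed-form and quadrature oracles, fitting
against an independent fixed-effects GLM, AICc arithmetic and
simulation-based residuals."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from fleetbycatch import glmm, synthetic
from fleetbycatch.synthetic import SimConfig, TrueParams


class TestModelSpec:
    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError, match="requires both main effects"):
            glmm.ModelSpec(fixed_terms=("mesh_class:log_soak_time",))

    def test_unknown_terms_rejected(self):
        with pytest.raises(ValueError):
            glmm.ModelSpec(fixed_terms=("gear_colour",))
        with pytest.raises(ValueError):
            glmm.ModelSpec(random_terms=("skipper",))
        with pytest.raises(ValueError):
            glmm.ModelSpec(spatial_grouping="decade")


class TestDesign:
    def _df(self, n=6):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "mesh_class": ["<120 mm", "120-200", ">200 mm"] * (n // 3),
            "vessel_class": ["<8 m", "8-10 m"] * (n // 2),
            "population": ["North Sea Population",
                           "Western Baltic Population"] * (n // 2),
            "soak_time_h": rng.uniform(10, 40, n),
            "net_length_m": rng.uniform(500, 5000, n),
            "depth_m": rng.uniform(10, 100, n),
            "year": 2020, "quarter": 1, "vessel_id": "V1",
            "lon": 7.5, "lat": 54.25, "bycatch_count": 0,
        })

    def test_three_levels_two_contrast_columns(self):
        X, names = glmm.build_fixed_design(self._df(), ("mesh_class",))
        assert names == ["intercept", "mesh_class[120-200]",
                         "mesh_class[>200 mm]"]
        assert X.shape[1] == 3

    def test_log_transform_value(self):
        df = self._df()
        df["soak_time_h"] = 20.0
        X, names = glmm.build_fixed_design(df, ("log_soak_time",))
        assert X[0, names.index("log_soak_time")] == pytest.approx(
            np.log(20.0), abs=1e-12
        )

    def test_interaction_columns_match_hand_built(self):
        df = self._df()
        X, names = glmm.build_fixed_design(
            df, ("mesh_class", "log_soak_time", "mesh_class:log_soak_time")
        )
        ls = np.log(df["soak_time_h"].to_numpy())
        for lev in ("120-200", ">200 mm"):
            dummy = (df["mesh_class"] == lev).to_numpy(float)
            col = names.index(f"mesh_class[{lev}]:log_soak_time")
            np.testing.assert_allclose(X[:, col], dummy * ls)

    def test_unseen_level_rejected(self):
        df = self._df()
        df.loc[0, "mesh_class"] = "tiny"
        with pytest.raises(ValueError, match="unseen"):
            glmm.build_fixed_design(df, ("mesh_class",))

    def test_nonpositive_covariate_rejected(self):
        df = self._df()
        df.loc[1, "depth_m"] = 0.0
        with pytest.raises(ValueError, match="depth_m"):
            glmm.build_fixed_design(df, ("log_depth",))

    def test_spatial_group_count(self, em_table):
        spec = glmm.ModelSpec(random_terms=("year",),
                              spatial_grouping="quarter_within_year")
        d = glmm.build_design(em_table, spec)
        n_years = em_table["year"].nunique()
        assert len(d.spatial.group_keys) == n_years * 4


class TestNB2Loglik:
    def test_geometric_special_case(self):
        # theta=1, y=0, mu=1: P = 1/2
        assert glmm.nb2_loglik(np.array([0]), np.array([1.0]), 1.0) == (
            pytest.approx(np.log(0.5), abs=1e-12)
        )

    def test_poisson_limit(self):
        y = np.arange(0, 15)
        mu = np.full_like(y, 3.0, dtype=float)
        ours = np.array(
            [glmm.nb2_loglik(y[[i]], mu[[i]], 1e9) for i in range(len(y))]
        )
        poisson = stats.poisson.logpmf(y, 3.0)
        np.testing.assert_allclose(ours, poisson, atol=1e-5)

    def test_matches_scipy_nbinom(self, rng):
        # independent parameterization route: nbinom(n=theta, p=theta/(theta+mu))
        for _ in range(20):
            y = rng.integers(0, 30, 5)
            mu = rng.uniform(0.1, 20.0, 5)
            theta = rng.uniform(0.2, 8.0)
            ours = glmm.nb2_loglik(y, mu, theta)
            ref = stats.nbinom.logpmf(y, theta, theta / (theta + mu)).sum()
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_domain_guards(self):
        with pytest.raises(ValueError):
            glmm.nb2_loglik(np.array([0]), np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            glmm.nb2_loglik(np.array([0]), np.array([-1.0]), 1.0)
        with pytest.raises(ValueError):
            glmm.nb2_loglik(np.array([0.5]), np.array([1.0]), 1.0)


def _toy_counts(mu0, theta, sd, n_groups, per_group, seed):
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sd, n_groups)
    rows = []
    for g in range(n_groups):
        mu = np.exp(np.log(mu0) + b[g])
        for y in rng.negative_binomial(theta, theta / (theta + mu), per_group):
            rows.append({"year": f"g{g}", "bycatch_count": int(y)})
    return pd.DataFrame(rows)


class TestLaplace:
    def test_no_random_terms_equals_fixed_likelihood(self, em_table):
        spec = glmm.ModelSpec(random_terms=(), spatial_grouping="none")
        d = glmm.build_design(em_table, spec)
        beta = np.zeros(len(d.colnames))
        beta[0] = -2.0
        nll = glmm.laplace_nll({"beta": beta, "theta": 1.3}, d)
        mu = np.exp(d.X @ beta)
        assert nll == pytest.approx(-glmm.nb2_loglik(d.y, mu, 1.3), abs=1e-10)

    def test_zero_variance_reduces_to_fixed_likelihood(self, em_table):
        spec = glmm.ModelSpec(random_terms=("year",), spatial_grouping="none")
        d = glmm.build_design(em_table, spec)
        beta = np.zeros(len(d.colnames))
        beta[0] = -2.0
        with np.errstate(divide="ignore"):
            nll = glmm.laplace_nll(
                {"beta": beta, "theta": 1.3, "sd_year": 0.0}, d
            )
        mu = np.exp(d.X @ beta)
        assert nll == pytest.approx(-glmm.nb2_loglik(d.y, mu, 1.3), abs=1e-10)

    def test_gaussian_response_matches_closed_form(self):
        # Laplace is exact for a Gaussian response: compare with the
        # closed-form LMM marginal N(Xb, sigma^2 I + sd^2 ZZ')
        rng = np.random.default_rng(5)
        n_g, m, sd, sigma = 3, 7, 0.8, 0.5
        df = pd.DataFrame({
            "year": np.repeat([f"g{i}" for i in range(n_g)], m),
            "y": rng.normal(2.0, 1.0, n_g * m),
        })
        spec = glmm.ModelSpec(fixed_terms=(), random_terms=("year",),
                              spatial_grouping="none", family="gaussian")
        d = glmm.build_design(df, spec, response="y")
        nll = glmm.laplace_nll(
            {"beta": [2.0], "sigma_resid": sigma, "sd_year": sd}, d
        )
        Z = np.zeros((n_g * m, n_g))
        Z[np.arange(n_g * m), np.repeat(np.arange(n_g), m)] = 1.0
        cov = sigma**2 * np.eye(n_g * m) + sd**2 * (Z @ Z.T)
        ref = stats.multivariate_normal.logpdf(
            df["y"], mean=np.full(n_g * m, 2.0), cov=cov
        )
        assert nll == pytest.approx(-ref, abs=1e-6)

    @pytest.mark.parametrize("mu0,theta,sd,seed", [
        (50.0, 10.0, 0.5, 7), (30.0, 8.0, 0.3, 13), (30.0, 8.0, 0.3, 2),
    ])
    def test_matches_adaptive_quadrature(self, mu0, theta, sd, seed):
        # 20-row, one-random-intercept toy with moderately large counts
        # (near-Gaussian conditional): mode-centred 1-D quadrature per
        # group is the independent oracle
        from scipy import optimize as sopt

        df = _toy_counts(mu0, theta, sd, n_groups=1, per_group=20, seed=seed)
        spec = glmm.ModelSpec(fixed_terms=(), random_terms=("year",),
                              spatial_grouping="none")
        d = glmm.build_design(df, spec)
        b0 = np.log(mu0)
        nll = glmm.laplace_nll(
            {"beta": [b0], "theta": theta, "sd_year": sd}, d
        )
        ll = 0.0
        for g in df["year"].unique():
            y = df.loc[df["year"] == g, "bycatch_count"].to_numpy()

            def logf(u):
                mu = np.exp(b0 + u)
                return stats.nbinom.logpmf(
                    y, theta, theta / (theta + mu)
                ).sum() + stats.norm.logpdf(u, 0.0, sd)

            uhat = sopt.minimize_scalar(
                lambda u: -logf(u), bounds=(-10 * sd, 10 * sd),
                method="bounded",
            ).x
            scale = logf(uhat)
            val, _ = integrate.quad(
                lambda u: np.exp(logf(u) - scale),
                uhat - 12 * sd, uhat + 12 * sd,
                epsabs=1e-13, epsrel=1e-11, limit=500, points=[uhat],
            )
            ll += scale + np.log(val)
        assert nll == pytest.approx(-ll, abs=1e-3)


class TestFit:
    def test_matches_independent_nb_glm_without_random_effects(self):
        # sigma = 0 data: the marginal model is a plain NB2 GLM;
        # statsmodels is the independent route
        import statsmodels.api as sm

        beta = dict(TrueParams().beta, intercept=-2.5)
        tp = TrueParams(beta=beta, sigma_vessel=0.0, sigma_year=0.0,
                        sigma_s=0.0, theta=1.5)
        cfg = SimConfig(n_vessels=60, years=(2019, 2020),
                        n_days_per_vessel_year=25, em_fraction=1.0, seed=88)
        _, em = synthetic.simulate_dataset(cfg, tp)
        spec = glmm.ModelSpec(random_terms=(), spatial_grouping="none")
        ours = glmm.fit(em, spec)

        X, names = glmm.build_fixed_design(em, spec.fixed_terms)
        ref = sm.NegativeBinomial(
            em["bycatch_count"].to_numpy(), X
        ).fit(disp=0, maxiter=200)
        se = ref.bse[: len(names)]
        diff = np.abs(np.array([ours.coef[c] for c in names]) - ref.params[: len(names)])
        assert np.all(diff < 2 * se)
        assert ours.theta == pytest.approx(1.0 / ref.params[-1], rel=0.05)
        assert ours.loglik == pytest.approx(ref.llf, abs=0.5)

    def test_refit_identical(self, em_table):
        spec = glmm.ModelSpec(random_terms=("year",),
                              spatial_grouping="none")
        a = glmm.fit(em_table, spec)
        b = glmm.fit(em_table, spec)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-8)
        assert a.theta == pytest.approx(b.theta, abs=1e-8)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_fitted_model_serializes(self, fitted_spatial):
        import json

        payload = json.loads(fitted_spatial.to_json())
        assert payload["spatial_grouping"] == "quarter_within_year"
        assert "coefficients" in payload and "data_hash" in payload
        assert payload["rho_km"] > 0


class TestAICc:
    def test_formula_arithmetic(self):
        # -2(-100) + 2*5 + 2*5*6/94
        assert glmm._aicc_value(-100.0, 5, 100) == pytest.approx(
            210.0 + 60.0 / 94.0
        )

    def test_approaches_aic_for_large_n(self):
        aic = -2.0 * (-100.0) + 2 * 5
        assert glmm._aicc_value(-100.0, 5, 10**7) == pytest.approx(
            aic, abs=1e-4
        )

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            glmm._aicc_value(-10.0, 5, 6)

    def test_nested_fits_delta(self, fitted_plain, fitted_year):
        k1, k2 = fitted_plain.n_params, fitted_year.n_params
        n = fitted_plain.n_obs
        expected = (
            (-2 * fitted_year.loglik + 2 * k2 + 2 * k2 * (k2 + 1) / (n - k2 - 1))
            - (-2 * fitted_plain.loglik + 2 * k1 + 2 * k1 * (k1 + 1) / (n - k1 - 1))
        )
        assert fitted_year.aicc - fitted_plain.aicc == pytest.approx(
            expected, abs=1e-9
        )


class TestSelection:
    def test_duplicate_specs_identical_aicc(self, em_table):
        spec = glmm.ModelSpec(random_terms=("year",), spatial_grouping="none")
        tab = glmm.select_model(em_table, [spec, spec])
        assert tab["aicc"].iloc[0] == pytest.approx(tab["aicc"].iloc[1],
                                                    abs=1e-6)
        assert tab["delta_aicc"].iloc[0] == 0.0

    def test_single_candidate(self, em_table):
        spec = glmm.ModelSpec(random_terms=(), spatial_grouping="none")
        tab = glmm.select_model(em_table, [spec])
        assert len(tab) == 1 and tab["ok"].all()

    def test_no_candidates_rejected(self, em_table):
        with pytest.raises(ValueError):
            glmm.select_model(em_table, [])

    def test_aicc_invariant_to_observation_order(self, em_table):
        spec = glmm.ModelSpec(random_terms=(), spatial_grouping="none")
        a = glmm.fit(em_table, spec)
        shuffled = em_table.sample(frac=1.0, random_state=7).reset_index(
            drop=True
        )
        b = glmm.fit(shuffled, spec)
        assert a.aicc == pytest.approx(b.aicc, abs=1e-6)

    def test_spatial_structure_detected_when_strong(self):
        """Selection self-consistency: with a strong generating field,
        the spatial candidate out-ranks the no-spatial one in most
        replicate datasets."""
        beta = dict(TrueParams().beta, intercept=-3.4)
        tp = TrueParams(beta=beta, sigma_vessel=0.0, sigma_year=0.2,
                        sigma_s=1.0, rho=60.0)
        specs = [
            glmm.ModelSpec(random_terms=("year",),
                           spatial_grouping="quarter_within_year"),
            glmm.ModelSpec(random_terms=("year",), spatial_grouping="none"),
        ]
        wins = 0
        n_rep = 6
        for r in range(n_rep):
            cfg = SimConfig(n_vessels=20, years=(2019, 2020),
                            n_days_per_vessel_year=20, em_fraction=1.0,
                            seed=4200 + r)
            _, em = synthetic.simulate_dataset(cfg, tp)
            tab = glmm.select_model(em, specs)
            best = tab.loc[tab["ok"]].iloc[0]
            wins += best["spatial_grouping"] == "quarter_within_year"
        assert wins >= 5, f"spatial model preferred in {wins}/{n_rep}"


class TestResiduals:
    def test_deterministic_given_seed(self, fitted_plain):
        a = glmm.quantile_residuals(fitted_plain, n_sim=150, seed=4)
        b = glmm.quantile_residuals(fitted_plain, n_sim=150, seed=4)
        np.testing.assert_array_equal(a["residuals"], b["residuals"])

    def test_all_zero_observations_under_large_mu(self):
        df = _toy_counts(40.0, 5.0, 0.2, n_groups=2, per_group=15, seed=11)
        spec = glmm.ModelSpec(fixed_terms=(), random_terms=("year",),
                              spatial_grouping="none")
        m = glmm.fit(df, spec)
        res = glmm.quantile_residuals(m, n_sim=200, seed=1,
                                      y=np.zeros(len(df)))
        assert np.max(res["residuals"]) < 0.05
        assert res["ks_p"] < 1e-6  # extreme lack of fit is detected

    def test_minimum_simulations_enforced(self, fitted_plain):
        with pytest.raises(ValueError):
            glmm.quantile_residuals(fitted_plain, n_sim=50)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_against_glmmtmb_reference(tmp_path):
    """Independent full-likelihood oracle: glmmTMB fits the identical
    NB2 model (vessel + year intercepts) on the same data."""
    beta = dict(TrueParams().beta, intercept=-3.9)
    tp = TrueParams(beta=beta, sigma_s=0.0)
    cfg = SimConfig(n_vessels=20, years=(2016, 2017, 2018, 2019, 2020),
                    n_days_per_vessel_year=12, em_fraction=1.0, seed=3)
    _, em = synthetic.simulate_dataset(cfg, tp)
    spec = glmm.ModelSpec(random_terms=("vessel_id", "year"),
                          spatial_grouping="none")
    ours = glmm.fit(em, spec)

    csv = tmp_path / "em.csv"
    em.to_csv(csv, index=False)
    script = tmp_path / "ref.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv('{csv}')
        d$mesh_class <- relevel(factor(d$mesh_class), ref='<120 mm')
        d$vessel_class <- relevel(factor(d$vessel_class), ref='<8 m')
        d$population <- relevel(factor(d$population),
                                ref='North Sea Population')
        m <- glmmTMB(bycatch_count ~ mesh_class + vessel_class + population
                     + log(net_length_m) + log(soak_time_h) + log(depth_m)
                     + mesh_class:log(soak_time_h)
                     + (1|vessel_id) + (1|year),
                     data=d, family=nbinom2)
        cat(sprintf('logLik %.6f\\n', as.numeric(logLik(m))))
        cat(sprintf('theta %.6f\\n', sigma(m)))
        cf <- fixef(m)$cond
        cat(sprintf('intercept %.6f\\n', cf[['(Intercept)']]))
        cat(sprintf('log_net %.6f\\n', cf[['log(net_length_m)']]))
        cat(sprintf('log_depth %.6f\\n', cf[['log(depth_m)']]))
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = {
        line.split()[0]: float(line.split()[1])
        for line in out.stdout.strip().splitlines()
        if len(line.split()) == 2
    }
    assert ours.loglik == pytest.approx(ref["logLik"], abs=0.5)
    assert ours.theta == pytest.approx(ref["theta"], rel=0.05)
    assert ours.coef["intercept"] == pytest.approx(ref["intercept"], abs=0.2)
    assert ours.coef["log_net_length"] == pytest.approx(ref["log_net"],
                                                        abs=0.05)
    assert ours.coef["log_depth"] == pytest.approx(ref["log_depth"], abs=0.05)
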