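"""Mixed-model estimation, adjusted means, R2, and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import grid_search_loglik, reml_loglik_dense
from leafsi import GeneratorConfig, generate_dataset
from leafsi.lmm import (
    ModelSpec,
    adjusted_means,
    anderson_darling,
    diagnostics,
    fit_lmm,
    ncv_test,
    r2_components,
    r2_nakagawa,
)


def _simulate(seed, n_sites=5, n_per=20, beta=(0.3, -0.5), s_site=0.4, s_resid=0.6):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        a = rng.normal(0, s_site)
        for _ in range(n_per):
            x1 = rng.integers(0, 2)
            x2 = rng.normal()
            y = beta[0] * x1 + beta[1] * x2 + a + rng.normal(0, s_resid)
            rows.append({"site_id": f"S{s}", "x1": x1, "x2": x2, "resp": np.exp(y)})
    return pd.DataFrame(rows)


SPEC = ModelSpec(response="resp", log_response=True, fixed=("x1", "x2"))


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("method", ["reml", "ml"])
def test_profile_optimum_matches_grid_oracle(seed, method):
    """Profiled 1-D optimum agrees with a dense 2-D grid-search likelihood."""
    df = _simulate(seed)
    fit = fit_lmm(SPEC, df, method=method)
    y = np.log(df["resp"].to_numpy())
    X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
    groups = pd.factorize(df["site_id"])[0]
    ll_grid, _, _ = grid_search_loglik(y, X, groups, reml=(method == "reml"))
    ll_fit = fit.loglik
    # implementation must achieve at least the grid optimum (same convention)
    assert ll_fit >= ll_grid - 1e-4
    ll_at_fit = reml_loglik_dense(y, X, groups, fit.sigma2_site,
                                  fit.sigma2_resid, reml=(method == "reml"))
    assert abs(ll_at_fit - ll_fit) < 1e-6


def test_degenerates_to_ols_when_site_variance_vanishes():
    cfg = GeneratorConfig(seed=4, site_sd=0.0, n_sites=6, soil_n_range=(0.05, 0.30),
                          slope_intercept=0.0, slope_per_map=0.0)
    samples, sites = generate_dataset(cfg)
    fit = fit_lmm(ModelSpec(fixed=("npk", "fence")), samples, sites)
    assert fit.sigma2_site <= 1e-6
    y = np.log(samples["si"].to_numpy())
    X = np.column_stack([np.ones(len(samples)), samples["npk"], samples["fence"]])
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.coefficients["estimate"].to_numpy(), beta_ols, atol=1e-8)


def test_agrees_with_statsmodels_mixedlm():
    """Independent route: statsmodels MixedLM reproduces the same fit."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = _simulate(7)
    fit = fit_lmm(SPEC, df, method="reml")
    y = np.log(df["resp"])
    X = sm.add_constant(df[["x1", "x2"]].astype(float))
    m = MixedLM(y, X, groups=df["site_id"]).fit(reml=True)
    assert np.allclose(fit.coefficients["estimate"], m.fe_params, atol=1e-6)
    assert np.allclose(fit.sigma2_site, m.cov_re.values[0, 0], atol=1e-4)
    assert np.allclose(fit.sigma2_resid, m.scale, atol=1e-5)
    assert abs(fit.loglik - m.llf) < 1e-5


def test_reml_and_ml_coefficients_agree_on_balanced_design():
    """Balanced random-intercept designs: GLS = OLS for any variance ratio."""
    cfg = GeneratorConfig(seed=6, n_sites=5, blocks_per_site=(3, 3))
    samples, sites = generate_dataset(cfg)
    spec = ModelSpec(fixed=("npk", "fence"))
    f1 = fit_lmm(spec, samples, sites, method="reml")
    f2 = fit_lmm(spec, samples, sites, method="ml")
    assert np.allclose(f1.coefficients["estimate"], f2.coefficients["estimate"],
                       atol=1e-6)


def test_adding_terms_never_decreases_ml_loglik(small_dataset):
    samples, sites = small_dataset
    lls = []
    for terms in [(), ("npk",), ("npk", "fence"), ("npk", "fence", "soil_c")]:
        fit = fit_lmm(ModelSpec(fixed=terms), samples, sites, method="ml")
        lls.append(fit.loglik)
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_single_site_rejected():
    df = _simulate(0, n_sites=1)
    with pytest.raises(ValueError, match="single site|two sites"):
        fit_lmm(SPEC, df)


def test_rank_deficient_design_names_aliased_terms():
    df = _simulate(1)
    df["x3"] = df["x2"]  # exact alias
    spec = ModelSpec(response="resp", fixed=("x1", "x2", "x3"))
    with pytest.raises(ValueError, match="x3|x2"):
        fit_lmm(spec, df)


def test_model_spec_from_string():
    spec = ModelSpec.from_string("logSi ~ NPK + soilN + NPK:soilN + (1|site)")
    assert spec.response == "si" and spec.log_response
    assert spec.fixed == ("npk", "soil_n")
    assert spec.interactions == (("npk", "soil_n"),)
    star = ModelSpec.from_string("logSi ~ NPK * soilN")
    assert star.fixed == ("npk", "soil_n") and star.interactions == (("npk", "soil_n"),)
    with pytest.raises(ValueError, match="unknown variable"):
        ModelSpec.from_string("logSi ~ biomass")
    with pytest.raises(ValueError, match="interaction"):
        ModelSpec(fixed=("npk",), interactions=(("npk", "soil_n"),))


# ---------------------------------------------------------------------------
# adjusted means

def test_adjusted_means_equal_group_means_in_balanced_one_factor():
    rng = np.random.default_rng(3)
    rows = []
    for s in range(4):
        for npk in (0, 1):
            for _ in range(5):
                rows.append({"site_id": f"S{s}", "npk": npk,
                             "resp": np.exp(rng.normal(0.5 - 0.3 * npk, 0.2))})
    df = pd.DataFrame(rows)
    spec = ModelSpec(response="resp", fixed=("npk",))
    fit = fit_lmm(spec, df)
    means = adjusted_means(fit, "npk")
    logresp = np.log(df["resp"])
    for lev in (0, 1):
        raw = np.exp(logresp[df["npk"] == lev].mean())
        assert means[lev][0] == pytest.approx(raw, rel=1e-8)


def test_adjusted_means_requires_factor_in_model(small_dataset):
    samples, sites = small_dataset
    fit = fit_lmm(ModelSpec(fixed=("npk",)), samples, sites)
    with pytest.raises(ValueError, match="fence"):
        adjusted_means(fit, "fence")


def test_adjusted_means_missing_level_rejected():
    df = _simulate(2)
    spec = ModelSpec(response="resp", fixed=("x1",))
    fit = fit_lmm(spec, df)
    # emulate prediction-time data from which one design level is absent
    fit._design = fit._design[fit._design["x1"] == 1]
    with pytest.raises(ValueError, match="level"):
        adjusted_means(fit, "x1")


# ---------------------------------------------------------------------------
# R2

def test_r2_closed_forms():
    assert r2_components(1.0, 1.0, 2.0) == (0.25, 0.50)
    r2m, r2c = r2_components(0.0, 1.0, 2.0)
    assert r2m == 0.0
    assert r2c == pytest.approx(1.0 / 3.0)


def test_r2_ordering_and_equality_condition(small_dataset):
    samples, sites = small_dataset
    fit = fit_lmm(ModelSpec(fixed=("npk",)), samples, sites)
    r2m, r2c = r2_nakagawa(fit)
    assert 0 <= r2m <= r2c <= 1
    assert (r2m, r2c) == (fit.r2_marginal, fit.r2_conditional)
    # equality iff no between-site variance
    assert r2_components(0.5, 0.0, 1.0)[0] == r2_components(0.5, 0.0, 1.0)[1]


def test_r2_recovery_from_known_components():
    """Variance components chosen for R2m=0.23, R2c=0.66 are recovered."""
    b = 2 * np.sqrt(0.23 / 0.34)      # fixed-effect variance b^2/4
    sd_site = np.sqrt(0.43 / 0.34)    # relative to resid var 1
    rng = np.random.default_rng(12)
    r2ms, r2cs = [], []
    for _ in range(30):
        rows = []
        for s in range(17):
            a = rng.normal(0, sd_site)
            for j in range(14):
                x = j % 2
                rows.append({"site_id": f"S{s}", "npk": x,
                             "resp": np.exp(b * x + a + rng.normal(0, 1.0))})
        df = pd.DataFrame(rows)
        fit = fit_lmm(ModelSpec(response="resp", fixed=("npk",)), df)
        r2ms.append(fit.r2_marginal)
        r2cs.append(fit.r2_conditional)
    assert abs(np.mean(r2ms) - 0.23) < 0.08
    assert abs(np.mean(r2cs) - 0.66) < 0.08


# ---------------------------------------------------------------------------
# diagnostics

def test_anderson_darling_level():
    """Nominal size: normal data rejected at 5% about 5% of the time."""
    rng = np.random.default_rng(0)
    ok = sum(anderson_darling(rng.normal(size=10_000))[1] > 0.05
             for _ in range(500))
    assert ok >= 0.94 * 500


def test_anderson_darling_detects_lognormal():
    rng = np.random.default_rng(1)
    a, p = anderson_darling(np.exp(rng.normal(size=1000)))
    assert p < 1e-3 and a > 1.0


def test_ncv_power_under_proportional_variance():
    """Variance growing with the mean is detected with power >= 0.8 at n=500."""
    rng = np.random.default_rng(2)
    hits = 0
    reps = 200
    for _ in range(reps):
        fitted = rng.uniform(1.0, 5.0, 500)
        resid = rng.normal(0.0, np.sqrt(fitted))
        chisq, p = ncv_test(resid, fitted)
        hits += p < 0.05
    assert hits / reps >= 0.8


def test_ncv_level_under_homoscedasticity():
    rng = np.random.default_rng(3)
    hits = sum(ncv_test(rng.normal(size=300), rng.uniform(0, 1, 300))[1] < 0.05
               for _ in range(300))
    assert hits / 300 < 0.10


def test_diagnostics_bundle_and_errors():
    rng = np.random.default_rng(4)
    x = rng.normal(size=100)
    res = diagnostics(x, fitted=rng.uniform(size=100))
    assert res.ad_statistic >= 0
    assert 0 <= res.ad_pvalue <= 1
    assert res.ncv_pvalue is not None
    with pytest.raises(ValueError, match="constant"):
        diagnostics(np.ones(50))
    with pytest.raises(ValueError, match="at least 8"):
        diagnostics(np.arange(5.0))
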