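"""Random-intercept linear mixed models for plot-level leaf chemistry.

The model for observation *j* in site *s* is::

    y_sj = x_sj' beta + a_s + e_sj,   a_s ~ N(0, sigma2_site),
                                      e_sj ~ N(0, sigma2_resid)

with the response typically log leaf Si (% dry weight) and fixed effects
drawn from the experimental treatments (NPK, FENCE) and site covariates
(MAP, MAT, PET, sand, pH, OM, soil C, soil N, grazing index).

Estimation profiles the variance ratio ``lambda = sigma2_site/sigma2_resid``:
for fixed lambda the GLS coefficients and the residual variance have closed
forms (the marginal covariance is block diagonal with compound-symmetric
blocks), so REML or ML reduces to a one-dimensional optimization over
log-lambda.  The restricted likelihood includes all constant terms, so values
are directly comparable with textbook formulas and other software.

Also provided: adjusted (population-level) treatment means back-transformed
to the % dry-weight scale, marginal/conditional R2 in the
Nakagawa-Schielzeth sense, an Anderson-Darling normality check with the
estimated-parameter correction, and a score test for non-constant variance
(squared standardized residuals regressed on fitted values, chi2 with 1 df).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "DiagnosticsResult",
    "fit_lmm",
    "adjusted_means",
    "r2_nakagawa",
    "r2_components",
    "diagnostics",
    "anderson_darling",
    "ncv_test",
]

#: canonical predictor columns available after merging samples with sites
PREDICTORS = (
    "npk",
    "fence",
    "map",
    "mat",
    "pet",
    "sand",
    "ph",
    "om",
    "soil_c",
    "soil_n",
    "grazing_index",
)

_ALIASES = {
    "npk": "npk",
    "fence": "fence",
    "map": "map",
    "mat": "mat",
    "pet": "pet",
    "sand": "sand",
    "ph": "ph",
    "om": "om",
    "soilc": "soil_c",
    "soiln": "soil_n",
    "grazing": "grazing_index",
    "grazingindex": "grazing_index",
    "si": "si",
    "c": "c",
    "n": "n",
    "p": "p",
    "k": "k",
    "ca": "ca",
    "mg": "mg",
}


def _canonical(name: str) -> str:
    key = re.sub(r"[\s_]+", "", name.strip().lower())
    if key not in _ALIASES:
        raise ValueError(f"unknown variable '{name}'")
    return _ALIASES[key]


@dataclass(frozen=True)
class ModelSpec:
    """A model formula: response, fixed terms, and the (implicit) site intercept.

    ``fixed`` holds main-effect column names; ``interactions`` holds pairs of
    main effects whose product enters the design.  The site random intercept
    is always present.
    """

    response: str = "si"
    log_response: bool = True
    fixed: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        terms = list(self.fixed) + [f"{a}:{b}" for a, b in self.interactions]
        if len(set(terms)) != len(terms):
            raise ValueError(f"duplicate terms in model spec: {terms}")
        for a, b in self.interactions:
            if a not in self.fixed or b not in self.fixed:
                raise ValueError(
                    f"interaction {a}:{b} requires both main effects in the model"
                )

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.fixed) + tuple(f"{a}:{b}" for a, b in self.interactions)

    def label(self) -> str:
        resp = f"log{self.response.capitalize()}" if self.log_response else self.response
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{resp} ~ {rhs} + (1|site)"

    @classmethod
    def from_string(cls, formula: str) -> "ModelSpec":
        """Parse e.g. ``"logSi ~ NPK + soilN + NPK:soilN + (1|site)"``."""
        lhs, _, rhs = formula.partition("~")
        lhs = lhs.strip()
        log_response = lhs.lower().startswith("log")
        response = _canonical(lhs[3:] if log_response else lhs)
        fixed: list[str] = []
        inters: list[tuple[str, str]] = []
        for tok in rhs.split("+"):
            tok = tok.strip()
            if not tok or tok == "1" or tok.startswith("("):
                continue  # random intercept is implicit
            if "*" in tok:
                a, b = (_canonical(t) for t in tok.split("*"))
                for m in (a, b):
                    if m not in fixed:
                        fixed.append(m)
                inters.append((a, b))
            elif ":" in tok:
                a, b = (_canonical(t) for t in tok.split(":"))
                inters.append((a, b))
            else:
                m = _canonical(tok)
                if m not in fixed:
                    fixed.append(m)
        return cls(response=response, log_response=log_response,
                   fixed=tuple(fixed), interactions=tuple(inters))


@dataclass
class MixedModelFit:
    spec: ModelSpec
    coefficients: pd.DataFrame  # index: term; columns: estimate, se, t, p
    sigma2_site: float
    sigma2_resid: float
    sigma2_fixed: float
    loglik: float
    loglik_ml: float
    aic: float
    df: int
    method: str
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    # private state used by adjusted_means / diagnostics
    _design: pd.DataFrame = field(repr=False, default=None)
    _beta: np.ndarray = field(repr=False, default=None)
    _cov_beta: np.ndarray = field(repr=False, default=None)
    _colnames: list = field(repr=False, default=None)
    _fitted: np.ndarray = field(repr=False, default=None)
    _residuals: np.ndarray = field(repr=False, default=None)

    @property
    def fitted(self) -> np.ndarray:
        """Conditional fitted values (fixed part plus site BLUPs)."""
        return self._fitted

    @property
    def residuals(self) -> np.ndarray:
        return self._residuals


@dataclass
class DiagnosticsResult:
    ad_statistic: float
    ad_pvalue: float
    ncv_chisq: float | None = None
    ncv_pvalue: float | None = None


# ---------------------------------------------------------------------------
# design construction

def build_design(spec: ModelSpec, samples: pd.DataFrame, sites: pd.DataFrame | None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, pd.DataFrame]:
    """Merge site covariates onto samples and build (X, y, groups)."""
    data = samples
    if sites is not None:
        data = samples.merge(sites, on="site_id", how="left", validate="many_to_one",
                             suffixes=("", "_site"))
    y = data[spec.response].to_numpy(dtype=float)
    if spec.log_response:
        if (y <= 0).any():
            raise ValueError("log response requires strictly positive concentrations")
        y = np.log(y)
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for t in spec.terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float))
        else:
            cols.append(data[t].to_numpy(dtype=float))
        names.append(t)
    X = np.column_stack(cols)
    groups = pd.factorize(data["site_id"])[0]
    return X, y, groups, names, data


def _check_rank(X: np.ndarray, names: list) -> None:
    # pivoted QR flags aliased columns by near-zero diagonal of R
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(d)) if d[i] <= tol]
    if bad:
        raise ValueError(f"rank-deficient fixed-effect design; aliased terms: {bad}")


# ---------------------------------------------------------------------------
# profiled likelihood

def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-site sufficient statistics for the compound-symmetric likelihood."""
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    _, starts = np.unique(gs, return_index=True)
    bounds = np.append(starts, len(gs))
    xtx = Xs.T @ Xs
    xty = Xs.T @ ys
    yty = float(ys @ ys)
    sx, sy, ns = [], [], []
    for i in range(len(starts)):
        sl = slice(bounds[i], bounds[i + 1])
        sx.append(Xs[sl].sum(axis=0))
        sy.append(float(ys[sl].sum()))
        ns.append(bounds[i + 1] - bounds[i])
    return xtx, xty, yty, np.array(sx), np.array(sy), np.array(ns, dtype=float)


def _profile(lam: float, stats_: tuple, n: int, p: int, reml: bool):
    """Profiled (restricted) log-likelihood and GLS solution at ratio ``lam``."""
    xtx, xty, yty, sx, sy, ns = stats_
    c = lam / (1.0 + lam * ns)  # shrinkage weight per site
    xtwx = xtx - (sx * c[:, None]).T @ sx
    xtwy = xty - sx.T @ (c * sy)
    ytwy = yty - float(c @ (sy * sy))
    beta = np.linalg.solve(xtwx, xtwy)
    q = max(ytwy - float(beta @ xtwy), 1e-300)  # r' W r at the GLS solution
    logdet_v = float(np.log1p(lam * ns).sum())
    if reml:
        dof = n - p
        s2 = q / dof
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * (dof * math.log(2 * math.pi) + dof * math.log(s2)
                     + logdet_v + logdet_xtwx + dof)
    else:
        s2 = q / n
        ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(s2) + logdet_v + n)
    return ll, beta, s2, xtwx


def _optimize_lambda(stats_: tuple, n: int, p: int, reml: bool) -> float:
    def neg(t: float) -> float:
        return -_profile(math.exp(t), stats_, n, p, reml)[0]

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg(t) for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    best_t = float(res.x)
    lam = math.exp(best_t)
    # boundary: sigma2_site = 0 may beat any interior point
    ll_zero = _profile(0.0, stats_, n, p, reml)[0]
    if ll_zero >= -res.fun:
        return 0.0
    return lam


def fit_lmm(spec: ModelSpec, samples: pd.DataFrame, sites: pd.DataFrame | None = None,
            method: str = "reml") -> MixedModelFit:
    """Fit the random-intercept model by profiled REML (default) or ML.

    AIC is always computed from the ML likelihood (candidate models differ in
    their fixed effects), with ``df`` counting the intercept, fixed terms and
    the two variance parameters.
    """
    method = method.lower()
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    X, y, groups, names, data = build_design(spec, samples, sites)
    n, p = X.shape
    if len(np.unique(groups)) < 2:
        raise ValueError("at least two sites are required: the site random "
                         "intercept is unidentifiable from a single site")
    _check_rank(X, names)
    stats_ = _group_stats(X, y, groups)

    reml = method == "reml"
    lam = _optimize_lambda(stats_, n, p, reml)
    ll, beta, s2, xtwx = _profile(lam, stats_, n, p, reml)
    if reml:
        lam_ml = _optimize_lambda(stats_, n, p, False)
        ll_ml = _profile(lam_ml, stats_, n, p, False)[0]
    else:
        ll_ml = ll

    cov_beta = s2 * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    df_resid = n - p
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    coef = pd.DataFrame({"estimate": beta, "se": se, "t": tvals, "p": pvals}, index=names)

    sigma2_site = lam * s2
    sigma2_resid = s2
    eta = X @ beta
    sigma2_fixed = float(np.var(eta, ddof=1)) if n > 1 else 0.0
    r2m, r2c = r2_components(sigma2_fixed, sigma2_site, sigma2_resid)
    df_model = p + 2
    aic = -2.0 * ll_ml + 2.0 * df_model

    # site BLUPs -> conditional fitted values and residuals
    marg = y - eta
    blup = np.zeros(n)
    for g in np.unique(groups):
        mask = groups == g
        ng = mask.sum()
        blup[mask] = (lam * ng / (1.0 + lam * ng)) * marg[mask].mean()
    fitted = eta + blup

    return MixedModelFit(
        spec=spec, coefficients=coef,
        sigma2_site=sigma2_site, sigma2_resid=sigma2_resid, sigma2_fixed=sigma2_fixed,
        loglik=ll, loglik_ml=ll_ml, aic=aic, df=df_model, method=method,
        r2_marginal=r2m, r2_conditional=r2c, n_obs=n,
        _design=data, _beta=beta, _cov_beta=cov_beta, _colnames=names,
        _fitted=fitted, _residuals=y - fitted,
    )


# ---------------------------------------------------------------------------
# adjusted means

def adjusted_means(fit: MixedModelFit, factor: str) -> dict[int, tuple[float, float]]:
    """Population-level predicted response per factor level, back-transformed.

    Each level's mean is the fixed-effect prediction with ``factor`` set to
    that level and every other term held at its observed average (interaction
    columns involving the factor are recomputed accordingly).  For a
    log-transformed response the mean and its SE are mapped to the
    % dry-weight scale by plain exponentiation (delta method for the SE).
    """
    try:
        factor = _canonical(factor)
    except ValueError:
        pass  # custom column names are allowed if they are model terms
    if factor not in fit.spec.fixed:
        raise ValueError(f"factor '{factor}' is not a term of the fitted model")
    data = fit._design
    levels = sorted(pd.unique(data[factor]))
    if len(levels) < 2:
        raise ValueError(f"factor '{factor}' has a single observed level {levels}; "
                         "adjusted means need every design level present")
    out: dict = {}
    for lev in levels:
        row = []
        for name in fit._colnames:
            if name == "(Intercept)":
                row.append(1.0)
            elif name == factor:
                row.append(float(lev))
            elif ":" in name:
                a, b = name.split(":")
                va = float(lev) if a == factor else float(data[a].mean())
                vb = float(lev) if b == factor else float(data[b].mean())
                row.append(va * vb)
            else:
                row.append(float(data[name].mean()))
        x = np.asarray(row)
        eta = float(x @ fit._beta)
        se = float(np.sqrt(x @ fit._cov_beta @ x))
        if fit.spec.log_response:
            out[lev] = (math.exp(eta), math.exp(eta) * se)
        else:
            out[lev] = (eta, se)
    return out


# ---------------------------------------------------------------------------
# R2 for mixed models

def r2_components(sigma2_fixed: float, sigma2_site: float, sigma2_resid: float
                  ) -> tuple[float, float]:
    """Marginal and conditional R2 from variance components.

    R2m = s2_f / (s2_f + s2_site + s2_resid);
    R2c = (s2_f + s2_site) / (same denominator).
    """
    denom = sigma2_fixed + sigma2_site + sigma2_resid
    if denom <= 0:
        raise ValueError("total variance must be positive")
    return sigma2_fixed / denom, (sigma2_fixed + sigma2_site) / denom


def r2_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    return r2_components(fit.sigma2_fixed, fit.sigma2_site, fit.sigma2_resid)


# ---------------------------------------------------------------------------
# diagnostics

def anderson_darling(x: np.ndarray) -> tuple[float, float]:
    """Anderson-Darling normality test with mean and variance estimated.

    Returns the A statistic and its p-value using the small-sample
    correction ``A* = A (1 + 0.75/n + 2.25/n^2)`` and the standard piecewise
    approximation for the corrected statistic.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError("Anderson-Darling test needs at least 8 observations")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("constant input: normality test undefined")
    z = (x - x.mean()) / s
    logcdf = stats.norm.logcdf(z)
    logsf = stats.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (logcdf + logsf[::-1]))
    a_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a_star + 0.0186 * a_star**2)
    elif a_star > 0.34:
        p = math.exp(0.9177 - 4.279 * a_star - 1.38 * a_star**2)
    elif a_star > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a_star - 59.938 * a_star**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a_star - 223.73 * a_star**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


def ncv_test(residuals: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    """Score test for non-constant error variance against fitted values.

    Squared standardized residuals are regressed on the fitted values; half
    the regression sum of squares is chi-squared with 1 df under
    homoscedasticity.
    """
    e = np.asarray(residuals, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if e.std() == 0 or f.std() == 0:
        raise ValueError("constant residuals or fitted values: test undefined")
    u = e**2 / np.mean(e**2)
    fc = f - f.mean()
    slope = float(fc @ u) / float(fc @ fc)
    ss_reg = slope**2 * float(fc @ fc)
    chisq = ss_reg / 2.0
    return chisq, float(stats.chi2.sf(chisq, 1))


def diagnostics(values: np.ndarray, fitted: np.ndarray | None = None) -> DiagnosticsResult:
    """Run the normality and (optionally) the non-constant-variance checks.

    ``values`` are residuals (or a raw response for the skew check); when
    ``fitted`` is given the variance score test is included.
    """
    a, p = anderson_darling(values)
    res = DiagnosticsResult(ad_statistic=a, ad_pvalue=p)
    if fitted is not None:
        res.ncv_chisq, res.ncv_pvalue = ncv_test(values, fitted)
    return res
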