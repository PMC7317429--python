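"""Per-site Si~C regression slopes and their relation to site precipitation.

Stage one fits an ordinary least-squares line of %Si on %C within each site
(raw percent scale).  Stage two regresses the site slopes on a site
covariate — mean annual precipitation by default — to test whether the
within-site trade-off weakens along the aridity gradient.  A positive
second-stage coefficient means the (negative) Si~C slope moves toward zero
as precipitation increases.

Second-stage inference treats the site slopes as data (first-stage
estimation error is ignored, the conventional two-stage approach); an
optional inverse-variance weighted mode is available and reduces to OLS
when all slope SEs are equal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SiteSlope", "SlopeMapFit", "site_slopes", "slope_vs_map", "slopes_to_frame"]

logger = logging.getLogger(__name__)


@dataclass
class SiteSlope:
    site_id: str
    slope: float
    intercept: float
    se_slope: float
    n_obs: int
    map: float | None = None


@dataclass
class SlopeMapFit:
    covariate: str
    gamma0: float          # intercept
    gamma1: float          # change in Si~C slope per covariate unit
    se_gamma1: float
    p_gamma1: float        # two-sided test of gamma1 = 0 (no climate dependence)
    n_sites: int
    weighted: bool


def site_slopes(samples: pd.DataFrame, sites: pd.DataFrame | None = None,
                response: str = "si", min_n: int = 3,
                controls_only: bool = False) -> list[SiteSlope]:
    """OLS slope of %Si on %C within each site.

    Sites with fewer than ``min_n`` samples or constant %C are skipped with a
    logged warning.  ``controls_only`` restricts to untreated plots.
    """
    data = samples
    if controls_only:
        data = data[(data["npk"] == 0) & (data["fence"] == 0)]
    map_by_site = None
    if sites is not None:
        map_by_site = sites.set_index("site_id")["map"]
    out: list[SiteSlope] = []
    for site_id, grp in data.groupby("site_id", sort=True):
        if len(grp) < min_n:
            logger.warning("site %s skipped: only %d samples (< %d)", site_id, len(grp), min_n)
            continue
        x = grp["c"].to_numpy(dtype=float)
        y = grp[response].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("site %s skipped: constant leaf C", site_id)
            continue
        with warnings.catch_warnings():
            # a perfectly collinear fixture makes stderr 0/0; that's fine
            warnings.simplefilter("ignore", category=RuntimeWarning)
            res = stats.linregress(x, y)
        out.append(SiteSlope(
            site_id=str(site_id), slope=float(res.slope), intercept=float(res.intercept),
            se_slope=float(res.stderr), n_obs=len(grp),
            map=float(map_by_site[site_id]) if map_by_site is not None else None,
        ))
    return out


def slope_vs_map(slopes: list[SiteSlope], sites: pd.DataFrame | None = None,
                 covariate: str = "map", weighted: bool = False) -> SlopeMapFit:
    """Second-stage regression of site slopes on a site covariate.

    ``covariate`` may be any numeric site column (map, mat, pet).  With
    ``weighted=True`` observations are weighted by inverse squared slope SE.
    """
    if sites is not None:
        cov = sites.set_index("site_id")[covariate]
        xs = np.array([cov[s.site_id] for s in slopes], dtype=float)
    else:
        if covariate != "map":
            raise ValueError("pass the sites table to regress on covariates other than map")
        xs = np.array([s.map for s in slopes], dtype=float)
        if np.isnan(xs).any():
            raise ValueError("site slopes lack MAP values; pass the sites table")
    ys = np.array([s.slope for s in slopes], dtype=float)
    if len(ys) < 4:
        raise ValueError(f"second-stage regression needs >= 4 sites, got {len(ys)}")

    if weighted:
        se = np.array([s.se_slope for s in slopes], dtype=float)
        if (se <= 0).any():
            raise ValueError("weighted mode requires positive slope SEs")
        w = 1.0 / se**2
    else:
        w = np.ones_like(ys)
    W = np.diag(w)
    X = np.column_stack([np.ones_like(xs), xs])
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ ys)
    resid = ys - X @ beta
    dof = len(ys) - 2
    s2 = float(resid @ (w * resid)) / dof
    cov_beta = s2 * np.linalg.inv(xtwx)
    se1 = float(np.sqrt(cov_beta[1, 1]))
    if se1 == 0:
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        p = float(2 * stats.t.sf(abs(beta[1]) / se1, dof))
    return SlopeMapFit(covariate=covariate, gamma0=float(beta[0]), gamma1=float(beta[1]),
                       se_gamma1=se1, p_gamma1=p, n_sites=len(ys), weighted=weighted)


def slopes_to_frame(slopes: list[SiteSlope]) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_id": s.site_id, "slope": s.slope, "intercept": s.intercept,
        "se": s.se_slope, "n": s.n_obs, "map": s.map,
    } for s in slopes])
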