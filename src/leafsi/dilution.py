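"""Permutation null model for compositional "stoichiometric dilution".

Because element concentrations are percentages of dry mass, any rise in %C
forces every other element's concentration down (closure).  To ask whether
leaf Si declines with C *more* than closure alone predicts, the observed
slope of the focal element on %C (from a random-intercept mixed model with
site as the grouping factor) is compared with a null distribution built by
replacing, independently for every sample, the focal response with the
same sample's concentration of one of the five nonfocal elements chosen
uniformly at random; the same mixed model is refit and its %C slope
recorded.  Repeating R times (default 999) yields the null distribution of
slopes expected under dilution alone.

An observed slope in the lower tail (more negative than the null) indicates
a genuine trade-off with carbon beyond closure; essential macronutrients
are expected to sit inside the null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import ModelSpec, fit_lmm
from .synthetic import ELEMENTS

__all__ = ["NullSlopeDistribution", "dilution_test", "run_all_elements", "results_to_frame"]


@dataclass
class NullSlopeDistribution:
    focal_element: str
    observed_slope: float
    null_slopes: np.ndarray
    p_lower: float
    p_upper: float
    seed: int
    n_obs: int

    @property
    def null_mean(self) -> float:
        return float(self.null_slopes.mean())

    def null_quantiles(self, q=(0.025, 0.975)) -> tuple[float, ...]:
        return tuple(float(v) for v in np.quantile(self.null_slopes, q))


def _c_slope(response: np.ndarray, samples: pd.DataFrame, log_response: bool) -> float:
    df = samples[["site_id", "c"]].copy()
    df["resp"] = response
    spec = ModelSpec(response="resp", log_response=log_response, fixed=("c",))
    fit = fit_lmm(spec, df, sites=None)
    return float(fit.coefficients.loc["c", "estimate"])


def _null_slopes_batch(Y: np.ndarray, c: np.ndarray, groups: np.ndarray,
                       n_lambda: int = 161) -> np.ndarray:
    """REML %C slope of every column of ``Y`` under the random-intercept model.

    All replicate responses share the fixed design (intercept, %C), so the
    profiled restricted likelihood is evaluated on one dense grid of the
    variance ratio for every replicate at once; each replicate's slope is
    taken at its own grid optimum.  The grid (log-spaced, plus the boundary
    at ratio zero) is fine enough that the slope error from discretization
    is far below Monte-Carlo noise.
    """
    n, R = Y.shape
    X = np.column_stack([np.ones(n), c])
    p = 2
    sites, inv = np.unique(groups, return_inverse=True)
    m = len(sites)
    ns = np.bincount(inv, minlength=m).astype(float)
    # per-site sums
    SX = np.zeros((m, p))
    for j in range(p):
        SX[:, j] = np.bincount(inv, weights=X[:, j], minlength=m)
    SY = np.zeros((m, R))
    for r in range(R):
        SY[:, r] = np.bincount(inv, weights=Y[:, r], minlength=m)
    xtx = X.T @ X
    xty = X.T @ Y              # p x R
    yty = (Y * Y).sum(axis=0)  # R

    lambdas = np.concatenate([[0.0], np.geomspace(1e-6, 1e4, n_lambda - 1)])
    dof = n - p
    best_ll = np.full(R, -np.inf)
    best_slope = np.zeros(R)
    for lam in lambdas:
        cshr = lam / (1.0 + lam * ns)  # m
        xtwx = xtx - (SX * cshr[:, None]).T @ SX
        xtwy = xty - SX.T @ (cshr[:, None] * SY)
        ytwy = yty - (cshr[:, None] * SY * SY).sum(axis=0)
        det = xtwx[0, 0] * xtwx[1, 1] - xtwx[0, 1] ** 2
        beta0 = (xtwx[1, 1] * xtwy[0] - xtwx[0, 1] * xtwy[1]) / det
        beta1 = (xtwx[0, 0] * xtwy[1] - xtwx[0, 1] * xtwy[0]) / det
        q = np.maximum(ytwy - (beta0 * xtwy[0] + beta1 * xtwy[1]), 1e-300)
        logdet_v = float(np.log1p(lam * ns).sum())
        ll = -0.5 * (dof * np.log(2 * np.pi * q / dof) + logdet_v
                     + math.log(det) + dof)
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best_slope = np.where(better, beta1, best_slope)
    return best_slope


def dilution_test(samples: pd.DataFrame, focal: str, R: int = 999,
                  seed: int = 0, log_response: bool = False) -> NullSlopeDistribution:
    """Test the focal element's %C slope against the dilution null.

    Empirical p-values use the add-one correction,
    ``p_lower = (1 + #{null <= observed}) / (R + 1)``; both tails are
    reported.  Determinism is guaranteed by ``seed`` and is invariant to
    sample order (responses are drawn in the table's row order after a
    stable sort on site and block labels).
    """
    focal = focal.lower()
    if focal not in ELEMENTS:
        raise ValueError(f"focal element must be one of {ELEMENTS}, got '{focal}'")
    if samples["site_id"].nunique() < 2:
        raise ValueError("dilution test needs at least two sites")
    for e in ELEMENTS:
        if e not in samples.columns or samples[e].isna().any():
            raise ValueError(f"missing concentration values for element '{e}'")
    if R < 99:
        warnings.warn(f"R={R} gives a very coarse null distribution; use R >= 99",
                      stacklevel=2)

    samples = samples.sort_values(["site_id", "block_id", "npk", "fence"]
                                  if {"block_id", "npk", "fence"} <= set(samples.columns)
                                  else ["site_id"], kind="stable").reset_index(drop=True)
    nonfocal = [e for e in ELEMENTS if e != focal]
    observed = _c_slope(samples[focal].to_numpy(dtype=float), samples, log_response)

    rng = np.random.default_rng(seed)
    M = samples[nonfocal].to_numpy(dtype=float)  # n x 5
    n = len(samples)
    picks = rng.integers(0, len(nonfocal), size=(R, n))
    Y = M[np.arange(n), picks].T  # n x R
    if log_response:
        Y = np.log(Y)
    groups = pd.factorize(samples["site_id"])[0]
    null_slopes = _null_slopes_batch(Y, samples["c"].to_numpy(dtype=float), groups)

    p_lower = (1 + int((null_slopes <= observed).sum())) / (R + 1)
    p_upper = (1 + int((null_slopes >= observed).sum())) / (R + 1)
    return NullSlopeDistribution(
        focal_element=focal, observed_slope=observed, null_slopes=null_slopes,
        p_lower=p_lower, p_upper=p_upper, seed=seed, n_obs=n,
    )


def run_all_elements(samples: pd.DataFrame, R: int = 999, seed: int = 0,
                     log_response: bool = False) -> dict[str, NullSlopeDistribution]:
    """Dilution test for each of the six elements, on independent substreams."""
    children = np.random.SeedSequence(seed).spawn(len(ELEMENTS))
    out = {}
    for elem, child in zip(ELEMENTS, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out[elem] = dilution_test(samples, elem, R=R, seed=sub_seed,
                                  log_response=log_response)
    return out


def results_to_frame(results: dict[str, NullSlopeDistribution]) -> pd.DataFrame:
    rows = []
    for elem, res in results.items():
        lo, hi = res.null_quantiles()
        rows.append({
            "element": elem,
            "observed_slope": res.observed_slope,
            "null_mean": res.null_mean,
            "null_q025": lo,
            "null_q975": hi,
            "p_lower": res.p_lower,
            "p_upper": res.p_upper,
            "n": res.n_obs,
            "R": len(res.null_slopes),
        })
    return pd.DataFrame(rows)
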