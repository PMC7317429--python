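"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leafsi import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic experiment (17 sites)."""
    return generate_dataset(GeneratorConfig(seed=11))


@pytest.fixture()
def small_dataset():
    """A small experiment for fast model fits."""
    return generate_dataset(GeneratorConfig(seed=5, n_sites=6))


# ---------------------------------------------------------------------------
# independent oracles

def reml_loglik_dense(y, X, groups, s2_site, s2_resid, reml=True):
    """Textbook (restricted) log-likelihood via dense marginal covariance.

    Deliberately brute-force: builds V = s2_resid*I + s2_site*ZZ' explicitly
    and evaluates the closed-form Gaussian (restricted) likelihood with GLS
    coefficients profiled out.  Independent of the package's profiled,
    group-structured implementation.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    Z = (np.asarray(groups)[:, None] == np.unique(groups)[None, :]).astype(float)
    V = s2_resid * np.eye(n) + s2_site * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    _, logdet_v = np.linalg.slogdet(V)
    if reml:
        _, logdet_x = np.linalg.slogdet(XtViX)
        return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_x + quad)
    return -0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)


def grid_search_loglik(y, X, groups, reml=True, size=25):
    """Maximize the dense likelihood by iteratively refined 2-D grid search.

    The final grid spacing is fine enough that the grid optimum sits within
    ~1e-5 log-likelihood units of the continuous optimum.
    """
    lo = (1e-7, 1e-4)
    hi = (5.0, 5.0)
    best = (-np.inf, None, None)
    for span in (None, 3.0, 1.25, 1.02):
        if span is not None:
            _, a0, e0 = best
            lo = (a0 / span, e0 / span)
            hi = (a0 * span, e0 * span)
        g1 = np.geomspace(lo[0], hi[0], size)
        g2 = np.geomspace(lo[1], hi[1], size)
        for a in g1:
            for e in g2:
                ll = reml_loglik_dense(y, X, groups, a, e, reml)
                if ll > best[0]:
                    best = (ll, a, e)
    return best


def brute_force_best_split(X, y, min_leaf):
    """Exhaustive scan of every predictor and every candidate cut."""
    n, p = X.shape
    parent = float(((y - y.mean()) ** 2).sum())
    best = None
    for j in range(p):
        xs = np.unique(X[:, j])
        for a, b in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (a + b)
            m = X[:, j] < thr
            n1 = int(m.sum())
            if n1 < min_leaf or n - n1 < min_leaf:
                continue
            sse = (((y[m] - y[m].mean()) ** 2).sum()
                   + ((y[~m] - y[~m].mean()) ** 2).sum())
            red = parent - sse
            if best is None or red > best[2] + 1e-12 * max(parent, 1.0):
                best = (j, thr, red)
    return best


def brute_force_kennard_stone(X, n_select):
    """Naive max-min greedy selection (double loop), indices into X."""
    X = X - X.mean(axis=0)
    n = len(X)
    d = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    besti, bestj, bestd = 0, 1, -1.0
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > bestd + 1e-12:
                besti, bestj, bestd = i, j, d[i, j]
    sel = [besti, bestj]
    while len(sel) < n_select:
        cand_best, cand_d = None, -1.0
        for i in range(n):
            if i in sel:
                continue
            dmin = min(d[i, j] for j in sel)
            if dmin > cand_d + 1e-12:
                cand_best, cand_d = i, dmin
        sel.append(cand_best)
    return sel
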