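"""AIC multimodel inference over candidate mixed models.

Candidates are all subsets of the main-effect predictors plus whitelisted
two-way interactions (an interaction enters a model only when both parents
are present).  Models are ranked by AIC from ML fits; delta-AIC below 2
marks models statistically equivalent to the best, above 7 a poor fit.
Akaike weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` are always
normalized over the set that was passed in, so full-set versus subset
semantics are the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .lmm import MixedModelFit, ModelSpec, fit_lmm

__all__ = ["ModelScore", "enumerate_candidates", "rank_models", "fit_candidates",
           "scores_to_frame", "DELTA_EQUIVALENT", "DELTA_POOR"]

DELTA_EQUIVALENT = 2.0
DELTA_POOR = 7.0


@dataclass
class ModelScore:
    spec: ModelSpec
    aic: float
    delta_aic: float
    weight: float
    r2_marginal: float
    r2_conditional: float
    df: int
    equivalent: bool
    poor: bool


def enumerate_candidates(
    predictors: list[str],
    interaction_whitelist: list[tuple[str, str]] = (),
    response: str = "si",
    log_response: bool = True,
) -> list[ModelSpec]:
    """All additive subsets of ``predictors`` plus whitelisted interactions.

    The null (intercept-only) model is always included.  Each interaction is
    added, on top of the corresponding additive model, only when both parent
    effects are in the subset.  Order is deterministic: by number of terms,
    then lexicographic.
    """
    if not predictors:
        raise ValueError("predictor list must be nonempty")
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictors")
    for a, b in interaction_whitelist:
        if a not in predictors or b not in predictors:
            raise ValueError(f"interaction {a}:{b} references a predictor not in the list")

    specs: list[ModelSpec] = []
    for r in range(len(predictors) + 1):
        for subset in combinations(predictors, r):
            specs.append(ModelSpec(response=response, log_response=log_response,
                                   fixed=subset))
            eligible = [(a, b) for a, b in interaction_whitelist
                        if a in subset and b in subset]
            # each nonempty combination of eligible interactions is a candidate
            for k in range(1, len(eligible) + 1):
                for inters in combinations(eligible, k):
                    specs.append(ModelSpec(response=response, log_response=log_response,
                                           fixed=subset, interactions=inters))
    seen = set()
    unique = []
    for s in specs:
        key = (s.fixed, s.interactions)
        if key not in seen:
            seen.add(key)
            unique.append(s)
    unique.sort(key=lambda s: (len(s.terms), s.label()))
    return unique


def rank_models(fits: list[MixedModelFit]) -> list[ModelScore]:
    """Rank fitted candidates by AIC; attach delta-AIC, weights and flags.

    Ties in AIC are broken by fewer parameters, then by the spec label.
    """
    if not fits:
        raise ValueError("empty fit list")
    methods = {f.method for f in fits}
    if len(methods) > 1:
        raise ValueError(f"mixed estimation methods in one candidate set: {methods}")
    responses = {(f.spec.response, f.spec.log_response) for f in fits}
    if len(responses) > 1:
        raise ValueError("all candidate models must share the same response")

    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    order = sorted(range(len(fits)),
                   key=lambda i: (aics[i], fits[i].df, fits[i].spec.label()))
    return [
        ModelScore(
            spec=fits[i].spec, aic=float(aics[i]), delta_aic=float(delta[i]),
            weight=float(w[i]), r2_marginal=fits[i].r2_marginal,
            r2_conditional=fits[i].r2_conditional, df=fits[i].df,
            equivalent=bool(delta[i] < DELTA_EQUIVALENT),
            poor=bool(delta[i] > DELTA_POOR),
        )
        for i in order
    ]


def fit_candidates(specs: list[ModelSpec], samples: pd.DataFrame,
                   sites: pd.DataFrame, method: str = "ml") -> list[MixedModelFit]:
    """Fit every candidate; ML by default so AICs are comparable."""
    return [fit_lmm(s, samples, sites, method=method) for s in specs]


def scores_to_frame(scores: list[ModelScore]) -> pd.DataFrame:
    """Ranked table with the conventional columns (model, df, AIC, dAIC, w, R2)."""
    return pd.DataFrame(
        {
            "model": [s.spec.label() for s in scores],
            "df": [s.df for s in scores],
            "aic": [s.aic for s in scores],
            "delta_aic": [s.delta_aic for s in scores],
            "weight": [s.weight for s in scores],
            "r2_marginal": [s.r2_marginal for s in scores],
            "r2_conditional": [s.r2_conditional for s in scores],
            "equivalent": [s.equivalent for s in scores],
            "poor": [s.poor for s in scores],
        }
    )


def write_scores(scores: list[ModelScore], path: str | Path) -> Path:
    path = Path(path)
    scores_to_frame(scores).to_csv(path, index=False)
    return path
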