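"""Canonical simulation-study configurations for validating the pipeline.

Each function returns a :class:`~leafsi.synthetic.GeneratorConfig` describing
one study condition used by the validation experiments (parameter-recovery
simulations, null-model calibration, threshold recovery).  Centralizing them
keeps the test suite and the reproduction script on identical conditions;
the rationale for each choice is documented in ``docs/methods.md``.
"""

from __future__ import annotations

import math

from .synthetic import GeneratorConfig

__all__ = [
    "npk_recovery",
    "adjusted_means_recovery",
    "dilution_closure",
    "dilution_tradeoff",
    "aridity_gradient",
    "threshold_structure",
]

#: log-scale Si~C slope matching the pure-closure decline of all elements
CLOSURE_SLOPE = -1.0 / 57.0


def npk_recovery(seed: int) -> GeneratorConfig:
    """Two-way design with beta_NPK = -0.49 and noise giving SE ~ 0.11.

    The soil-N range sits below the threshold (no attenuated plots) and the
    Si~C coupling is off, so the residual SD maps directly onto the
    coefficient's standard error.
    """
    return GeneratorConfig(seed=seed, beta_npk=-0.49, resid_sd=0.60,
                           soil_n_range=(0.05, 0.30),
                           slope_intercept=0.0, slope_per_map=0.0)


def adjusted_means_recovery(seed: int) -> GeneratorConfig:
    """Control mean 1.72 %dw and fertilized mean 1.27 %dw on the Si scale."""
    return GeneratorConfig(seed=seed, mu0=math.log(1.72),
                           beta_npk=math.log(1.27 / 1.72),
                           soil_n_range=(0.05, 0.30),
                           slope_intercept=0.0, slope_per_map=0.0)


def _exchangeable(seed: int, slope_intercept: float) -> GeneratorConfig:
    # equal element baselines make the focal element exchangeable with the
    # nonfocal pool, the condition under which the permutation null is
    # calibrated (see docs/methods.md)
    return GeneratorConfig(seed=seed, beta_npk=0.0, mu0=0.0, site_sd=0.1,
                           resid_sd=0.2, slope_intercept=slope_intercept,
                           slope_per_map=0.0,
                           element_bases={e: 1.0 for e in ("n", "p", "k", "ca", "mg")})


def dilution_closure(seed: int) -> GeneratorConfig:
    """Pure closure: Si declines with C exactly as the other elements do."""
    return _exchangeable(seed, CLOSURE_SLOPE)


def dilution_tradeoff(seed: int) -> GeneratorConfig:
    """A genuine Si-C trade-off much steeper than closure alone."""
    return _exchangeable(seed, -0.12)


def aridity_gradient(seed: int) -> GeneratorConfig:
    """Si~C slope strongly negative at arid sites, ~zero at ~1900 mm/yr."""
    return GeneratorConfig(seed=seed, resid_sd=0.25, slope_intercept=-0.2,
                           slope_per_map=1.04e-4, soil_n_range=(0.05, 0.30))


def threshold_structure(seed: int) -> GeneratorConfig:
    """Default conditions: the soil-N threshold mechanism at 0.43 %N."""
    return GeneratorConfig(seed=seed)
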