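"""Synthetic data emulating a distributed grassland fertilization experiment.

The generator reproduces the statistical structure of a multi-site
nutrient-addition x grazer-exclusion (NPK x FENCE) factorial: sites spanning
a broad precipitation/temperature gradient, 2-5 blocks per site, one grass
composite sample per plot, and leaf chemistry (Si, C and the macronutrients
N, P, K, Ca, Mg in % dry weight).

Leaf Si is generated on the natural-log scale::

    log Si = mu0 - drop*[soilN > thr] + a_site + beta_npk*NPK
             + beta_fence*FENCE + slope(MAP)*(C - c_mid) + eps

with ``a_site ~ N(0, site_sd)``, ``eps ~ N(0, resid_sd)`` and the within-site
Si~C slope a linear function of site precipitation,
``slope(MAP) = slope_intercept + slope_per_map * MAP``.  Soil nitrogen is
measured (and varies) at the plot scale: each plot's soil N scatters around
its site mean with SD ``soil_n_plot_sd``.  Where local soil N exceeds
``soil_n_threshold`` the NPK effect and the Si variance contributions are
attenuated (multiplied by ``attenuation``) and the baseline is lowered by
``threshold_baseline_drop``, so leaf Si is uniformly low with little
variation above the threshold.

Macronutrients follow a pure "stoichiometric dilution" mechanism: each
element is its baseline concentration scaled by ``(100 - C)/(100 - c_mid)``
(percent closure) times multiplicative log-normal noise, so every element's
expected concentration declines as %C rises purely because percentages are
closed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneratorConfig",
    "generate_dataset",
    "write_tables",
    "read_tables",
    "validate_samples",
    "validate_sites",
    "TableFormatError",
]

MACRO_ELEMENTS = ("n", "p", "k", "ca", "mg")
ELEMENTS = ("si",) + MACRO_ELEMENTS
SAMPLE_COLUMNS = ["site_id", "block_id", "npk", "fence", "si", "c", "n", "p", "k", "ca", "mg"]
# plot-level soil N measurements ride along when present (soil data are
# collected per plot in the field design the generator emulates)
OPTIONAL_SAMPLE_COLUMNS = ["soil_n"]
SITE_COLUMNS = ["site_id", "map", "mat", "pet", "soil_n", "soil_c", "ph", "sand", "om", "grazing_index"]


class TableFormatError(ValueError):
    """Raised when an input table violates the expected schema or invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the study conditions: 17 sites, MAP 365-1898 mm/yr,
    MAT 0.3-22.1 C, leaf C uniform in 38-48 %, an NPK effect of -0.49 on
    log Si, and a soil-N threshold at 0.43 % above which Si variation
    collapses.
    """

    n_sites: int = 17
    blocks_per_site: tuple[int, int] = (2, 5)
    map_range: tuple[float, float] = (365.0, 1898.0)
    mat_range: tuple[float, float] = (0.3, 22.1)
    soil_n_range: tuple[float, float] = (0.05, 0.90)
    c_range: tuple[float, float] = (38.0, 48.0)
    mu0: float = math.log(1.72)
    beta_npk: float = -0.49
    beta_fence: float = 0.0
    site_sd: float = 0.35
    resid_sd: float = 0.35
    slope_intercept: float = -0.152
    slope_per_map: float = 8.0e-5
    soil_n_threshold: float = 0.43
    attenuation: float = 0.2
    threshold_baseline_drop: float = 0.9
    element_bases: dict[str, float] = field(
        default_factory=lambda: {"n": 1.5, "p": 0.2, "k": 1.8, "ca": 0.6, "mg": 0.25}
    )
    element_noise_sd: float = 0.2
    soil_n_plot_sd: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        for name in ("map_range", "mat_range", "soil_n_range", "c_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must have lower bound < upper bound, got {(lo, hi)}")
        b_lo, b_hi = self.blocks_per_site
        if not (1 <= b_lo <= b_hi):  # a fixed block count is a valid design
            raise ValueError(f"blocks_per_site must satisfy 1 <= lo <= hi, got {(b_lo, b_hi)}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.site_sd < 0 or self.resid_sd < 0:
            raise ValueError("site_sd and resid_sd must be >= 0")
        if not 0 <= self.attenuation <= 1:
            raise ValueError("attenuation must lie in [0, 1]")
        if self.element_noise_sd < 0:
            raise ValueError("element_noise_sd must be >= 0")
        if self.soil_n_plot_sd < 0:
            raise ValueError("soil_n_plot_sd must be >= 0")
        lo, hi = self.c_range
        if lo <= 0 or hi >= 100:
            raise ValueError("c_range must lie strictly inside (0, 100) % dry weight")
        if set(self.element_bases) != set(MACRO_ELEMENTS):
            raise ValueError(f"element_bases must have keys {MACRO_ELEMENTS}")
        if any(v <= 0 for v in self.element_bases.values()):
            raise ValueError("element baseline concentrations must be positive")
        # feasibility: expected composition must leave room below 100 % even
        # at the top of the carbon range (rough 6-sigma margin on noise)
        margin = sum(self.element_bases.values()) * math.exp(6 * self.element_noise_sd)
        if hi + margin >= 100:
            raise ValueError(
                "infeasible composition: element baselines plus maximal leaf C "
                "can exceed the 100 % dry-weight closure"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a YAML or JSON mapping (JSON is a YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise TableFormatError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TableFormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("blocks_per_site", "map_range", "mat_range", "soil_n_range", "c_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _generate_sites(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_sites
    map_ = rng.uniform(*cfg.map_range, n)
    mat = rng.uniform(*cfg.mat_range, n)
    # PET rises with temperature; keep strictly positive
    pet = np.clip(450.0 + 55.0 * mat + rng.normal(0.0, 120.0, n), 50.0, None)
    soil_n = rng.uniform(*cfg.soil_n_range, n)
    # soil C tracks soil N only loosely (C:N stoichiometry varies across sites)
    soil_c = np.clip(2.0 + soil_n * 6.0 + rng.normal(0.0, 2.0, n), soil_n, 100.0)
    ph = rng.uniform(4.5, 8.5, n)
    sand = rng.uniform(5.0, 95.0, n)
    om = np.clip(soil_c * 1.72 + rng.normal(0.0, 0.5, n), 0.0, 100.0)
    grazing = rng.integers(0, 30, n)
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(n)],
            "map": map_,
            "mat": mat,
            "pet": pet,
            "soil_n": soil_n,
            "soil_c": soil_c,
            "ph": ph,
            "sand": sand,
            "om": om,
            "grazing_index": grazing,
        }
    )


def generate_dataset(cfg: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic experiment.

    Returns ``(samples, sites)``: plot-level leaf chemistry in the complete
    2x2 factorial over blocks, and site-level environmental covariates.
    Identical config (including seed) yields identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sites = _generate_sites(cfg, rng)

    c_mid = 0.5 * (cfg.c_range[0] + cfg.c_range[1])
    rows: list[dict] = []
    for s in sites.itertuples(index=False):
        a_site = rng.normal(0.0, cfg.site_sd)
        slope = cfg.slope_intercept + cfg.slope_per_map * s.map
        n_blocks = int(rng.integers(cfg.blocks_per_site[0], cfg.blocks_per_site[1] + 1))
        for b in range(n_blocks):
            for npk in (0, 1):
                for fence in (0, 1):
                    # the threshold acts on local (plot-level) soil N: above it
                    # leaf Si is uniformly low with attenuated variation and a
                    # muted fertilization response
                    soil_n_plot = max(rng.normal(s.soil_n, cfg.soil_n_plot_sd), 0.005)
                    above = soil_n_plot > cfg.soil_n_threshold
                    atten = cfg.attenuation if above else 1.0
                    beta = cfg.beta_npk * atten
                    sd = cfg.resid_sd * atten
                    base_mu = (cfg.mu0 - (cfg.threshold_baseline_drop if above else 0.0)
                               + a_site * atten)
                    c = rng.uniform(*cfg.c_range)
                    # rejection sampling keeps the % dry-weight closure; redraws
                    # consume the same stream so output stays seed-stable
                    while True:
                        eps = rng.normal(0.0, sd)
                        si = math.exp(
                            base_mu + beta * npk + cfg.beta_fence * fence + slope * (c - c_mid) + eps
                        )
                        dilution = (100.0 - c) / (100.0 - c_mid)
                        elems = {
                            e: cfg.element_bases[e]
                            * dilution
                            * math.exp(rng.normal(0.0, cfg.element_noise_sd))
                            for e in MACRO_ELEMENTS
                        }
                        if si + c + sum(elems.values()) < 100.0:
                            break
                    rows.append(
                        {
                            "site_id": s.site_id,
                            "block_id": f"B{b + 1}",
                            "npk": npk,
                            "fence": fence,
                            "si": si,
                            "c": c,
                            **elems,
                            "soil_n": soil_n_plot,
                        }
                    )
    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS + OPTIONAL_SAMPLE_COLUMNS)
    return samples, sites


# ---------------------------------------------------------------------------
# table I/O with validation

def validate_samples(samples: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise TableFormatError(f"samples table missing required column(s): {missing}")
    conc = samples[list(ELEMENTS) + ["c"]]
    bad = conc.columns[~conc.map(np.isreal).all(axis=0)].tolist()
    if bad or conc.isna().any().any():
        raise TableFormatError(f"non-numeric or missing concentration values in column(s): {bad or 'NA'}")
    if (conc.to_numpy(dtype=float) < 0).any():
        raise TableFormatError("negative element concentration violates the % dry-weight invariant")
    totals = conc.sum(axis=1).to_numpy()
    if (totals >= 100.0).any():
        raise TableFormatError("element concentrations sum to >= 100 % dry weight (closure violated)")


def validate_sites(sites: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise TableFormatError(f"sites table missing required column(s): {missing}")
    if sites["site_id"].duplicated().any():
        dupes = sites.loc[sites["site_id"].duplicated(), "site_id"].tolist()
        raise TableFormatError(f"duplicate site_id in sites table: {dupes}")
    if (sites[["map", "pet"]].to_numpy(dtype=float) <= 0).any():
        raise TableFormatError("map and pet must be positive")
    gi = sites["grazing_index"].to_numpy()
    if ((gi < 0) | (gi > 29)).any():
        raise TableFormatError("grazing_index must lie in 0-29")
    for col in ("soil_n", "soil_c", "sand", "om"):
        v = sites[col].to_numpy(dtype=float)
        if ((v < 0) | (v > 100)).any():
            raise TableFormatError(f"{col} must lie in [0, 100] %")


def write_tables(samples: pd.DataFrame, sites: pd.DataFrame, path: str | Path) -> tuple[Path, Path]:
    """Write ``samples.csv`` and ``sites.csv`` under ``path`` (full precision)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    validate_samples(samples)
    validate_sites(sites)
    sp, tp = path / "samples.csv", path / "sites.csv"
    cols = SAMPLE_COLUMNS + [c for c in OPTIONAL_SAMPLE_COLUMNS if c in samples.columns]
    # repr-based float formatting round-trips bit-exactly through read_csv
    fmt = lambda v: repr(float(v))  # noqa: E731
    samples[cols].to_csv(sp, index=False, float_format=fmt)
    sites[SITE_COLUMNS].to_csv(tp, index=False, float_format=fmt)
    return sp, tp


def read_tables(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate ``samples.csv`` / ``sites.csv`` written by :func:`write_tables`."""
    path = Path(path)
    try:
        samples = pd.read_csv(path / "samples.csv", float_precision="round_trip")
        sites = pd.read_csv(path / "sites.csv", float_precision="round_trip")
    except ValueError as err:  # non-numeric values surface here on typed reads
        raise TableFormatError(str(err)) from err
    for col in list(ELEMENTS) + ["c"]:
        if col in samples.columns and not np.issubdtype(samples[col].dtype, np.number):
            raise TableFormatError(f"non-numeric values in samples column '{col}'")
    validate_samples(samples)
    validate_sites(sites)
    return samples, sites
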