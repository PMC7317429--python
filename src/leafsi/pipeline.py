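"""End-to-end analysis pipeline with reproducible hierarchical seeding.

Stage order mirrors the analysis workflow: generate (or ingest) the
plot-level chemistry tables, run distributional diagnostics, fit the
two-way NPK x FENCE mixed model with adjusted means, rank the candidate
model set by AIC, detect threshold structure with a pruned regression tree,
run the stoichiometric-dilution permutation null for all six elements,
relate per-site Si~C slopes to precipitation, and exercise the NIRS
calibration pipeline on synthetic spectra.

Each stage draws randomness from its own named substream of the master
seed (derived by hashing the stage name), so adding or removing a stage
never perturbs another stage's results.  A rerun with the same config and
master seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import make_synthetic_spectra, run_calibration
from .dilution import results_to_frame, run_all_elements
from .lmm import ModelSpec, adjusted_means, diagnostics, fit_lmm
from .selection import enumerate_candidates, fit_candidates, rank_models, scores_to_frame
from .slopes import site_slopes, slope_vs_map, slopes_to_frame
from .synthetic import GeneratorConfig, generate_dataset, read_tables, write_tables
from .tree import grow_tree, prune_one_se

__all__ = ["RunConfig", "run", "STAGES", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "diagnostics", "twoway", "select", "tree", "dilution",
          "slopes", "chemcal")

#: predictors entering the full model comparison
SELECTION_PREDICTORS = ("npk", "fence", "soil_n", "soil_c", "ph",
                        "grazing_index", "sand", "map", "mat")
SELECTION_INTERACTIONS = (("npk", "soil_n"),)

#: predictors offered to the regression tree
TREE_PREDICTORS = ("npk", "fence", "soil_n", "soil_c", "ph", "grazing_index",
                   "sand", "om", "map", "mat", "pet")


@dataclass
class RunConfig:
    out_dir: str | Path = "leafsi_run"
    input_dir: str | Path | None = None   # read tables instead of generating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stages: tuple[str, ...] = STAGES
    seed: int = 0                          # master seed
    R: int = 999                           # dilution replicates
    k_folds: int = 10
    chem_n_samples: int = 1725
    chem_fraction: float = 0.2

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}; "
                             f"valid stages are {STAGES}")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed: master entropy combined with the stage-name hash."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:8], "big")
    ss = np.random.SeedSequence(entropy=[int(master), h])
    return int(ss.generate_state(1)[0] % (2**31))


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of stage results.

    Stage CSV/JSON outputs, a run manifest and a plain-text summary are
    written under ``config.out_dir``.  Any stage failure aborts the run with
    the stage name and cause; partial outputs are kept alongside a FAILED
    marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    seeds_used: dict[str, int] = {}
    summary: list[str] = []

    def seed_for(stage: str) -> int:
        s = stage_seed(config.seed, stage)
        seeds_used[stage] = s
        return s

    stage = "setup"
    try:
        # --- data ---------------------------------------------------------
        if config.input_dir is not None:
            stage = "generate"
            samples, sites = read_tables(config.input_dir)
            logger.info("loaded %d samples / %d sites from %s",
                        len(samples), len(sites), config.input_dir)
        else:
            stage = "generate"
            gen = dataclasses.replace(config.generator, seed=seed_for("generate"))
            samples, sites = generate_dataset(gen)
            logger.info("generated %d samples across %d sites", len(samples), len(sites))
        if "generate" in config.stages:
            write_tables(samples, sites, out)
        results["data"] = (samples, sites)

        if "diagnostics" in config.stages:
            stage = "diagnostics"
            raw = diagnostics(samples["si"].to_numpy())
            fit0 = fit_lmm(ModelSpec(fixed=("npk", "fence")), samples, sites)
            resid = diagnostics(fit0.residuals, fit0.fitted)
            payload = {
                "raw_si": {"ad_statistic": raw.ad_statistic, "ad_pvalue": raw.ad_pvalue},
                "log_si_residuals": {
                    "ad_statistic": resid.ad_statistic, "ad_pvalue": resid.ad_pvalue,
                    "ncv_chisq": resid.ncv_chisq, "ncv_pvalue": resid.ncv_pvalue,
                },
            }
            (out / "diagnostics.json").write_text(json.dumps(payload, indent=2))
            results["diagnostics"] = payload
            summary.append(f"raw Si Anderson-Darling A = {raw.ad_statistic:.3f} "
                           f"(p = {raw.ad_pvalue:.3g})")

        if "twoway" in config.stages:
            stage = "twoway"
            spec = ModelSpec(fixed=("npk", "fence"), interactions=(("npk", "fence"),))
            fit = fit_lmm(spec, samples, sites, method="reml")
            fit.coefficients.rename_axis("term").to_csv(out / "twoway_coefficients.csv")
            means = adjusted_means(fit, "npk")
            pd.DataFrame(
                [{"npk": k, "mean_si_pct": v[0], "se_pct": v[1]} for k, v in means.items()]
            ).to_csv(out / "adjusted_means.csv", index=False)
            results["twoway"] = fit
            results["adjusted_means"] = means
            b = fit.coefficients.loc["npk"]
            summary.append(f"two-way model NPK effect on log Si: "
                           f"{b.estimate:.3f} +/- {b.se:.3f} (t = {b.t:.2f})")
            summary.append(f"adjusted mean Si: -NPK {means[0][0]:.2f} %dw, "
                           f"+NPK {means[1][0]:.2f} %dw")

        if "select" in config.stages:
            stage = "select"
            specs = enumerate_candidates(list(SELECTION_PREDICTORS),
                                         list(SELECTION_INTERACTIONS))
            fits = fit_candidates(specs, samples, sites, method="ml")
            scores = rank_models(fits)
            scores_to_frame(scores).to_csv(out / "model_selection.csv", index=False)
            results["selection"] = scores
            top = scores[0]
            summary.append(f"top model by AIC: {top.spec.label()} "
                           f"(w = {top.weight:.3f}, R2m = {top.r2_marginal:.2f}, "
                           f"R2c = {top.r2_conditional:.2f})")

        if "tree" in config.stages:
            stage = "tree"
            # plot-level soil N (samples) shadows the site mean where present
            merged = samples.merge(sites, on="site_id", how="left",
                                   suffixes=("", "_site"))
            X = merged[list(TREE_PREDICTORS)]
            y = np.log(merged["si"].to_numpy())
            grown = grow_tree(X, y, min_leaf=7, cp_min=0.01,
                              strata=merged["site_id"].to_numpy())
            pruned = prune_one_se(grown, k_folds=config.k_folds, seed=seed_for("tree"))
            (out / "tree.json").write_text(pruned.to_json())
            (out / "tree.txt").write_text(pruned.to_text() + "\n")
            pruned.cp_table.to_csv(out / "cp_table.csv", index=False)
            results["tree"] = pruned
            if pruned.first_split is not None:
                var, thr = pruned.first_split
                summary.append(f"pruned tree first split: {var} < {thr:.3f} "
                               f"(cp = {pruned.selected_cp:.3f}, "
                               f"{pruned.n_leaves} leaves)")
            else:
                summary.append("pruned tree: root only (no threshold structure)")

        if "dilution" in config.stages:
            stage = "dilution"
            dil = run_all_elements(samples, R=config.R, seed=seed_for("dilution"))
            results_to_frame(dil).to_csv(out / "dilution.csv", index=False)
            results["dilution"] = dil
            si = dil["si"]
            summary.append(f"dilution null (R = {config.R}): Si observed slope "
                           f"{si.observed_slope:.4f} vs null mean {si.null_mean:.4f} "
                           f"(p_lower = {si.p_lower:.4f})")

        if "slopes" in config.stages:
            stage = "slopes"
            ss = site_slopes(samples, sites)
            slopes_to_frame(ss).to_csv(out / "slopes.csv", index=False)
            sm = slope_vs_map(ss, sites)
            pd.DataFrame([dataclasses.asdict(sm)]).to_csv(out / "slope_vs_map.csv",
                                                          index=False)
            results["slopes"] = ss
            results["slope_vs_map"] = sm
            summary.append(f"Si~C slope vs MAP: gamma1 = {sm.gamma1:.3g} per mm "
                           f"(p = {sm.p_gamma1:.3g}, {sm.n_sites} sites)")

        if "chemcal" in config.stages:
            stage = "chemcal"
            spectra = make_synthetic_spectra(n_samples=config.chem_n_samples,
                                             seed=seed_for("chemcal"))
            model, selected = run_calibration(spectra, fraction=config.chem_fraction)
            payload = {
                "n_samples": config.chem_n_samples,
                "n_calibration": len(selected),
                "n_components": model.n_components,
                "validation_r2": model.validation_r2,
            }
            (out / "chemometrics.json").write_text(json.dumps(payload, indent=2))
            results["chemometrics"] = payload
            summary.append(f"NIRS calibration: {len(selected)} samples selected, "
                           f"{model.n_components} PLS components, "
                           f"external validation R2 = {model.validation_r2:.3f}")
    except Exception as err:  # noqa: BLE001 - abort with stage context
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {err}\n")
        raise StageFailure(stage, err) from err

    manifest = {
        "package": "leafsi",
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds_used,
        "stages": list(config.stages),
        "R": config.R,
        "k_folds": config.k_folds,
        "generator": dataclasses.asdict(config.generator),
        "input_dir": str(config.input_dir) if config.input_dir else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    results["manifest"] = manifest
    results["summary"] = summary
    return results
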