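"""Full-pipeline orchestration: simulate/load -> AMMI -> indices -> BLUP -> FR -> PLSR.

The pipeline mirrors how a MET stability study is actually run: the
experimental stages (combined ANOVA, AMMI decomposition, stability
indices with simultaneous selection, BLUP genotypic values with
HMGV/RPGV/HMRPGV) always execute; the analytical stages (factorial
regression, PLSR) run only when environment covariates are available and
are otherwise marked as skipped.  Every stage writes a tidy CSV and the
whole run is summarized in a versioned ``report.json`` whose numbers are
serialized at full precision alongside a two-decimal display mirror.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import ammi as ammi_mod
from . import blup as blup_mod
from . import covariates as cov_mod
from . import stability as stab_mod
from .core import (
    CovariateMatrix,
    METDataset,
    center_covariates,
    compute_ge_means,
    read_covariates_csv,
    read_met_csv,
    write_covariates_csv,
    write_ge_means_csv,
    write_met_csv,
)
from .simulate import SimulationSpec, generate_covariate_linked, generate_met

log = logging.getLogger("metstab")

REPORT_SCHEMA_VERSION = "1.0"

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "make_report", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One run's inputs, tuning knobs and output location."""

    trials: Optional[Path] = None
    covariates: Optional[Path] = None
    simulation: Optional[SimulationSpec] = None
    alpha: float = 0.05
    n_axes: Optional[int] = None          # override for N'-based indices
    waas_axes: Optional[int] = None       # override; default all axes
    plsr_factors: int = 2
    plsr_scale: bool = True
    nipals_tol: float = 1e-10
    reml_tolerance: float = 1e-8
    reml_max_iterations: int = 500
    impute: Optional[str] = None
    out_dir: Path = Path("metstab_out")
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.trials is None) == (self.simulation is None):
            raise ValueError("provide exactly one of a trials CSV path or a simulation spec")
        if self.nipals_tol <= 0 or self.reml_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Build a config from a YAML file; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if sim is not None and raw.get("trials") is None:
        if overrides.get("seed") is not None:
            sim["seed"] = overrides["seed"]
        raw["simulation"] = SimulationSpec(**sim)
    for key in ("trials", "covariates", "out_dir"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    return PipelineConfig(**raw)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _round2(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _round2(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round2(v) for v in obj]
    if isinstance(obj, float):
        return round(obj, 2)
    return obj


def _frame_records(df: pd.DataFrame, index_name: str = "name") -> list[dict]:
    if isinstance(df.index, pd.RangeIndex):
        out = df.copy()
    else:
        out = df.reset_index()
        if out.columns[0] == "index":
            out = out.rename(columns={"index": index_name})
    return _jsonable(out.to_dict(orient="records"))


def make_report(stages: dict[str, Any]) -> dict[str, Any]:
    """Assemble the consolidated report document from completed stage outputs.

    The AMMI stage is required; analytical sections are null when their
    stage was skipped.  Full-precision numbers live under each section;
    a two-decimal mirror of the whole document sits under ``display``.
    """
    if "ammi" not in stages:
        raise ValueError("make_report needs at least the AMMI stage output")
    report: dict[str, Any] = {"schema_version": REPORT_SCHEMA_VERSION}
    report["stages_completed"] = sorted(stages)

    means = stages.get("means")
    if means is not None:
        report["means"] = {
            "grand_mean": float(means.grand_mean),
            "genotype_means": _jsonable(dict(zip(means.genotypes, means.genotype_means()))),
            "environment_means": _jsonable(dict(zip(means.environments, means.environment_means()))),
        }

    anova = stages.get("anova")
    if anova is not None:
        report["anova"] = {
            "table": _frame_records(anova.table, "source"),
            "has_error_term": anova.has_error_term,
        }

    am = stages["ammi"]
    report["ammi"] = {
        "singular_values": _jsonable(am.singular_values),
        "percent_explained": _jsonable(am.percent_explained),
        "cumulative_percent": _jsonable(am.cumulative_percent),
        "n_significant": am.n_significant,
        "zero_interaction": am.zero_interaction,
        "gollob": _frame_records(am.gollob, "axis") if am.gollob is not None else None,
    }

    if "stability" in stages:
        report["stability"] = {
            "table": _frame_records(stages["stability"], "genotype"),
            "n_axes": int(stages["stability"].attrs.get("n_axes", 0)),
        }

    if "blup" in stages:
        vc, hmr = stages["blup"]
        report["blup"] = {
            "variance_components": {
                "sigma2_g": vc.sigma2_g,
                "sigma2_ge": vc.sigma2_ge,
                "sigma2_e": vc.sigma2_e,
                "loglik_reml": vc.loglik_reml,
                "n_iterations": vc.n_iterations,
                "converged": vc.converged,
                "boundary": list(vc.boundary),
            },
            "hmrpgv": _frame_records(hmr, "genotype"),
        }

    report["fr"] = None
    if "fr" in stages:
        fr = stages["fr"]
        report["fr"] = {
            "selected_variables": fr.selected_variables,
            "steps": _frame_records(fr.aic_trace, "step"),
            "explained_ss_per_variable": _jsonable(fr.explained_ss_per_variable),
            "residual_ss": fr.residual_ss,
            "total_ss": fr.total_ss,
            "perfect_fit": fr.perfect_fit,
        }

    report["plsr"] = None
    if "plsr" in stages:
        pl = stages["plsr"]
        report["plsr"] = {
            "percent_y_explained": _jsonable(pl.percent_y_explained),
            "percent_x_explained": _jsonable(pl.percent_x_explained),
            "n_factors": pl.n_factors,
        }

    report["display"] = _round2({k: v for k, v in report.items() if k not in ("schema_version", "display")})
    return report


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all applicable stages, writing per-stage CSVs and report.json.

    Returns the report document.  On a stage failure the partial outputs
    stay on disk, ``manifest.json`` records the completed stages, and a
    :class:`StageError` naming the stage propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, Any] = {}
    completed: list[str] = []

    def _write_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps({"completed_stages": completed}, indent=2) + "\n")

    def run_stage(name: str, fn):
        log.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            _write_manifest()
            raise StageError(name, exc) from exc
        completed.append(name)
        return result

    # --- inputs ---------------------------------------------------------
    def load_inputs():
        if config.simulation is not None:
            spec = config.simulation
            if config.seed is not None:
                spec = dataclasses.replace(spec, seed=config.seed)
            if spec.covariate_link is not None:
                data, cov, truth = generate_covariate_linked(spec)
            else:
                data, truth = generate_met(spec)
                cov = None
            write_met_csv(data, out / "trials.csv")
            if cov is not None:
                write_covariates_csv(cov, out / "covariates.csv")
        else:
            data = read_met_csv(config.trials)
            cov = (
                read_covariates_csv(config.covariates, data.environments)
                if config.covariates is not None
                else None
            )
        return data, cov

    data, cov = run_stage("inputs", load_inputs)

    # --- experimental stages -------------------------------------------
    def stage_means():
        m = compute_ge_means(data, impute=config.impute)
        write_ge_means_csv(m, out / "ge_means.csv")
        return m

    means = run_stage("means", stage_means)
    stages["means"] = means

    def stage_anova():
        a = ammi_mod.combined_anova(data)
        a.table.rename_axis("source").to_csv(out / "anova.csv")
        return a

    anova = run_stage("anova", stage_anova)
    stages["anova"] = anova

    def stage_ammi():
        am = ammi_mod.ammi_decompose(means, replicate_count=data.uniform_replicate_count())
        if anova.has_error_term:
            am = ammi_mod.gollob_test(am, anova, alpha=config.alpha)
        else:
            am = dataclasses.replace(am, n_significant=am.n_axes)
            log.warning("no pooled error term: Gollob test skipped, all axes treated as significant")
        am.scores_frame().to_csv(out / "ammi_scores.csv")
        ammi_mod.ammi1_coords(means, am).to_csv(out / "ammi1_coords.csv", index=False)
        if am.n_axes >= 2:
            ammi_mod.ammi2_coords(am).to_csv(out / "ammi2_coords.csv", index=False)
        return am

    am = run_stage("ammi", stage_ammi)
    stages["ammi"] = am

    def stage_stability():
        table = stab_mod.stability_table(am, means, n_axes=config.n_axes, waas_axes=config.waas_axes)
        table.to_csv(out / "stability.csv")
        return table

    stages["stability"] = run_stage("stability", stage_stability)

    def stage_blup():
        vc, gvals = blup_mod.fit_met_mixed_model(
            data, tolerance=config.reml_tolerance, max_iterations=config.reml_max_iterations
        )
        vc.as_series().rename_axis("parameter").to_frame("value").to_csv(out / "varcomp.csv")
        gvals.gv_frame().rename_axis("genotype").to_csv(out / "genotypic_values.csv")
        hmr = blup_mod.hmrpgv_table(gvals, means.grand_mean)
        hmr.to_csv(out / "hmrpgv.csv")
        return vc, hmr

    stages["blup"] = run_stage("blup", stage_blup)

    # --- analytical stages ---------------------------------------------
    if cov is None:
        log.info("no covariates provided: factorial regression and PLSR skipped")
    else:
        def stage_fr():
            centered = center_covariates(cov)
            fr = cov_mod.stepwise_fr_aic(means.interaction, centered, genotypes=means.genotypes)
            fr.aic_trace.to_csv(out / "fr_steps.csv", index=False)
            fr.xi_frame().to_csv(out / "fr_sensitivities.csv")
            return fr

        stages["fr"] = run_stage("fr", stage_fr)

        def stage_plsr():
            x = center_covariates(cov, standardize=config.plsr_scale)
            a_max = min(x.n_environments - 1, x.n_variables)
            n_factors = min(config.plsr_factors, a_max)
            pl = cov_mod.fit_plsr(
                x, means.interaction.T, n_factors, genotypes=means.genotypes, tol=config.nipals_tol
            )
            pd.DataFrame(
                {
                    "factor": np.arange(1, pl.n_factors + 1),
                    "percent_y_explained": pl.percent_y_explained,
                    "percent_x_explained": pl.percent_x_explained,
                }
            ).to_csv(out / "plsr_factors.csv", index=False)
            if pl.n_factors >= 2:
                cov_mod.plsr_biplot_coords(pl).to_csv(out / "plsr_biplot.csv", index=False)
            return pl

        stages["plsr"] = run_stage("plsr", stage_plsr)

    def stage_report():
        report = make_report(stages)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report

    report = run_stage("report", stage_report)
    _write_manifest()
    return report
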