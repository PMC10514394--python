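"""End-to-end analysis pipeline.

Orchestrates load -> scenario -> direction split -> MDF staircase ->
per-stage bottleneck/limiting-metabolite/enzyme-cost diagnostics ->
microcompartment merges -> post-merge staircase, and writes tabular
reports, a manifest and staircase plots into an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .diagnostics import enzyme_cost_variability, identify_bottlenecks
from .io import load_merge_specs, load_model, load_thermo_config
from .merge import apply_scenario, merge_reactions
from .model import CompartModel, ThermoConfig, split_reversible, validate_model
from .opt import assemble_constraints, solve_max_flux_at_mdf
from .profile import sweep_mdf_curve

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report"]

log = logging.getLogger("mdflux.pipeline")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    model_path: str
    product: str
    out_dir: str
    params_path: str | None = None
    thermo_config_path: str | None = None
    scenario: str = "aerobic"
    n_points: int = 30
    refine: bool = True
    enzyme_on: bool = False
    merge_spec_path: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PipelineConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from exc


@dataclass
class PipelineResult:
    model: CompartModel
    config: ThermoConfig
    curve_before: object = None
    curve_after: object = None
    merged_model: CompartModel | None = None
    stage_reports: list = field(default_factory=list)
    enzyme_records: list = field(default_factory=list)
    merge_audits: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config``; returns the results
    and writes reports under ``config.out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    thermo = (
        load_thermo_config(config.thermo_config_path)
        if config.thermo_config_path
        else ThermoConfig()
    )
    model = load_model(config.model_path, config.params_path, thermo)
    if not model.has_reaction(config.product):
        raise PipelineConfigError(f"product reaction {config.product!r} not in model")
    if config.scenario != "aerobic":
        model = apply_scenario(model, config.scenario)
        log.info("applied scenario %s", config.scenario)
    model = split_reversible(model)
    findings = validate_model(model)
    if findings:
        raise PipelineConfigError("model invalid: " + "; ".join(findings))

    result = PipelineResult(model=model, config=thermo)
    log.info("sweeping MDF staircase for %s", config.product)
    curve = sweep_mdf_curve(
        model, thermo, config.product, n_points=config.n_points,
        refine=config.refine, enzyme_on=config.enzyme_on,
    )
    result.curve_before = curve
    log.info("staircase: %d stages, max flux %.4g", len(curve.stages), curve.max_flux)

    for stage in curve.stages:
        try:
            report = identify_bottlenecks(
                model, thermo, config.product, stage.flux_hi, enzyme_on=config.enzyme_on
            )
        except ValueError as exc:
            log.warning("stage %d diagnostics skipped: %s", stage.index, exc)
            continue
        stage.bottlenecks = sorted(report.bottlenecks)
        result.stage_reports.append((stage.index, report))
        if config.enzyme_on:
            try:
                result.enzyme_records.append(
                    (
                        stage.index,
                        enzyme_cost_variability(
                            model, thermo, config.product, stage.flux_hi, report.mdf
                        ),
                    )
                )
            except ValueError as exc:
                log.warning("stage %d enzyme costs skipped: %s", stage.index, exc)

    merged_model = None
    if config.merge_spec_path:
        merged_model = model
        for spec in load_merge_specs(config.merge_spec_path):
            res = merge_reactions(merged_model, spec)
            merged_model = res.new_model
            result.merge_audits.append(res.audit)
            log.info("applied merge %s", spec.merged_id)
        curve_after = sweep_mdf_curve(
            merged_model, thermo, config.product, n_points=config.n_points,
            refine=config.refine, enzyme_on=config.enzyme_on,
        )
        result.curve_after = curve_after
        result.merged_model = merged_model

    result.summary = _summarize(result, thermo, config)
    write_report(result, config.out_dir, pipeline_config=config)
    return result


def _feasible_flux_limit(model, thermo, product, enzyme_on) -> float:
    """Largest product flux keeping MDF >= 0 (second law)."""
    problem = assemble_constraints(model, thermo, enzyme_on=enzyme_on, thermo_on=True)
    res = solve_max_flux_at_mdf(problem, product, 0.0)
    return res.objective_value if res.optimal else 0.0


def _summarize(result: PipelineResult, thermo, config) -> dict:
    before = result.curve_before
    summary = {
        "product": config.product,
        "scenario": config.scenario,
        "max_flux": before.max_flux,
        "n_stages_before": len(before.stages),
        "mdf_at_zero_demand_before": before.mdf_values[0],
        "feasible_flux_limit_before": _feasible_flux_limit(
            result.model, thermo, config.product, config.enzyme_on
        ),
    }
    if result.curve_after is not None:
        after = result.curve_after
        summary.update(
            {
                "n_stages_after": len(after.stages),
                "mdf_at_zero_demand_after": after.mdf_values[0],
                "max_flux_after": after.max_flux,
                "feasible_flux_limit_after": _feasible_flux_limit(
                    result.merged_model, thermo, config.product, config.enzyme_on
                ),
                "mdf_improved_at_low_demand": bool(
                    after.mdf_values[0] > before.mdf_values[0] + thermo.mdf_tol
                ),
            }
        )
    return summary


def write_report(results: PipelineResult, out_dir, pipeline_config=None) -> list:
    """Write TSV/JSON reports, a run manifest and staircase plots.

    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _curve_tsv(curve, name):
        stage_of = {}
        for s in curve.stages:
            for f in curve.grid:
                if (f > s.flux_lo or s.index == 1) and f <= s.flux_hi + 1e-12:
                    stage_of.setdefault(f, s.index)
        df = pd.DataFrame(
            {
                "min_flux": curve.grid,
                "mdf": curve.mdf_values,
                "stage_index": [stage_of.get(f, -1) for f in curve.grid],
            }
        )
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    _curve_tsv(results.curve_before, "curve_before.tsv")
    if results.curve_after is not None:
        _curve_tsv(results.curve_after, "curve_after.tsv")

    rows = []
    for stage_idx, rep in results.stage_reports:
        for rid in sorted(rep.bottlenecks):
            rows.append(
                {
                    "stage": stage_idx,
                    "reaction": rid,
                    "max_df": rep.per_reaction_max_df[rid],
                    "class": rep.classification,
                    "stage_mdf": rep.mdf,
                }
            )
    path = out / "bottlenecks.tsv"
    pd.DataFrame(rows, columns=["stage", "reaction", "max_df", "class", "stage_mdf"]).to_csv(
        path, sep="\t", index=False
    )
    written.append(path)

    rows = []
    for stage_idx, rep in results.stage_reports:
        for lm in rep.limiting_metabolites:
            rows.append(
                {
                    "stage": stage_idx,
                    "metabolite": lm.id,
                    "conc_min": lm.conc_min,
                    "conc_max": lm.conc_max,
                    "reason": lm.reason,
                }
            )
    path = out / "limiting_metabolites.tsv"
    pd.DataFrame(
        rows, columns=["stage", "metabolite", "conc_min", "conc_max", "reason"]
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    rows = []
    for stage_idx, records in results.enzyme_records:
        for rec in records:
            rows.append(
                {
                    "stage": stage_idx,
                    "reaction": rec.id,
                    "cost_min": rec.cost_min,
                    "cost_max": rec.cost_max,
                    "is_key": rec.is_key,
                }
            )
    path = out / "enzyme_costs.tsv"
    pd.DataFrame(
        rows, columns=["stage", "reaction", "cost_min", "cost_max", "is_key"]
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    if results.merge_audits:
        path = out / "merge_audit.txt"
        path.write_text("\n\n".join(results.merge_audits) + "\n")
        written.append(path)

    manifest = {
        "summary": results.summary,
        "solver": "scipy-highs",
        "tolerances": {
            "mdf_tol": results.config.mdf_tol,
            "flux_tol": results.config.flux_tol,
            "bigM": results.config.bigM,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if pipeline_config is not None:
        cfg = asdict(pipeline_config)
        manifest["pipeline_config"] = cfg
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    written.append(path)

    try:
        written.append(_plot_curves(results, out))
    except Exception as exc:  # plotting must never sink the analysis
        log.warning("plotting failed: %s", exc)
    return written


def _plot_curves(results: PipelineResult, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    b = results.curve_before
    ax.step(b.grid, b.mdf_values, where="post", label="before", color="tab:orange")
    if results.curve_after is not None:
        a = results.curve_after
        ax.step(a.grid, a.mdf_values, where="post", label="after merge", color="tab:purple")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("required product flux (mmol/gDW/h)")
    ax.set_ylabel("MDF (kJ/mol)")
    ax.legend()
    fig.tight_layout()
    path = out / "mdf_curves.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
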