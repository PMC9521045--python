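"""End-to-end orchestration: generate/load -> fit -> aggregate -> economics
-> edit -> model -> compare, with every intermediate table persisted.

The run is a pure function of (config, seed): repeated runs produce
byte-identical artifacts.  A manifest records the config hash, the seed
and a checksum per artifact.
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

from .data_editing import FilterConfig, apply_filters, merge_sources
from .errors import InvalidConfigError
from .herd_economics import compute_indicator_table
from .hlcc_aggregation import aggregate_hlcc, partition_lactation_weights, pivot_hlcc_wide
from .lactation_model import fit_lactation_table
from .mixed_models import ModelSpec, backward_select_aic, r2_decomposition, standardize_continuous
from .nonnested_tests import compare_models
from .synthetic_data import (
    CONTINUOUS_COVARIATES,
    SyntheticConfig,
    generate_population,
    write_population,
)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run", "default_specs"]

logger = logging.getLogger(__name__)

HLCC_TERMS = (
    "magnitude_primiparous",
    "time_to_peak_primiparous",
    "persistency_primiparous",
    "magnitude_multiparous",
    "time_to_peak_multiparous",
    "persistency_multiparous",
)

DEFAULT_CONTINUOUS_CONTROLS = (
    "equity_ratio",
    "herd_intensity",
    "relative_milk_price",
    "herd_size",
    "expansion_rate",
    "scc",
    "calving_interval",
    "age_days",
)

DEFAULT_CATEGORICAL_CONTROLS = (
    "soil_type",
    "milking_system",
    "successor",
    "outsourced_rearing",
)

DESCRIPTIVE_VARIABLES = (
    "iofc_cow",
    "iofc_milk",
    "hm305",
    "equity_ratio",
    "herd_intensity",
    "relative_milk_price",
    "herd_size",
    "expansion_rate",
    "age_days",
    "scc",
    "calving_interval",
) + HLCC_TERMS


@dataclass(frozen=True)
class PipelineConfig:
    input_mode: str = "synthetic"  # "synthetic" | "files"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_paths: dict = field(default_factory=dict)
    filters: FilterConfig = field(default_factory=FilterConfig)
    outcomes: tuple[str, ...] = ("iofc_cow", "iofc_milk")
    model_sets: tuple[str, ...] = ("hlcc", "hm305")
    continuous_controls: tuple[str, ...] = DEFAULT_CONTINUOUS_CONTROLS
    categorical_controls: tuple[str, ...] = DEFAULT_CATEGORICAL_CONTROLS
    alpha: float = 0.05
    j_mode: str = "lmm"
    run_comparison: bool = True
    run_selection: bool = True
    outdir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise InvalidConfigError("input_mode must be 'synthetic' or 'files'")
        if self.input_mode == "files":
            required = {"test_days", "accounting", "performance", "national_price"}
            missing = required - set(self.input_paths)
            if missing:
                raise InvalidConfigError(f"missing input paths: {sorted(missing)}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def default_specs(
    outcome: str,
    model_set: str,
    continuous_controls=DEFAULT_CONTINUOUS_CONTROLS,
    categorical_controls=DEFAULT_CATEGORICAL_CONTROLS,
) -> ModelSpec:
    """The candidate model for one outcome and one predictor family."""
    lead = HLCC_TERMS if model_set == "hlcc" else ("hm305",)
    return ModelSpec(
        outcome=outcome,
        continuous_terms=tuple(lead) + tuple(continuous_controls),
        categorical_terms=tuple(categorical_controls),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.input_mode == "synthetic":
        tables = generate_population(config.synthetic)
        write_population(tables, outdir / "inputs")
        span = config.synthetic.years
        return tables.test_days, tables.accounting, tables.performance, tables.national_price, span
    paths = config.input_paths
    test_days = pd.read_csv(paths["test_days"], parse_dates=["calving_date", "test_date"])
    accounting = pd.read_csv(paths["accounting"])
    performance = pd.read_csv(paths["performance"])
    national_price = pd.read_csv(paths["national_price"])
    years = pd.to_datetime(test_days["test_date"]).dt.year
    span = (int(years.min()), int(years.max()))
    return test_days, accounting, performance, national_price, span


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a bundle of artifact paths and results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        artifacts[name] = path

    stage = "load-inputs"
    try:
        test_days, accounting, performance, national_price, span = _load_inputs(
            config, outdir
        )

        stage = "fit-curves"
        fits = fit_lactation_table(test_days)
        save("fits", fits)

        stage = "aggregate-hlcc"
        weights = partition_lactation_weights(test_days, fits)
        hlcc = aggregate_hlcc(fits, weights, span)
        save("hlcc", hlcc)
        hlcc_wide = pivot_hlcc_wide(hlcc)

        stage = "economics"
        indicators = compute_indicator_table(accounting, national_price)
        save("indicators", indicators)

        stage = "edit"
        herd_traits = accounting[
            ["herd_id", "year", "herd_size"]
            + [
                c
                for c in (
                    "soil_type", "milking_system", "successor",
                    "outsourced_rearing", "direct_seller", "organic",
                )
                if c in accounting.columns
            ]
        ]
        economics = indicators.merge(herd_traits, on=["herd_id", "year"])
        merged = merge_sources(economics, hlcc_wide, performance)
        filters = config.filters
        present = tuple(v for v in filters.outlier_variables if v in merged.columns)
        if present != filters.outlier_variables:
            filters = dataclasses.replace(filters, outlier_variables=present)
        analysis, audit = apply_filters(merged, filters)
        save("analysis", analysis)
        (outdir / "audit.json").write_text(audit.to_json())
        artifacts["audit"] = outdir / "audit.json"

        stage = "model"
        model_results = {}
        r2_payload = {}
        std_table = analysis
        continuous = [c for c in CONTINUOUS_COVARIATES if c in analysis.columns]
        if len(analysis):
            std_table, _scaling = standardize_continuous(analysis, continuous)
        for outcome in config.outcomes:
            for model_set in config.model_sets:
                spec = default_specs(
                    outcome,
                    model_set,
                    config.continuous_controls,
                    config.categorical_controls,
                )
                if config.run_selection:
                    fit, trace = backward_select_aic(spec, std_table)
                else:
                    from .mixed_models import fit_lmm

                    fit, trace = fit_lmm(spec, std_table, reml=True), []
                key = f"model_{outcome}_{model_set}"
                save(key, fit.coefficients)
                r2 = r2_decomposition(fit, fit.spec, std_table)
                r2_payload[key] = {
                    "marginal": r2.marginal,
                    "conditional": r2.conditional,
                    "part": r2.part,
                    "aic": fit.aic,
                    "herd_variance": fit.herd_variance,
                    "residual_variance": fit.residual_variance,
                    "selection_trace": trace,
                }
                model_results[key] = fit
        (outdir / "r2.json").write_text(json.dumps(r2_payload, indent=2))
        artifacts["r2"] = outdir / "r2.json"

        stage = "compare"
        if config.run_comparison and {"hlcc", "hm305"} <= set(config.model_sets):
            comparisons = []
            for outcome in config.outcomes:
                fit_a = model_results[f"model_{outcome}_hlcc"]
                fit_b = model_results[f"model_{outcome}_hm305"]
                table6 = compare_models(
                    fit_a.spec,
                    fit_b.spec,
                    std_table,
                    alpha=config.alpha,
                    label_a="HLCC",
                    label_b="HM305",
                    j_mode=config.j_mode,
                )
                comparisons.append(table6)
            save("nonnested", pd.concat(comparisons, ignore_index=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.synthetic.rng_seed if config.input_mode == "synthetic" else None,
        "artifacts": {k: _sha256(p) for k, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = outdir / "manifest.json"

    summary = summarize_run(outdir)
    (outdir / "summary.md").write_text(summary)
    artifacts["summary"] = outdir / "summary.md"
    return {"artifacts": artifacts, "models": model_results, "manifest": manifest}


def summarize_run(outdir: str | Path) -> str:
    """One-page markdown summary of a run bundle; robust to missing parts."""
    outdir = Path(outdir)
    lines = ["# Pipeline run summary", ""]

    audit_path = outdir / "audit.json"
    if audit_path.exists():
        audit = json.loads(audit_path.read_text())
        lines.append("## Data editing waterfall")
        lines.append("")
        lines.append(f"Input records: {audit['input_records']}")
        for step in audit["steps"]:
            lines.append(
                f"- {step['step']}: excluded {step['excluded']}, "
                f"remaining {step['remaining']}"
            )
        lines.append("")
    else:
        lines.append("_audit log missing_\n")

    analysis_path = outdir / "analysis.csv"
    if analysis_path.exists():
        analysis = pd.read_csv(analysis_path)
        if len(analysis) == 0:
            lines.append("## Analysis table\n\nZero modelled rows; no model section.\n")
        else:
            lines.append("## Descriptive statistics")
            lines.append("")
            lines.append("| variable | mean | SD |")
            lines.append("|---|---|---|")
            for var in DESCRIPTIVE_VARIABLES:
                if var in analysis.columns:
                    lines.append(
                        f"| {var} | {analysis[var].mean():.3g} | {analysis[var].std():.3g} |"
                    )
            lines.append("")
    else:
        lines.append("_analysis table missing_\n")

    r2_path = outdir / "r2.json"
    if r2_path.exists() and analysis_path.exists() and len(pd.read_csv(analysis_path)):
        r2 = json.loads(r2_path.read_text())
        lines.append("## Models")
        lines.append("")
        for key, payload in r2.items():
            lines.append(
                f"- {key}: marginal R2 {payload['marginal']:.3f}, "
                f"conditional R2 {payload['conditional']:.3f}, AIC {payload['aic']:.1f}"
            )
        lines.append("")

    nn_path = outdir / "nonnested.csv"
    if nn_path.exists():
        nn = pd.read_csv(nn_path)
        lines.append("## Non-nested comparison")
        lines.append("")
        for (test, outcome), grp in nn.groupby(["test", "outcome"]):
            verdict = grp["interpretation"].iloc[0]
            lines.append(f"- {test} test, {outcome}: {verdict}")
        lines.append("")
    return "\n".join(lines)
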