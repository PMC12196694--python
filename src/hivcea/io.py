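"""File formats, run configuration, and the end-to-end pipeline.

All tabular artifacts are plain CSV: transition matrices (one 4x4 file
per year, header row and first column naming the stages), long-format
patient panels, cost schedules, cohort traces, PSA samples, and tornado
rankings. Run configuration is YAML or JSON. Every pipeline run writes
a manifest (config, seed, package version, timestamp) sufficient to
reproduce it.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .costing import CostSchedule, CurrencyConfig, Phase, ResourceItem, build_cost_schedule
from .estimation import (
    PanelDataset,
    count_transitions,
    estimate_baseline,
    estimate_transitions,
)
from .fixtures import load_fixtures
from .markov import (
    CUResult,
    ModelConfig,
    StageVector,
    TransitionSchedule,
    UtilitySchedule,
    run_cohort,
    summarize,
)
from .sensitivity import ModelInputs, PSAConfig, PSAResult, TornadoEntry, run_psa, tornado
from .stages import STAGE_LABELS, ImmuneStage

__all__ = [
    "read_panel",
    "write_panel",
    "read_transition_matrix",
    "write_transition_schedule",
    "read_transition_schedule",
    "read_cost_schedule",
    "write_cost_schedule",
    "read_resource_items",
    "write_trace",
    "write_psa_samples",
    "write_tornado",
    "load_config",
    "PipelineResult",
    "run_pipeline",
]


# ---------------------------------------------------------------- panels


def read_panel(path: str | Path) -> PanelDataset:
    df = pd.read_csv(path)
    required = {"patient_id", "year_index", "cd4_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    return PanelDataset.from_frame(df, provenance=str(path))


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


# ------------------------------------------------------------- matrices


def read_transition_matrix(path: str | Path) -> np.ndarray:
    """One 4x4 matrix; rows = origin stage, columns = destination stage."""
    df = pd.read_csv(path)
    if list(df.iloc[:, 0]) != list(STAGE_LABELS) or list(df.columns[1:]) != list(
        STAGE_LABELS
    ):
        raise ValueError(f"{path}: matrix must be labelled with {STAGE_LABELS}")
    return df[list(STAGE_LABELS)].to_numpy(dtype=float)


def write_transition_schedule(
    schedule: TransitionSchedule, directory: str | Path, prefix: str = "transitions_year"
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for year, mat in schedule.matrices.items():
        df = pd.DataFrame(np.round(mat, 4), columns=list(STAGE_LABELS))
        df.insert(0, "stage", list(STAGE_LABELS))
        p = directory / f"{prefix}{year}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_transition_schedule(paths: Sequence[str | Path]) -> TransitionSchedule:
    """Year files in cycle order (year 1 first)."""
    return TransitionSchedule(
        {year: read_transition_matrix(p) for year, p in enumerate(paths, start=1)}
    )


# ---------------------------------------------------------------- costs


def read_cost_schedule(path: str | Path) -> CostSchedule:
    df = pd.read_csv(path)
    if list(df["stage"]) != list(STAGE_LABELS):
        raise ValueError(f"{path}: cost schedule must list stages {STAGE_LABELS}")
    return CostSchedule(
        df["initial_cost"].to_numpy(float), df["incremental_cost"].to_numpy(float)
    )


def write_cost_schedule(schedule: CostSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_resource_items(path: str | Path) -> list[ResourceItem]:
    """Resource table: name, unit_cost, currency, annual_frequency,
    proportion_using, stages (semicolon-separated labels or ALL), phase."""
    df = pd.read_csv(path)
    items = []
    for row in df.itertuples():
        stages_field = str(row.stages).strip()
        if stages_field.upper() == "ALL":
            stages = tuple(ImmuneStage)
        else:
            stages = tuple(
                ImmuneStage.from_label(s) for s in stages_field.split(";") if s.strip()
            )
        items.append(
            ResourceItem(
                name=str(row.name),
                unit_cost=float(row.unit_cost),
                currency=str(row.currency),
                annual_frequency=float(row.annual_frequency),
                proportion_using=float(row.proportion_using),
                applies_to_stages=stages,
                applies_to_years=str(row.phase).upper(),
            )
        )
    return items


# --------------------------------------------------------------- traces


def write_trace(trace, path: str | Path) -> None:
    df = trace.to_frame()
    df[list(STAGE_LABELS)] = df[list(STAGE_LABELS)].round(4)
    df[["discounted_cost", "discounted_qaly"]] = df[
        ["discounted_cost", "discounted_qaly"]
    ].round(4)
    df.to_csv(path, index=False)


def write_psa_samples(result: PSAResult, path: str | Path) -> None:
    df = result.to_frame()
    df[["total_cost", "cost_per_qaly"]] = df[["total_cost", "cost_per_qaly"]].round(2)
    df["total_qalys"] = df["total_qalys"].round(4)
    df.to_csv(path, index=False)


def write_tornado(entries: Sequence[TornadoEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "parameter": e.parameter_name,
                "low_total_cost": round(e.low_total_cost, 2),
                "high_total_cost": round(e.high_total_cost, 2),
                "impact_pct": round(e.impact_pct, 4),
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- config


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def _model_config(cfg: dict) -> ModelConfig:
    return ModelConfig(
        horizon_years=int(cfg.get("horizon_years", 5)),
        discount_rate_costs=float(cfg.get("discount_rate_costs", 0.05)),
        discount_rate_qalys=float(cfg.get("discount_rate_qalys", 0.05)),
        wtp_per_qaly=float(cfg.get("wtp_per_qaly", 13_790.0)),
    )


@dataclass
class PipelineResult:
    result: CUResult
    inputs: ModelInputs
    psa: Optional[PSAResult] = None
    tornado: Optional[list[TornadoEntry]] = None
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    config_path: str | Path, output_dir: str | Path | None = None
) -> PipelineResult:
    """Estimate (optional) -> build costs -> run cohort -> summarize ->
    optional PSA/tornado, writing trace, summary, and manifest."""
    cfg = load_config(config_path) or {}
    out = Path(output_dir or cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    mc = _model_config(cfg)
    currency = CurrencyConfig(float(cfg.get("exchange_rate_mxn_per_usd", 18.22)))

    # Inputs: estimated from a panel when one is configured, else fixtures
    stage = "inputs"
    try:
        baseline_fix, utilities, costs_fix = load_fixtures("table1")
        if cfg.get("panel"):
            panel = read_panel(cfg["panel"])
            baseline = estimate_baseline(panel)
            counts = count_transitions(panel, max_year=mc.horizon_years)
            transitions = estimate_transitions(
                counts, carry_forward_from=int(cfg.get("carry_forward_from", 3))
            )
        else:
            baseline = baseline_fix
            transitions = load_fixtures("table2")

        stage = "costing"
        items = None
        if cfg.get("resources"):
            items = read_resource_items(cfg["resources"])
            costs = build_cost_schedule(items, currency=currency)
        elif cfg.get("costs"):
            costs = read_cost_schedule(cfg["costs"])
        else:
            costs = costs_fix

        stage = "cohort"
        inputs = ModelInputs(baseline, transitions, costs, utilities, mc, items)
        trace = run_cohort(baseline, transitions, costs, utilities, mc)
        result = summarize(trace, mc)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    artifacts: dict[str, Path] = {}
    write_trace(trace, out / "trace.csv")
    artifacts["trace"] = out / "trace.csv"
    summary = result.to_dict()

    pipeline_psa = None
    psa_cfg = cfg.get("psa") or {}
    if psa_cfg.get("enabled"):
        stage = "psa"
        pconf = PSAConfig(
            n_iterations=int(psa_cfg.get("n_iterations", 10_000)),
            variation=float(psa_cfg.get("variation", 0.07)),
            seed=int(psa_cfg.get("seed", cfg.get("seed", 0))),
        )
        pipeline_psa = run_psa(inputs, pconf)
        write_psa_samples(pipeline_psa, out / "psa_samples.csv")
        artifacts["psa_samples"] = out / "psa_samples.csv"
        summary["psa"] = {
            "mean_cost": round(pipeline_psa.mean_cost, 2),
            "mean_qalys": round(pipeline_psa.mean_qalys, 4),
            "fraction_below_wtp": pipeline_psa.fraction_below_wtp,
        }

    pipeline_tornado = None
    t_cfg = cfg.get("tornado") or {}
    if t_cfg.get("enabled"):
        stage = "tornado"
        pipeline_tornado = tornado(
            inputs,
            t_cfg.get("parameters", []),
            variation=float(t_cfg.get("variation", 0.07)),
        )
        write_tornado(pipeline_tornado, out / "tornado.csv")
        artifacts["tornado"] = out / "tornado.csv"

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    artifacts["summary"] = out / "summary.json"

    manifest = {
        "config_path": str(Path(config_path).resolve()),
        "config": cfg,
        "seed": cfg.get("seed", 0),
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = out / "manifest.json"

    return PipelineResult(
        result=result,
        inputs=inputs,
        psa=pipeline_psa,
        tornado=pipeline_tornado,
        artifacts=artifacts,
    )
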