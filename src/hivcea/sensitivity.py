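"""Probabilistic and one-way (tornado) sensitivity analysis.

The probabilistic sensitivity analysis re-runs the cohort model under
independent multiplicative perturbation of every scalar input — unit
costs (or stage-cost cells when no resource table is attached),
utilities, baseline probabilities, and transition probabilities. Each
scalar is multiplied by an independent Uniform[1-v, 1+v] draw (v = 7%
by default, per Mexican economic-evaluation guidance); utilities are
clamped to [0, 1] and every probability structure is renormalized after
perturbation, so each draw is a valid model. The one-way (tornado)
analysis instead moves a single named parameter to (1-v)x and (1+v)x
and reports the resulting swing in total discounted cost as a percent
of the base case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .costing import CostSchedule, ResourceItem, build_cost_schedule
from .markov import (
    CUResult,
    ModelConfig,
    StageVector,
    TransitionSchedule,
    UtilitySchedule,
    run_cohort,
    summarize,
)
from .stages import N_STAGES, ImmuneStage

__all__ = [
    "ModelInputs",
    "PSAConfig",
    "PSAResult",
    "TornadoEntry",
    "perturb_inputs",
    "run_psa",
    "tornado",
]


@dataclass
class ModelInputs:
    """Everything one cohort run needs, bundled for joint perturbation.

    ``items`` optionally carries the resource-table decomposition of the
    cost schedule; when present, cost perturbations act on the items'
    unit costs (and tornado handles can name individual resources).
    """

    baseline: StageVector
    transitions: TransitionSchedule
    costs: CostSchedule
    utilities: UtilitySchedule
    config: ModelConfig = field(default_factory=ModelConfig)
    items: Optional[Sequence[ResourceItem]] = None

    def run(self) -> CUResult:
        trace = run_cohort(
            self.baseline, self.transitions, self.costs, self.utilities, self.config
        )
        return summarize(trace, self.config)


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings: iterations, variation width, seed."""

    n_iterations: int = 10_000
    variation: float = 0.07
    utility_variation: float | Sequence[tuple[float, float]] | None = None
    seed: int = 0
    distribution: str = "UNIFORM"

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if not 0.0 <= self.variation < 1.0:
            raise ValueError("variation must lie in [0, 1)")
        if self.distribution != "UNIFORM":
            raise ValueError("only the UNIFORM perturbation family is implemented")


@dataclass
class PSAResult:
    """Joint cost/QALY samples with summary statistics."""

    samples: np.ndarray  # (n, 2): total_cost, total_qalys
    mean_cost: float
    mean_qalys: float
    sd_cost: float
    sd_qalys: float
    ci_cost: tuple[float, float]  # 2.5/97.5 percentiles
    ci_qalys: tuple[float, float]
    ci_ratio: tuple[float, float]
    fraction_below_wtp: float

    @property
    def ratios(self) -> np.ndarray:
        return self.samples[:, 0] / self.samples[:, 1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=["total_cost", "total_qalys"])
        df.insert(0, "iteration", np.arange(len(df)))
        df["cost_per_qaly"] = self.ratios
        return df


@dataclass(frozen=True)
class TornadoEntry:
    """One-way swing of total cost when a single parameter moves +/-v."""

    parameter_name: str
    low_total_cost: float
    high_total_cost: float
    impact_pct: float


def _mult(rng: np.random.Generator, v: float, size=None):
    return rng.uniform(1.0 - v, 1.0 + v, size=size)


def perturb_inputs(
    base: ModelInputs, config: PSAConfig, rng: np.random.Generator
) -> ModelInputs:
    """One joint draw: every scalar input times an independent multiplier."""
    v = config.variation

    # Costs: perturb item unit costs when a resource table is attached,
    # otherwise the schedule cells directly.
    if base.items is not None:
        items = [
            replace(it, unit_cost=it.unit_cost * _mult(rng, v)) for it in base.items
        ]
        costs = build_cost_schedule(items)
    else:
        items = None
        costs = CostSchedule(
            base.costs.initial_cost * _mult(rng, v, N_STAGES),
            base.costs.incremental_cost * _mult(rng, v, N_STAGES),
        )

    # Utilities: same width unless overridden; clamp to the valid range.
    uv = config.utility_variation
    u = base.utilities.as_array()
    if uv is None or np.isscalar(uv):
        width = v if uv is None else float(uv)
        u = u * _mult(rng, width, N_STAGES)
    else:
        lohi = np.asarray(uv, dtype=float)
        if lohi.shape != (N_STAGES, 2):
            raise ValueError("per-stage utility ranges must be 4 (lo, hi) pairs")
        u = rng.uniform(lohi[:, 0], lohi[:, 1])
    utilities = UtilitySchedule(np.clip(u, 0.0, 1.0))

    p = base.baseline.as_array() * _mult(rng, v, N_STAGES)
    baseline = StageVector(p / p.sum())  # renormalize: deviation is by design

    matrices = {
        year: mat * _mult(rng, v, (N_STAGES, N_STAGES))
        for year, mat in base.transitions.matrices.items()
    }
    # wide thresholds: the deviation from 1 is by design here
    transitions = TransitionSchedule(matrices, warn_above=1.0, error_above=1.0)

    return ModelInputs(baseline, transitions, costs, utilities, base.config, items)


def run_psa(base: ModelInputs, config: PSAConfig = PSAConfig()) -> PSAResult:
    """Monte Carlo re-evaluation of the model under joint input uncertainty."""
    base.run()  # fail fast if the base case itself is broken
    rng = np.random.default_rng(config.seed)
    samples = np.empty((config.n_iterations, 2))
    for k in range(config.n_iterations):
        res = perturb_inputs(base, config, rng).run()
        samples[k] = (res.total_cost, res.total_qalys)

    ratios = samples[:, 0] / samples[:, 1]
    lo, hi = 2.5, 97.5
    return PSAResult(
        samples=samples,
        mean_cost=float(samples[:, 0].mean()),
        mean_qalys=float(samples[:, 1].mean()),
        sd_cost=float(samples[:, 0].std(ddof=1)) if len(samples) > 1 else 0.0,
        sd_qalys=float(samples[:, 1].std(ddof=1)) if len(samples) > 1 else 0.0,
        ci_cost=tuple(np.percentile(samples[:, 0], [lo, hi])),
        ci_qalys=tuple(np.percentile(samples[:, 1], [lo, hi])),
        ci_ratio=tuple(np.percentile(ratios, [lo, hi])),
        fraction_below_wtp=float((ratios <= base.config.wtp_per_qaly).mean()),
    )


def _apply_handle(base: ModelInputs, handle: str, factor: float) -> ModelInputs:
    """Return a copy of the inputs with one named scalar scaled by ``factor``.

    Handles: ``item:<name>`` (resource unit cost; needs an attached
    resource table), ``initial_cost:<STAGE>``, ``incremental_cost:<STAGE>``,
    ``utility:<STAGE>`` (clamped to [0,1]), ``baseline:<STAGE>``
    (renormalized afterwards).
    """
    kind, _, target = handle.partition(":")
    out = replace(base)
    if kind == "item":
        if base.items is None:
            raise ValueError("item handles need a resource-table decomposition")
        matched = [it for it in base.items if it.name == target]
        if not matched:
            raise ValueError(f"no resource item named {target!r}")
        items = [
            replace(it, unit_cost=it.unit_cost * factor) if it.name == target else it
            for it in base.items
        ]
        out.items = items
        out.costs = build_cost_schedule(items)
    elif kind in ("initial_cost", "incremental_cost"):
        s = int(ImmuneStage.from_label(target))
        init = base.costs.initial_cost.copy()
        incr = base.costs.incremental_cost.copy()
        (init if kind == "initial_cost" else incr)[s] *= factor
        out.costs = CostSchedule(init, incr)
        out.items = None  # the decomposition no longer matches the schedule
    elif kind == "utility":
        s = int(ImmuneStage.from_label(target))
        u = base.utilities.as_array()
        u[s] = min(1.0, max(0.0, u[s] * factor))
        out.utilities = UtilitySchedule(u)
    elif kind == "baseline":
        s = int(ImmuneStage.from_label(target))
        p = base.baseline.as_array()
        p[s] *= factor
        out.baseline = StageVector(p / p.sum())
    else:
        raise ValueError(f"unknown parameter handle {handle!r}")
    return out


def tornado(
    base: ModelInputs, parameters: Sequence[str], variation: float = 0.07
) -> list[TornadoEntry]:
    """One-way sensitivity of total cost, ranked by impact.

    ``impact_pct`` is the larger absolute deviation of the low/high runs
    from the base-case total cost, as a percent of the base case.
    """
    base_cost = base.run().total_cost
    entries = []
    for handle in parameters:
        low = _apply_handle(base, handle, 1.0 - variation).run().total_cost
        high = _apply_handle(base, handle, 1.0 + variation).run().total_cost
        impact = max(abs(low - base_cost), abs(high - base_cost)) / base_cost * 100.0
        entries.append(
            TornadoEntry(
                parameter_name=handle,
                low_total_cost=low,
                high_total_cost=high,
                impact_pct=impact,
            )
        )
    return sorted(entries, key=lambda e: e.impact_pct, reverse=True)
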