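"""Cohort categorization rules, sample size, panel summaries, budgets.

Categorization follows the clinic's reporting conventions: CD4 counts
fall into the four WHO immunological strata; a viral load under 50
copies/mL is undetectable (50 or above counts as unsuppressed); an
adherence index of 95 or more is adherent; age is reported in quartile
bands. The sample-size formula is the classic single-proportion margin
of error calculation. The budget projection scales the model's
per-person annual cost to a clinic population growing geometrically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import PanelDataset
from .markov import CUResult
from .stages import ImmuneStage, classify_cd4

__all__ = [
    "ViralLoadCategory",
    "AdherenceCategory",
    "CategorizationRules",
    "BudgetProjection",
    "classify_cd4",
    "classify_viral_load",
    "classify_adherence",
    "sample_size_proportion",
    "project_budget",
    "summarize_panel",
]


class ViralLoadCategory:
    UNDETECTABLE = "UNDETECTABLE"
    UNSUPPRESSED = "UNSUPPRESSED"


class AdherenceCategory:
    ADHERENT = "ADHERENT"
    NON_ADHERENT = "NON_ADHERENT"


@dataclass(frozen=True)
class CategorizationRules:
    """Thresholds used in descriptive panel summaries.

    The default age breaks reproduce the study's quartile bands
    (<28, 28-34, 35-42, >42 years); ``from_sample`` recomputes them as
    empirical quartiles of a supplied age vector.
    """

    viral_load_threshold: float = 50.0
    adherence_threshold: float = 95.0
    age_breaks: tuple[float, ...] = (28.0, 35.0, 43.0)

    def __post_init__(self):
        if self.viral_load_threshold <= 0 or self.adherence_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if list(self.age_breaks) != sorted(set(self.age_breaks)):
            raise ValueError("age breaks must be strictly increasing")

    @classmethod
    def from_sample(cls, ages: Sequence[float], **kwargs) -> "CategorizationRules":
        q = np.percentile(np.asarray(ages, float), [25, 50, 75])
        return cls(age_breaks=tuple(np.ceil(q)), **kwargs)

    def age_band(self, age: float) -> str:
        b = self.age_breaks
        edges = [f"<{b[0]:g}"] + [
            f"{b[i]:g}-{b[i + 1] - 1:g}" for i in range(len(b) - 1)
        ] + [f">{b[-1] - 1:g}"]
        return edges[int(np.searchsorted(b, age, side="right"))]


def classify_viral_load(copies: float, threshold: float = 50.0) -> str:
    """Undetectable below the assay threshold, unsuppressed at or above it."""
    if copies < 0:
        raise ValueError("viral load must be non-negative")
    return (
        ViralLoadCategory.UNDETECTABLE
        if copies < threshold
        else ViralLoadCategory.UNSUPPRESSED
    )


def classify_adherence(ai: float, threshold: float = 95.0) -> str:
    """Optimal adherence is an index at or above 95 on the 0-100 scale."""
    if not 0.0 <= ai <= 100.0:
        raise ValueError("adherence index must lie in [0, 100]")
    return (
        AdherenceCategory.ADHERENT if ai >= threshold else AdherenceCategory.NON_ADHERENT
    )


def sample_size_proportion(p: float, confidence: float = 0.95, margin: float = 0.05) -> int:
    """Classic descriptive-study sample size for one proportion.

    n = ceil(z^2 p (1-p) / d^2), z the two-sided normal quantile for the
    confidence level, d the margin of error.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if not 0.0 < confidence < 1.0 or not 0.0 < margin < 1.0:
        raise ValueError("confidence and margin must lie in (0, 1)")
    if p in (0.0, 1.0):
        warnings.warn("degenerate proportion: sample size is 0", stacklevel=2)
        return 0
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return math.ceil(z**2 * p * (1.0 - p) / margin**2)


@dataclass(frozen=True)
class BudgetProjection:
    """Clinic-level annual spending under geometric caseload growth."""

    per_person_annual_cost: float
    population: int
    growth_rate: float
    horizon: int
    series: np.ndarray  # total USD per year, years 0..horizon

    @property
    def year0_total(self) -> float:
        return float(self.series[0])


def project_budget(
    result: CUResult,
    population: int,
    growth_rate: float = 0.121,
    horizon: int = 5,
    model_horizon_years: int = 5,
) -> BudgetProjection:
    """Scale the per-person model cost to the clinic caseload over time.

    The per-person annual cost is the model's cumulative per-person cost
    divided by its horizon; year t of the series compounds the caseload
    by (1 + growth_rate)^t.
    """
    if population < 0:
        raise ValueError("population must be non-negative")
    if horizon < 1 or model_horizon_years < 1:
        raise ValueError("horizons must be at least one year")
    per_person = result.total_cost / model_horizon_years
    t = np.arange(horizon + 1)
    series = per_person * population * (1.0 + growth_rate) ** t
    return BudgetProjection(
        per_person_annual_cost=per_person,
        population=population,
        growth_rate=growth_rate,
        horizon=horizon,
        series=series,
    )


def summarize_panel(
    panel: PanelDataset, rules: CategorizationRules = CategorizationRules()
) -> pd.DataFrame:
    """Descriptive table of a panel's baseline characteristics.

    Counts and percentages per category (stage at year 0, viral
    suppression at year 0, adherence, gender, age band) and mean +/- SD
    for the continuous fields; empty optional fields are omitted.
    """
    if len(panel) == 0:
        raise ValueError("cannot summarize an empty panel")
    rows: list[dict] = []
    n = len(panel)

    def _cat(variable: str, labels: list[str]) -> None:
        if not labels:
            return
        vc = pd.Series(labels).value_counts()
        for cat, cnt in vc.items():
            rows.append(
                {
                    "variable": variable,
                    "category": cat,
                    "n": int(cnt),
                    "percent": round(100.0 * cnt / len(labels), 2),
                }
            )

    def _cont(variable: str, values: list[float]) -> None:
        if not values:
            return
        arr = np.asarray(values, float)
        rows.append(
            {
                "variable": variable,
                "category": "mean±sd",
                "mean": round(float(arr.mean()), 2),
                "sd": round(float(arr.std(ddof=1)), 2) if len(arr) > 1 else 0.0,
                "n": len(arr),
            }
        )

    base_stage, base_vl = [], []
    for rec in panel.records:
        obs = rec.baseline_observation
        if obs is not None:
            base_stage.append(classify_cd4(obs.cd4_count).name)
            if obs.viral_load is not None:
                base_vl.append(classify_viral_load(obs.viral_load, rules.viral_load_threshold))
    _cat("baseline_cd4_stage", base_stage)
    _cat("baseline_viral_load", base_vl)
    _cat(
        "adherence",
        [
            classify_adherence(r.adherence_index, rules.adherence_threshold)
            for r in panel.records
            if r.adherence_index is not None
        ],
    )
    _cat("gender", [r.gender for r in panel.records if r.gender is not None])
    _cat(
        "age_band",
        [rules.age_band(r.age) for r in panel.records if r.age is not None],
    )
    _cont(
        "adherence_index",
        [r.adherence_index for r in panel.records if r.adherence_index is not None],
    )
    _cont("age", [r.age for r in panel.records if r.age is not None])
    return pd.DataFrame(rows)
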