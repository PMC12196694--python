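"""Per-stage annual care costs from resource line items.

The annual cost of care for a stage is the sum over health resources of
unit cost x annual frequency of use x proportion of patients using the
resource, expressed in USD (MXN amounts are converted at a fixed
exchange rate). Stage costs are split into an *initial* (first year of
care) and an *incremental* (subsequent years) figure, the two columns
the Markov engine consumes. A cost schedule can also be supplied
directly as per-stage totals when the underlying resource table is not
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stages import N_STAGES, STAGE_LABELS, ImmuneStage

__all__ = [
    "Phase",
    "CurrencyConfig",
    "ResourceItem",
    "CostSchedule",
    "convert",
    "stage_annual_cost",
    "build_cost_schedule",
    "decompose_schedule_with_drug",
    "DRUG_MONTHLY_COST_USD",
    "DRUG_ANNUAL_COST_USD",
]

# Negotiated public-sector price of the BIC/FTC/TAF single-tablet regimen.
DRUG_MONTHLY_COST_USD = 94.40
DRUG_ANNUAL_COST_USD = DRUG_MONTHLY_COST_USD * 12  # 12 monthly dispensations


class Phase:
    """Which model years a resource applies to."""

    INITIAL = "INITIAL"  # first year of care (cycle 1 costs, accrued at t=0)
    SUBSEQUENT = "SUBSEQUENT"  # maintenance years (cycles 2+)
    BOTH = "BOTH"


@dataclass(frozen=True)
class CurrencyConfig:
    """Fixed MXN/USD exchange rate (2024 Banxico average by default)."""

    mxn_per_usd: float = 18.22

    def __post_init__(self):
        if self.mxn_per_usd <= 0:
            raise ValueError("exchange rate must be positive")


def convert(amount: float, currency: str, config: CurrencyConfig = CurrencyConfig()) -> float:
    """Express a money amount in USD."""
    if amount < 0:
        raise ValueError("money amounts must be non-negative")
    code = currency.upper()
    if code == "USD":
        return float(amount)
    if code == "MXN":
        return float(amount) / config.mxn_per_usd
    raise ValueError(f"unknown currency code {currency!r}")


@dataclass(frozen=True)
class ResourceItem:
    """One line of the resource-use table: UC x F x P."""

    name: str
    unit_cost: float
    currency: str = "USD"
    annual_frequency: float = 1.0  # F, uses per year
    proportion_using: float = 1.0  # P, fraction of patients
    applies_to_stages: tuple[ImmuneStage, ...] = tuple(ImmuneStage)
    applies_to_years: str = Phase.BOTH

    def __post_init__(self):
        if self.unit_cost < 0:
            raise ValueError(f"{self.name}: unit cost must be non-negative")
        if self.annual_frequency < 0:
            raise ValueError(f"{self.name}: annual frequency must be non-negative")
        if not 0.0 <= self.proportion_using <= 1.0:
            raise ValueError(f"{self.name}: proportion using must lie in [0, 1]")
        if self.applies_to_years not in (Phase.INITIAL, Phase.SUBSEQUENT, Phase.BOTH):
            raise ValueError(f"{self.name}: bad phase {self.applies_to_years!r}")
        object.__setattr__(
            self, "applies_to_stages", tuple(ImmuneStage(s) for s in self.applies_to_stages)
        )

    def annual_cost_usd(self, config: CurrencyConfig = CurrencyConfig()) -> float:
        return convert(self.unit_cost, self.currency, config) * self.annual_frequency * self.proportion_using

    def applies(self, stage: ImmuneStage, phase: str) -> bool:
        return stage in self.applies_to_stages and self.applies_to_years in (phase, Phase.BOTH)


@dataclass(frozen=True)
class CostSchedule:
    """USD cost per stage: initial (cycle 1) and incremental (cycles 2+)."""

    initial_cost: np.ndarray
    incremental_cost: np.ndarray

    def __post_init__(self):
        for name in ("initial_cost", "incremental_cost"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_STAGES,):
                raise ValueError(f"{name}: expected {N_STAGES} stage costs")
            if np.any(arr < 0):
                raise ValueError(f"{name}: costs must be non-negative")
            object.__setattr__(self, name, arr)

    def scaled(self, k: float) -> "CostSchedule":
        return CostSchedule(self.initial_cost * k, self.incremental_cost * k)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": list(STAGE_LABELS),
                "initial_cost": np.round(self.initial_cost, 2),
                "incremental_cost": np.round(self.incremental_cost, 2),
            }
        )


def stage_annual_cost(
    items: Iterable[ResourceItem],
    stage: ImmuneStage,
    phase: str,
    currency: CurrencyConfig = CurrencyConfig(),
) -> float:
    """Sum UC x F x P in USD over the items applicable to a stage/phase."""
    if phase not in (Phase.INITIAL, Phase.SUBSEQUENT):
        raise ValueError(f"phase must be INITIAL or SUBSEQUENT, got {phase!r}")
    return sum(it.annual_cost_usd(currency) for it in items if it.applies(stage, phase))


def build_cost_schedule(
    items: Sequence[ResourceItem] | None = None,
    *,
    initial: Sequence[float] | None = None,
    incremental: Sequence[float] | None = None,
    currency: CurrencyConfig = CurrencyConfig(),
) -> CostSchedule:
    """Assemble the schedule from line items OR direct per-stage totals.

    Exactly one input mode must be used: either a resource table
    (``items``), from which each cell is computed with the cost
    equation, or both direct total vectors (``initial``/``incremental``).
    """
    direct = initial is not None or incremental is not None
    if (items is None) == (not direct):
        raise ValueError("supply either line items or direct stage totals, not both")
    if direct:
        if initial is None or incremental is None:
            raise ValueError("direct mode needs both initial and incremental totals")
        return CostSchedule(np.asarray(initial, float), np.asarray(incremental, float))
    init = [stage_annual_cost(items, s, Phase.INITIAL, currency) for s in ImmuneStage]
    incr = [stage_annual_cost(items, s, Phase.SUBSEQUENT, currency) for s in ImmuneStage]
    return CostSchedule(np.array(init), np.array(incr))


def decompose_schedule_with_drug(
    schedule: CostSchedule,
    drug_monthly_cost: float = DRUG_MONTHLY_COST_USD,
    drug_name: str = "BIC/FTC/TAF",
) -> list[ResourceItem]:
    """Split stage totals into a shared ART drug item plus per-stage residuals.

    Every patient receives the single-tablet regimen 12 times a year in
    every stage and phase; whatever the stage total exceeds the drug's
    annual cost by is carried as a residual "other services" item. This
    makes the drug's unit cost a single named handle for one-way
    sensitivity analysis while reproducing the original schedule exactly.
    """
    drug_annual = drug_monthly_cost * 12
    items = [
        ResourceItem(
            name=drug_name,
            unit_cost=drug_monthly_cost,
            annual_frequency=12,
            proportion_using=1.0,
            applies_to_years=Phase.BOTH,
        )
    ]
    for phase, totals in (
        (Phase.INITIAL, schedule.initial_cost),
        (Phase.SUBSEQUENT, schedule.incremental_cost),
    ):
        for stage in ImmuneStage:
            residual = totals[int(stage)] - drug_annual
            if residual < 0:
                raise ValueError(
                    f"{stage.name} {phase}: total {totals[int(stage)]:.2f} below drug cost"
                )
            items.append(
                ResourceItem(
                    name=f"other services {stage.name} {phase}",
                    unit_cost=residual,
                    annual_frequency=1,
                    proportion_using=1.0,
                    applies_to_stages=(stage,),
                    applies_to_years=phase,
                )
            )
    return items
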