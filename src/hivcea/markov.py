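"""Deterministic Markov cohort engine for the four CD4 stages.

The cohort is a probability distribution over the four immunological
strata. Each annual cycle multiplies the occupancy row-vector by a
year-specific row-stochastic transition matrix; transition matrices
beyond the last estimated year are carried forward unchanged. Costs and
QALY-weighted utilities are accrued at the six model times t = 0..5 of a
five-year horizon: stage-specific *initial* costs at t = 0 only,
*incremental* (maintenance) costs at t = 1..horizon, and
occupancy-weighted utilities at every evaluation point; each accrual is
discounted by (1+r)^-t. No half-cycle correction is applied and there is
no death state (the model describes outpatient care), although absorbing
rows are handled without special-casing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .stages import N_STAGES, STAGE_LABELS, ImmuneStage

if TYPE_CHECKING:  # pragma: no cover
    from .costing import CostSchedule

__all__ = [
    "StageVector",
    "TransitionSchedule",
    "UtilitySchedule",
    "ModelConfig",
    "CohortTrace",
    "CUResult",
    "advance",
    "run_cohort",
    "summarize",
    "microsim_oracle",
]

_TOL = 1e-9


def _renormalize(
    arr: np.ndarray, what: str, warn_above: float = 0.02, error_above: float = 0.05
) -> np.ndarray:
    """Divide a probability vector by its sum, policing how far off it was.

    Printed probability tables routinely sum to 0.99-1.01 because of
    independent rounding; such rows are silently rescaled. Larger
    discrepancies warn, and discrepancies beyond ``error_above`` raise.
    """
    arr = np.asarray(arr, dtype=float)
    if arr.shape != (N_STAGES,):
        raise ValueError(f"{what}: expected {N_STAGES} entries, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"{what}: negative probabilities not allowed")
    total = arr.sum()
    if total <= 0:
        raise ValueError(f"{what}: probabilities sum to {total}, cannot normalize")
    dev = abs(total - 1.0)
    if dev > error_above:
        raise ValueError(f"{what}: sum {total:.4f} deviates from 1 by more than {error_above}")
    if dev > warn_above:
        warnings.warn(
            f"{what}: sum {total:.4f} renormalized (deviation {dev:.4f})",
            stacklevel=3,
        )
    return arr / total


@dataclass(frozen=True)
class StageVector:
    """Probability distribution over the four CD4 stages."""

    p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", _renormalize(self.p, "stage vector"))

    def __getitem__(self, stage: ImmuneStage) -> float:
        return float(self.p[int(stage)])

    def as_array(self) -> np.ndarray:
        return self.p.copy()


@dataclass(frozen=True)
class UtilitySchedule:
    """Stage-indexed QALY weights (utility per year lived in the stage)."""

    u: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.u, dtype=float)
        if arr.shape != (N_STAGES,):
            raise ValueError(f"expected {N_STAGES} utilities, got shape {arr.shape}")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("utilities must lie in [0, 1]")
        object.__setattr__(self, "u", arr)

    def as_array(self) -> np.ndarray:
        return self.u.copy()


class TransitionSchedule:
    """Year-indexed 4x4 row-stochastic matrices with carry-forward.

    ``matrices`` maps the 1-based cycle number to its transition matrix
    (rows = origin stage, columns = destination stage). Lookups past
    ``last_estimated_year`` return the last estimated matrix — the
    standing assumption that later years behave like the last year with
    sufficient data.
    """

    def __init__(
        self,
        matrices: Mapping[int, np.ndarray],
        warn_above: float = 0.02,
        error_above: float = 0.05,
    ):
        if not matrices:
            raise ValueError("transition schedule needs at least one matrix")
        years = sorted(matrices)
        if years[0] != 1 or years != list(range(1, years[-1] + 1)):
            raise ValueError(f"matrix years must be contiguous from 1, got {years}")
        self.matrices: dict[int, np.ndarray] = {}
        for year, mat in matrices.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (N_STAGES, N_STAGES):
                raise ValueError(f"year {year}: matrix must be {N_STAGES}x{N_STAGES}")
            rows = [
                _renormalize(
                    mat[i], f"year {year} row {STAGE_LABELS[i]}", warn_above, error_above
                )
                for i in range(N_STAGES)
            ]
            self.matrices[year] = np.vstack(rows)
        self.last_estimated_year = years[-1]

    def matrix_for(self, year: int) -> np.ndarray:
        """Matrix governing cycle ``year`` (1-based); carries forward."""
        if year < 1:
            raise ValueError("cycle number must be >= 1")
        return self.matrices[min(year, self.last_estimated_year)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TransitionSchedule)
            and self.last_estimated_year == other.last_estimated_year
            and all(
                np.allclose(self.matrices[y], other.matrices[y]) for y in self.matrices
            )
        )


class AccrualConvention:
    """Single supported reward-timing convention (enumeration point)."""

    EVAL_AT_STAGE_START = "EVAL_AT_STAGE_START"


@dataclass(frozen=True)
class ModelConfig:
    """Run settings: horizon, discount rates, and the WTP threshold."""

    horizon_years: int = 5
    discount_rate_costs: float = 0.05
    discount_rate_qalys: float = 0.05
    wtp_per_qaly: float = 13_790.0
    accrual_convention: str = AccrualConvention.EVAL_AT_STAGE_START

    def __post_init__(self):
        if self.horizon_years < 1:
            raise ValueError("horizon must be at least one year")
        for r in (self.discount_rate_costs, self.discount_rate_qalys):
            if not 0.0 <= r < 1.0:
                raise ValueError("discount rates must lie in [0, 1)")
        if self.wtp_per_qaly <= 0:
            raise ValueError("willingness-to-pay must be positive")
        if self.accrual_convention != AccrualConvention.EVAL_AT_STAGE_START:
            raise ValueError(f"unsupported accrual convention {self.accrual_convention!r}")


@dataclass
class CohortTrace:
    """Stage occupancy and discounted accruals at model times t = 0..horizon."""

    occupancy: np.ndarray  # (horizon+1, 4)
    cost_accruals: np.ndarray  # (horizon+1,) discounted USD
    qaly_accruals: np.ndarray  # (horizon+1,) discounted QALYs

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=list(STAGE_LABELS))
        df.insert(0, "time", np.arange(self.occupancy.shape[0]))
        df["discounted_cost"] = self.cost_accruals
        df["discounted_qaly"] = self.qaly_accruals
        return df


@dataclass(frozen=True)
class CUResult:
    """Per-person totals and the cost-per-QALY verdict against WTP."""

    total_cost: float
    total_qalys: float
    cost_per_qaly: float
    below_wtp: bool

    def to_dict(self) -> dict:
        return {
            "total_cost": round(self.total_cost, 2),
            "total_qalys": round(self.total_qalys, 4),
            "cost_per_qaly": round(self.cost_per_qaly, 2),
            "below_wtp": self.below_wtp,
        }


def advance(state: StageVector, matrix: np.ndarray) -> StageVector:
    """One annual cycle: left-multiply the occupancy vector by the matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_STAGES, N_STAGES):
        raise ValueError(f"transition matrix must be {N_STAGES}x{N_STAGES}")
    if np.any(matrix < 0):
        raise ValueError("transition matrix entries must be non-negative")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("transition matrix rows must sum to 1; renormalize first")
    return StageVector(state.as_array() @ matrix)


def run_cohort(
    baseline: StageVector,
    transitions: TransitionSchedule,
    costs: "CostSchedule",
    utilities: UtilitySchedule,
    config: ModelConfig = ModelConfig(),
) -> CohortTrace:
    """Evolve the cohort and accrue discounted costs and QALYs.

    Occupancy row t is the distribution after t cycles. The t = 0 accrual
    uses the initial (first-year) stage costs undiscounted; rows 1..horizon
    use the incremental stage costs discounted at the cost rate. Utilities
    are accrued at all horizon+1 evaluation points at the QALY rate.
    """
    H = config.horizon_years
    occ = np.empty((H + 1, N_STAGES))
    occ[0] = baseline.as_array()
    state = baseline
    for t in range(1, H + 1):
        state = advance(state, transitions.matrix_for(t))
        occ[t] = state.as_array()

    rc, rq = config.discount_rate_costs, config.discount_rate_qalys
    t_idx = np.arange(H + 1)
    cost_acc = np.empty(H + 1)
    cost_acc[0] = occ[0] @ costs.initial_cost
    cost_acc[1:] = (occ[1:] @ costs.incremental_cost) / (1 + rc) ** t_idx[1:]
    qaly_acc = (occ @ utilities.as_array()) / (1 + rq) ** t_idx
    return CohortTrace(occupancy=occ, cost_accruals=cost_acc, qaly_accruals=qaly_acc)


def summarize(trace: CohortTrace, config: ModelConfig = ModelConfig()) -> CUResult:
    """Total the accruals and judge the cost-per-QALY against WTP."""
    total_cost = float(trace.cost_accruals.sum())
    total_qalys = float(trace.qaly_accruals.sum())
    if total_qalys <= 0:
        if total_cost == 0:
            ratio = 0.0
        else:
            raise ZeroDivisionError("total QALYs is zero; cost per QALY undefined")
    else:
        ratio = total_cost / total_qalys
    return CUResult(
        total_cost=total_cost,
        total_qalys=total_qalys,
        cost_per_qaly=ratio,
        below_wtp=ratio <= config.wtp_per_qaly,
    )


def microsim_oracle(
    baseline: StageVector,
    transitions: TransitionSchedule,
    costs: "CostSchedule",
    utilities: UtilitySchedule,
    config: ModelConfig = ModelConfig(),
    n_individuals: int = 200_000,
    seed: int = 0,
) -> CUResult:
    """Brute-force microsimulation cross-check of :func:`run_cohort`.

    Samples ``n_individuals`` stage paths by categorical draws from the
    same transition matrices and averages per-individual discounted
    accruals. Converges to the cohort-trace result as n grows; used as an
    independent oracle in tests, never as the production path.
    """
    if n_individuals < 1:
        raise ValueError("need at least one simulated individual")
    rng = np.random.default_rng(seed)
    H = config.horizon_years
    states = rng.choice(N_STAGES, size=n_individuals, p=baseline.as_array())

    rc, rq = config.discount_rate_costs, config.discount_rate_qalys
    cost = costs.initial_cost[states].astype(float)
    qaly = utilities.as_array()[states].astype(float)
    for t in range(1, H + 1):
        mat = transitions.matrix_for(t)
        cum = np.cumsum(mat, axis=1)[states]  # (n, 4)
        u = rng.random(n_individuals)
        # clamp guards the float-rounding case where u exceeds the last cumsum
        states = np.minimum((u[:, None] > cum).sum(axis=1), N_STAGES - 1)
        cost += costs.incremental_cost[states] / (1 + rc) ** t
        qaly += utilities.as_array()[states] / (1 + rq) ** t

    total_cost = float(cost.mean())
    total_qalys = float(qaly.mean())
    ratio = total_cost / total_qalys if total_qalys > 0 else 0.0
    return CUResult(
        total_cost=total_cost,
        total_qalys=total_qalys,
        cost_per_qaly=ratio,
        below_wtp=ratio <= config.wtp_per_qaly,
    )
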