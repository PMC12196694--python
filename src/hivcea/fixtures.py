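"""Packaged model inputs: baseline mix, utilities, stage costs, matrices.

The published model inputs ship as small CSV files inside the package:
``table1.csv`` holds the baseline stage distribution, stage utility
scores, and initial/incremental stage costs; ``table2_year{1,2,3}.csv``
hold the year-specific transition matrices (rows = origin stage,
columns = destination stage; the year-3 matrix carries forward to years
4 and 5). Printed probability rows can sum to 0.99-1.01 from rounding;
they are renormalized at load time.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .costing import CostSchedule
from .markov import StageVector, TransitionSchedule, UtilitySchedule
from .stages import STAGE_LABELS

__all__ = [
    "load_fixtures",
    "table1_baseline",
    "table1_utilities",
    "table1_costs",
    "table2_transitions",
]

_LAST_ESTIMATED_YEAR = 3


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("hivcea.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _table1() -> pd.DataFrame:
    df = _read_csv("table1.csv")
    if list(df["stage"]) != list(STAGE_LABELS):
        raise ValueError("table1 fixture: unexpected stage ordering")
    return df


def table1_baseline() -> StageVector:
    return StageVector(_table1()["baseline_probability"].to_numpy())


def table1_utilities() -> UtilitySchedule:
    return UtilitySchedule(_table1()["utility"].to_numpy())


def table1_costs() -> CostSchedule:
    df = _table1()
    return CostSchedule(
        df["initial_cost"].to_numpy(), df["incremental_cost"].to_numpy()
    )


def table2_transitions(warn_above: float = 0.005) -> TransitionSchedule:
    matrices = {}
    for year in range(1, _LAST_ESTIMATED_YEAR + 1):
        df = _read_csv(f"table2_year{year}.csv")
        if list(df["stage"]) != list(STAGE_LABELS) or list(df.columns[1:]) != list(
            STAGE_LABELS
        ):
            raise ValueError(f"table2 year {year} fixture: unexpected stage labels")
        matrices[year] = df[list(STAGE_LABELS)].to_numpy(dtype=float)
    return TransitionSchedule(matrices, warn_above=warn_above)


def load_fixtures(name: str):
    """Load a named packaged fixture set.

    ``"table1"`` returns ``(StageVector, UtilitySchedule, CostSchedule)``;
    ``"table2"`` returns the :class:`TransitionSchedule` with year-3
    carry-forward.
    """
    if name == "table1":
        return table1_baseline(), table1_utilities(), table1_costs()
    if name == "table2":
        return table2_transitions()
    raise ValueError(f"unknown fixture {name!r}; expected 'table1' or 'table2'")
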