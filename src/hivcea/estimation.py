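"""Transition-matrix and baseline estimation from longitudinal CD4 panels.

Patients are observed once per year of care; each CD4 count classifies
into one of the four immunological stages. Baseline occupancy is the
stage frequency at year 0 among ART-naive patients. Year-specific
transition matrices are maximum-likelihood multinomial row proportions
of the observed (stage at year t-1, stage at year t) pairs; pairs
spanning a missing year are skipped rather than interpolated. Years
beyond the last estimable one carry the last matrix forward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .markov import StageVector, TransitionSchedule
from .stages import N_STAGES, classify_cd4

__all__ = [
    "Observation",
    "PatientRecord",
    "PanelDataset",
    "TransitionCounts",
    "estimate_baseline",
    "count_transitions",
    "estimate_transitions",
]


@dataclass(frozen=True)
class Observation:
    """One patient-year: CD4 count plus optional viral load."""

    year_index: int
    cd4_count: float
    viral_load: Optional[float] = None

    def __post_init__(self):
        if self.year_index < 0:
            raise ValueError("year index must be >= 0")
        if self.cd4_count < 0:
            raise ValueError("CD4 count must be >= 0")
        if self.viral_load is not None and self.viral_load < 0:
            raise ValueError("viral load must be >= 0")


@dataclass
class PatientRecord:
    """A patient's yearly CD4 trajectory with optional covariates."""

    patient_id: str
    observations: Sequence[Observation]
    art_naive: bool = True
    age: Optional[float] = None
    gender: Optional[str] = None
    adherence_index: Optional[float] = None

    def __post_init__(self):
        years = [o.year_index for o in self.observations]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"{self.patient_id}: year indices must be strictly increasing")

    @property
    def baseline_observation(self) -> Optional[Observation]:
        return next((o for o in self.observations if o.year_index == 0), None)


@dataclass
class PanelDataset:
    """Collection of patient records with unique ids."""

    records: Sequence[PatientRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def filter_art_naive(self) -> "PanelDataset":
        return PanelDataset(
            [r for r in self.records if r.art_naive], provenance=self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format, one row per patient-year."""
        rows = []
        for r in self.records:
            for o in r.observations:
                rows.append(
                    {
                        "patient_id": r.patient_id,
                        "year_index": o.year_index,
                        "cd4_count": o.cd4_count,
                        "viral_load": o.viral_load,
                        "age": r.age,
                        "gender": r.gender,
                        "adherence_index": r.adherence_index,
                        "art_naive": r.art_naive,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "PanelDataset":
        has_vl = "viral_load" in df.columns
        records = []
        for pid, grp in df.groupby("patient_id", sort=True):
            grp = grp.sort_values("year_index")
            obs = [
                Observation(
                    int(row.year_index),
                    float(row.cd4_count),
                    (
                        None
                        if not has_vl or pd.isna(row.viral_load)
                        else float(row.viral_load)
                    ),
                )
                for row in grp.itertuples()
            ]
            first = grp.iloc[0]

            def _opt(col, cast=float):
                v = first.get(col)
                return None if v is None or pd.isna(v) else cast(v)

            records.append(
                PatientRecord(
                    patient_id=str(pid),
                    observations=obs,
                    art_naive=bool(first.get("art_naive", True)),
                    age=_opt("age"),
                    gender=_opt("gender", str),
                    adherence_index=_opt("adherence_index"),
                )
            )
        return cls(records, provenance=provenance)


@dataclass
class TransitionCounts:
    """Observed (origin stage, destination stage) pair counts per year."""

    counts: dict[int, np.ndarray]

    def total_pairs(self, year: int) -> int:
        return int(self.counts[year].sum())


def estimate_baseline(panel: PanelDataset) -> StageVector:
    """Stage frequencies of year-0 CD4 counts among ART-naive patients."""
    naive = panel.filter_art_naive()
    stages = []
    for rec in naive.records:
        obs = rec.baseline_observation
        if obs is None:
            raise ValueError(f"{rec.patient_id}: no year-0 observation for baseline")
        stages.append(int(classify_cd4(obs.cd4_count)))
    if not stages:
        raise ValueError("empty panel: cannot estimate a baseline distribution")
    freq = np.bincount(stages, minlength=N_STAGES).astype(float)
    return StageVector(freq / freq.sum())


def count_transitions(panel: PanelDataset, max_year: int) -> TransitionCounts:
    """Tally consecutive-year stage pairs up to ``max_year``.

    Only pairs of observations at years (t-1, t) contribute; a gap in a
    trajectory simply produces no count (no interpolation).
    """
    if max_year < 1:
        raise ValueError("max_year must be >= 1")
    counts = {t: np.zeros((N_STAGES, N_STAGES), dtype=int) for t in range(1, max_year + 1)}
    for rec in panel.records:
        years = np.array([o.year_index for o in rec.observations])
        if years.size < 2:
            continue
        stages = classify_cd4(np.array([o.cd4_count for o in rec.observations]))
        consecutive = np.flatnonzero((np.diff(years) == 1) & (years[1:] <= max_year))
        for k in consecutive:
            counts[int(years[k + 1])][stages[k], stages[k + 1]] += 1
    return TransitionCounts(counts)


def estimate_transitions(
    counts: TransitionCounts,
    carry_forward_from: int = 3,
    smoothing: float = 0.0,
) -> TransitionSchedule:
    """Row-normalize pair counts into a transition schedule.

    ``smoothing`` adds a Laplace pseudo-count to every cell before
    normalizing (useful for sparse synthetic panels). A row with no
    observations and no smoothing falls back to "stay in stage" (the
    identity row) with a warning. Years past ``carry_forward_from``
    resolve to its matrix through the schedule's carry-forward lookup.
    """
    if carry_forward_from < 1:
        raise ValueError("carry_forward_from must be >= 1")
    if smoothing < 0:
        raise ValueError("smoothing pseudo-count must be >= 0")
    missing = [t for t in range(1, carry_forward_from + 1) if t not in counts.counts]
    if missing:
        raise ValueError(f"counts missing for years {missing}")

    matrices = {}
    for t in range(1, carry_forward_from + 1):
        raw = counts.counts[t].astype(float) + smoothing
        totals = raw.sum(axis=1)
        mat = np.empty((N_STAGES, N_STAGES))
        for i in range(N_STAGES):
            if totals[i] > 0:
                mat[i] = raw[i] / totals[i]
            else:
                warnings.warn(
                    f"year {t}: no observed transitions out of stage {i}; "
                    "assuming patients remain in stage",
                    stacklevel=2,
                )
                mat[i] = np.eye(N_STAGES)[i]
        matrices[t] = mat
    return TransitionSchedule(matrices)
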