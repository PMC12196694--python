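"""WHO immunological staging of CD4 T-cell counts.

The four strata (<200, 200-349, 350-499, >=500 cells/uL) are the health
states of the Markov cohort model and the categories used throughout
panel summaries and transition estimation. The bins are half-open on the
left, so a count of exactly 200 falls in the 200-349 stratum and a count
of exactly 500 in the >=500 stratum.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = ["ImmuneStage", "N_STAGES", "STAGE_LABELS", "classify_cd4"]


class ImmuneStage(enum.IntEnum):
    """CD4 stratum; integer value doubles as the state index (worst first)."""

    CD4_LT_200 = 0
    CD4_200_349 = 1
    CD4_350_499 = 2
    CD4_GE_500 = 3

    @property
    def bounds(self) -> tuple[float, float]:
        """Half-open CD4 interval [lo, hi) in cells/uL."""
        return _BOUNDS[self]

    @classmethod
    def from_label(cls, label: str) -> "ImmuneStage":
        try:
            return cls[label.strip()]
        except KeyError:
            raise ValueError(
                f"unknown immune stage {label!r}; expected one of {STAGE_LABELS}"
            ) from None


_BOUNDS = {
    ImmuneStage.CD4_LT_200: (0.0, 200.0),
    ImmuneStage.CD4_200_349: (200.0, 350.0),
    ImmuneStage.CD4_350_499: (350.0, 500.0),
    ImmuneStage.CD4_GE_500: (500.0, float("inf")),
}

N_STAGES = 4
STAGE_LABELS = tuple(s.name for s in ImmuneStage)

# Bin edges for vectorized classification; right edge open.
_EDGES = np.array([200.0, 350.0, 500.0])


def classify_cd4(count):
    """Map CD4 count(s) in cells/uL to an :class:`ImmuneStage`.

    Accepts a scalar (returns an ImmuneStage) or an array (returns an
    integer array of stage indices). Negative counts are rejected.
    """
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("CD4 count must be non-negative")
    idx = np.searchsorted(_EDGES, arr, side="right")
    if arr.ndim == 0:
        return ImmuneStage(int(idx))
    return idx
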