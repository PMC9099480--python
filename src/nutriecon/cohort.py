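"""Deterministic cohort propagation and life-day accounting.

The cohort model starts the whole cohort on the normal ward and multiplies
the occupancy vector by the daily transition matrix once per cycle.
Occupancy is recorded at the start of each day and a full day of time (and
later, cost) accrues to the occupied state; there is no half-cycle
correction.  Over a 180-day horizon the trace therefore has 180 rows
(days 0 through 179) and the per-state life days are column sums of the
alive-state occupancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .states import (
    ALIVE_STATES,
    STATE_LABELS,
    HealthState,
    TransitionMatrix,
)

__all__ = ["CohortTrace", "StateTallies", "run_cohort", "tally_life_days", "write_trace"]

_ROW_TOL = 1e-10


@dataclass
class CohortTrace:
    """Per-cycle occupancy fractions of the cohort.

    ``occupancy[t]`` is the start-of-day-``t`` distribution over the five
    states; row 0 puts all mass on WARD.
    """

    occupancy: np.ndarray
    horizon: int

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (self.horizon, len(HealthState)):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} does not match "
                f"horizon {self.horizon} x {len(HealthState)} states"
            )
        rows = self.occupancy.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            raise ValueError("trace rows must sum to 1")


@dataclass
class StateTallies:
    """Expected days per alive state over the horizon, plus end-of-horizon mortality.

    ``life_days`` maps each alive-state label to the expected number of days
    the cohort spends there; ``dead_fraction_at_end`` is the DEAD occupancy
    in the trace's final row.
    """

    life_days: dict[str, float]
    dead_fraction_at_end: float
    horizon: int

    @property
    def total_life_days(self) -> float:
        return float(sum(self.life_days.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.life_days[s.name] for s in ALIVE_STATES])


def run_cohort(matrix: TransitionMatrix, horizon: int) -> CohortTrace:
    """Propagate the cohort through ``horizon`` daily cycles.

    Parameters
    ----------
    matrix
        A valid daily transition matrix.
    horizon
        Number of daily cycles (rows in the returned trace), >= 1.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    matrix.require_valid()

    occupancy = np.zeros((horizon, len(HealthState)))
    occupancy[0, HealthState.WARD] = 1.0
    for t in range(1, horizon):
        occupancy[t] = occupancy[t - 1] @ matrix.probs
    return CohortTrace(occupancy, horizon)


def tally_life_days(trace: CohortTrace) -> StateTallies:
    """Column-sum the alive-state occupancy into expected life days per state."""
    sums = trace.occupancy.sum(axis=0)
    life_days = {s.name: float(sums[s]) for s in ALIVE_STATES}
    dead_fraction = float(trace.occupancy[-1, HealthState.DEAD])
    return StateTallies(life_days, dead_fraction, trace.horizon)


def write_trace(trace: CohortTrace, path: str | Path, *, metadata: dict | None = None) -> None:
    """Write a trace as a delimited table with a JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(trace.occupancy, columns=list(STATE_LABELS))
    frame.insert(0, "day", np.arange(trace.horizon))
    frame.to_csv(path, index=False)
    meta = {"horizon": trace.horizon}
    if metadata:
        meta.update(metadata)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
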