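"""Health-state space and daily transition matrices.

The model tracks hospitalized chronic-heart-failure patients through five
health states with one-day cycles:

* ``WARD`` — stable hospitalization on a normal ward (the sole initial state),
* ``COMPLICATION`` — an in-hospital complication such as myocardial
  infarction or arrhythmia, modeled as its own state because it carries a
  higher daily death risk,
* ``ICU`` — intensive-care treatment,
* ``DISCHARGED`` — alive post-discharge (non-elective readmission returns
  the patient to the ward),
* ``DEAD`` — absorbing.

A :class:`TransitionMatrix` couples a 5x5 row-stochastic probability matrix
with a boolean mask of structurally allowed transitions; everything outside
the mask must be exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "STATE_LABELS",
    "TransitionMatrix",
    "ValidationReport",
    "default_mask",
    "validate_matrix",
    "read_matrix",
    "write_matrix",
]


class HealthState(IntEnum):
    """The five health states, in canonical row/column order."""

    WARD = 0
    COMPLICATION = 1
    ICU = 2
    DISCHARGED = 3
    DEAD = 4


ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.WARD,
    HealthState.COMPLICATION,
    HealthState.ICU,
    HealthState.DISCHARGED,
)

STATE_LABELS: tuple[str, ...] = tuple(s.name for s in HealthState)

N_STATES = len(HealthState)

_ROW_SUM_TOL = 1e-12


def default_mask() -> np.ndarray:
    """Boolean mask of structurally allowed daily transitions.

    Ward patients may stay, develop a complication, move to the ICU, be
    discharged, or die.  Complication patients may additionally recover to
    the ward.  ICU patients return to the ward (or complication state) before
    discharge — no direct ICU-to-discharge jump.  Discharged patients may be
    readmitted to the ward or die.  Death is absorbing.  The mask is an input
    everywhere it matters, so alternative readings of the state diagram are
    expressible without touching code.
    """
    W, C, I, D, X = HealthState
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    mask[W, [W, C, I, D, X]] = True
    mask[C, [C, W, I, D, X]] = True
    mask[I, [I, W, C, X]] = True
    mask[D, [D, W, X]] = True
    mask[X, X] = True
    return mask


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of structural validation of a transition matrix."""

    violations: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


@dataclass
class TransitionMatrix:
    """A 5x5 daily transition-probability matrix with a structural mask.

    Parameters
    ----------
    probs
        Row-stochastic matrix; ``probs[i, j]`` is the probability of moving
        from state ``i`` to state ``j`` in one day.
    mask
        Boolean matrix of allowed transitions.  Defaults to
        :func:`default_mask`.
    """

    probs: np.ndarray
    mask: np.ndarray = field(default_factory=default_mask)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    def validate(self) -> ValidationReport:
        return validate_matrix(self)

    def require_valid(self) -> None:
        report = self.validate()
        if not report.ok:
            raise ValueError(
                "invalid transition matrix: " + "; ".join(report.violations)
            )


def validate_matrix(matrix: TransitionMatrix) -> ValidationReport:
    """Check every structural invariant; report violations, never raise.

    The checks: correct shape; entries within [0, 1]; each row summing to 1
    (within 1e-12); zero mass on masked-out transitions; DEAD absorbing.
    """
    violations: list[str] = []
    P, mask = matrix.probs, matrix.mask

    if P.shape != (N_STATES, N_STATES):
        return ValidationReport((f"shape: expected 5x5, got {P.shape}",))
    if mask.shape != (N_STATES, N_STATES):
        return ValidationReport((f"mask shape: expected 5x5, got {mask.shape}",))

    if not np.all(np.isfinite(P)):
        violations.append("non-finite entries present")
    else:
        if np.any(P < 0):
            bad = [f"{STATE_LABELS[i]}->{STATE_LABELS[j]}" for i, j in zip(*np.where(P < 0))]
            violations.append("negative entries: " + ", ".join(bad))
        if np.any(P > 1):
            bad = [f"{STATE_LABELS[i]}->{STATE_LABELS[j]}" for i, j in zip(*np.where(P > 1))]
            violations.append("entries above 1: " + ", ".join(bad))
        row_sums = P.sum(axis=1)
        for i, s in enumerate(row_sums):
            if abs(s - 1.0) > _ROW_SUM_TOL:
                violations.append(f"row-sum: {STATE_LABELS[i]} row sums to {s!r}, not 1")
        off_mask = P[~mask]
        if np.any(off_mask != 0.0):
            bad = [
                f"{STATE_LABELS[i]}->{STATE_LABELS[j]}"
                for i, j in zip(*np.where((~mask) & (P != 0.0)))
            ]
            violations.append("mask: probability mass on disallowed transitions: " + ", ".join(bad))
        dead = int(HealthState.DEAD)
        if P[dead, dead] != 1.0 or np.any(P[dead, :dead] != 0.0):
            violations.append("absorbing: DEAD row must be the unit vector onto DEAD")

    return ValidationReport(tuple(violations))


def write_matrix(matrix: TransitionMatrix, path: str | Path, *, metadata: dict | None = None) -> None:
    """Write a matrix as a labelled CSV, with a JSON metadata sidecar.

    The mask is stored alongside in ``<stem>.mask.csv`` so the pair
    round-trips; ``metadata`` (e.g. provenance of a calibrated matrix) goes
    to ``<stem>.meta.json``.
    """
    path = Path(path)
    frame = pd.DataFrame(matrix.probs, index=list(STATE_LABELS), columns=list(STATE_LABELS))
    frame.to_csv(path, index_label="state")
    mask_frame = pd.DataFrame(
        matrix.mask.astype(int), index=list(STATE_LABELS), columns=list(STATE_LABELS)
    )
    mask_frame.to_csv(path.with_suffix(".mask.csv"), index_label="state")
    if metadata is not None:
        path.with_suffix(".meta.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_matrix(path: str | Path) -> TransitionMatrix:
    """Read a matrix written by :func:`write_matrix`.

    Falls back to the default mask when no mask sidecar is present.
    """
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(STATE_LABELS) or list(frame.columns) != list(STATE_LABELS):
        raise ValueError(f"{path}: expected state labels {STATE_LABELS} as index and columns")
    mask_path = path.with_suffix(".mask.csv")
    if mask_path.exists():
        mask = pd.read_csv(mask_path, index_col=0).to_numpy().astype(bool)
    else:
        mask = default_mask()
    return TransitionMatrix(frame.to_numpy(dtype=float), mask)
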