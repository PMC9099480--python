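"""Recover arm-specific daily transition matrices from trial-level targets.

The published evidence gives each arm's expected days per health state over
180 days and its 180-day mortality, but not the daily transition
probabilities themselves.  This module inverts the cohort model: it searches
over valid transition matrices (respecting the structural mask) for one
whose 180-day tallies match the targets.

The fit is deliberately agnostic about identifiability — several matrices
can produce identical tallies, so downstream code and tests rely on target
recovery, never on recovering any particular matrix.

Parameterization: each alive row's masked entries are softmax-transformed
from unconstrained reals, which keeps every candidate row-stochastic and
mask-respecting by construction.  The objective is a weighted sum of squared
relative errors over the five targets (four life-day tallies and the dead
fraction), minimized by L-BFGS-B from several seeded starting points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import StateTallies, run_cohort, tally_life_days
from .states import ALIVE_STATES, HealthState, TransitionMatrix, default_mask

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "InfeasibleTargetsError",
    "calibrate_arm",
    "recovery_report",
]

# Relative errors are measured against max(target, floor) so that zero-valued
# targets still contribute a well-scaled penalty.
_DAY_FLOOR = 1.0
_FRACTION_FLOOR = 0.01

#: Feasibility line: a best fit whose worst per-target relative error exceeds
#: this means the model structure cannot express the targets.
FEASIBILITY_TOL = 0.10


@dataclass(frozen=True)
class CalibrationTargets:
    """Per-arm calibration targets over a fixed horizon.

    ``life_days`` maps alive-state labels (WARD, COMPLICATION, ICU,
    DISCHARGED) to expected days over the horizon; ``dead_fraction`` is the
    end-of-horizon mortality.  ``weights`` scale each target's squared
    relative error in the objective; mortality defaults to weight 5 because
    it is the trial's primary significant endpoint.
    """

    life_days: dict[str, float]
    dead_fraction: float
    horizon: int = 180
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "WARD": 1.0,
            "COMPLICATION": 1.0,
            "ICU": 1.0,
            "DISCHARGED": 1.0,
            "dead_fraction": 5.0,
        }
    )

    def __post_init__(self) -> None:
        missing = {s.name for s in ALIVE_STATES} - set(self.life_days)
        if missing:
            raise ValueError(f"life-day targets missing states: {sorted(missing)}")
        if any(v < 0 for v in self.life_days.values()):
            raise ValueError("life-day targets must be non-negative")
        if sum(self.life_days.values()) > self.horizon + 1e-9:
            raise ValueError("life-day targets exceed the horizon")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead fraction must lie in [0, 1]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in ALIVE_STATES) + ("dead_fraction",)

    def value(self, name: str) -> float:
        return self.dead_fraction if name == "dead_fraction" else self.life_days[name]

    def floor(self, name: str) -> float:
        return _FRACTION_FLOOR if name == "dead_fraction" else _DAY_FLOOR


@dataclass
class CalibrationResult:
    """A fitted transition matrix and how well it hits each target."""

    matrix: TransitionMatrix
    achieved: StateTallies
    objective: float
    relative_errors: dict[str, float]
    iterations: int
    n_starts: int
    terminated_why: str
    seed: int
    feasible: bool

    @property
    def max_relative_error(self) -> float:
        return max(self.relative_errors.values())


class InfeasibleTargetsError(RuntimeError):
    """Raised when no valid matrix brings every target within tolerance."""

    def __init__(self, result: CalibrationResult):
        self.result = result
        super().__init__(
            "calibration infeasible: worst relative error "
            f"{result.max_relative_error:.3f} exceeds {FEASIBILITY_TOL:.2f}"
        )


def _free_cells(mask: np.ndarray) -> list[np.ndarray]:
    """Masked column indices per alive row — the free parameters."""
    return [np.flatnonzero(mask[s]) for s in range(len(HealthState) - 1)]


def _theta_to_matrix(theta: np.ndarray, cells: list[np.ndarray], mask: np.ndarray) -> np.ndarray:
    P = np.zeros((len(HealthState), len(HealthState)))
    pos = 0
    for row, cols in enumerate(cells):
        t = theta[pos : pos + len(cols)]
        t = t - t.max()
        e = np.exp(t)
        P[row, cols] = e / e.sum()
        pos += len(cols)
    P[HealthState.DEAD, HealthState.DEAD] = 1.0
    return P


def _forward_tallies(P: np.ndarray, horizon: int) -> np.ndarray:
    """Fast path: per-state life days (alive states) then end dead fraction."""
    occ = np.zeros(len(HealthState))
    occ[HealthState.WARD] = 1.0
    sums = np.zeros(len(HealthState))
    for _ in range(horizon):
        sums += occ
        prev = occ
        occ = occ @ P
    # `prev` is the final (start-of-last-day) occupancy already counted in sums
    return np.append(sums[: HealthState.DEAD], prev[HealthState.DEAD])


def _objective(theta, cells, mask, target_vec, floor_vec, weight_vec, horizon):
    P = _theta_to_matrix(theta, cells, mask)
    achieved = _forward_tallies(P, horizon)
    rel = (achieved - target_vec) / np.maximum(target_vec, floor_vec)
    return float(np.dot(weight_vec, rel * rel))


def _heuristic_start(targets: CalibrationTargets, cells: list[np.ndarray]) -> np.ndarray:
    """A structured first start: heavy self-persistence, small daily death
    risk sized so cumulative mortality lands near the target."""
    daily_death = -np.log(max(1.0 - targets.dead_fraction, 1e-6)) / targets.horizon
    guess = np.full((len(HealthState), len(HealthState)), 1e-3)
    for s in ALIVE_STATES:
        share = targets.life_days[s.name] / targets.horizon
        guess[s, s] = max(0.5 + 0.45 * share, 1e-3)
        guess[s, HealthState.DEAD] = max(daily_death, 1e-6)
    theta = []
    for row, cols in enumerate(cells):
        theta.extend(np.log(guess[row, cols]))
    return np.asarray(theta)


def calibrate_arm(
    targets: CalibrationTargets,
    mask: np.ndarray | None = None,
    seed: int = 0,
    *,
    n_starts: int = 10,
    raise_on_infeasible: bool = True,
) -> CalibrationResult:
    """Fit a valid transition matrix to one arm's targets.

    Runs ``n_starts`` local L-BFGS-B searches over the softmax
    parameterization — one structured start plus seeded random starts — and
    keeps the best.  Identical ``seed`` and targets give identical fits.

    Raises :class:`InfeasibleTargetsError` when even the best fit leaves some
    target more than 10% off (relative), unless ``raise_on_infeasible`` is
    false, in which case the flagged result is returned for inspection.
    """
    if mask is None:
        mask = default_mask()
    cells = _free_cells(mask)
    names = targets.names
    target_vec = np.array([targets.value(n) for n in names])
    floor_vec = np.array([targets.floor(n) for n in names])
    weight_vec = np.array([targets.weights.get(n, 1.0) for n in names])

    rng = np.random.default_rng(seed)
    n_params = sum(len(c) for c in cells)
    starts = [_heuristic_start(targets, cells)]
    starts += [rng.normal(0.0, 1.5, size=n_params) for _ in range(n_starts - 1)]

    best = None
    total_iters = 0
    for theta0 in starts:
        res = minimize(
            _objective,
            theta0,
            args=(cells, mask, target_vec, floor_vec, weight_vec, targets.horizon),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        total_iters += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res

    P = _theta_to_matrix(best.x, cells, mask)
    matrix = TransitionMatrix(P, mask)
    achieved = tally_life_days(run_cohort(matrix, targets.horizon))

    achieved_vec = np.append(achieved.as_array(), achieved.dead_fraction_at_end)
    rel_errors = {
        n: float(abs(a - t) / max(t, f))
        for n, a, t, f in zip(names, achieved_vec, target_vec, floor_vec)
    }
    feasible = max(rel_errors.values()) <= FEASIBILITY_TOL
    result = CalibrationResult(
        matrix=matrix,
        achieved=achieved,
        objective=float(best.fun),
        relative_errors=rel_errors,
        iterations=total_iters,
        n_starts=n_starts,
        terminated_why=str(best.message),
        seed=seed,
        feasible=feasible,
    )
    if not feasible and raise_on_infeasible:
        raise InfeasibleTargetsError(result)
    return result


def recovery_report(result: CalibrationResult, targets: CalibrationTargets) -> pd.DataFrame:
    """Tabulate target vs achieved values with absolute and relative errors."""
    rows = []
    achieved_vec = np.append(
        result.achieved.as_array(), result.achieved.dead_fraction_at_end
    )
    for name, achieved in zip(targets.names, achieved_vec):
        target = targets.value(name)
        rows.append(
            {
                "target_name": name,
                "target": target,
                "achieved": float(achieved),
                "abs_error": float(abs(achieved - target)),
                "rel_error": result.relative_errors[name],
            }
        )
    return pd.DataFrame(rows)
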