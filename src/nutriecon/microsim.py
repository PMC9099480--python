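"""Individual-level Monte Carlo cross-check of the cohort model.

Simulates patients one day at a time from the same daily transition matrix
the cohort model uses.  Sample-mean life days per state converge to the
cohort tallies (law of large numbers), which the test suite exploits as an
equivalence check.  All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

import numpy as np

from .cohort import StateTallies
from .states import ALIVE_STATES, HealthState, TransitionMatrix

__all__ = ["simulate_individuals", "simulate_states"]


def simulate_states(
    matrix: TransitionMatrix, n: int, horizon: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample an ``n x horizon`` integer array of daily states.

    Column ``t`` holds each patient's state at the start of day ``t``;
    everyone starts on the ward.  Vectorized across patients: each day the
    alive patients in a given state draw their next state from that state's
    row via inverse-CDF sampling.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    matrix.require_valid()

    cum = np.cumsum(matrix.probs, axis=1)
    cum[:, -1] = 1.0  # guard against float round-off in searchsorted
    states = np.full((n, horizon), int(HealthState.DEAD), dtype=np.int8)
    current = np.full(n, int(HealthState.WARD), dtype=np.int8)
    states[:, 0] = current
    for t in range(1, horizon):
        u = rng.random(n)
        nxt = np.empty_like(current)
        for s in range(len(HealthState)):
            in_s = current == s
            if not in_s.any():
                continue
            nxt[in_s] = np.searchsorted(cum[s], u[in_s], side="right")
        current = nxt
        states[:, t] = current
    return states


def simulate_individuals(
    matrix: TransitionMatrix, n: int, horizon: int, seed: int
) -> tuple[StateTallies, np.ndarray]:
    """Monte Carlo estimate of per-state life days and end-of-horizon mortality.

    Returns the sample-mean tallies (same container the cohort model fills)
    together with the per-patient day counts, an ``n x 5`` integer array.
    Identical seeds yield identical output.
    """
    rng = np.random.default_rng(seed)
    states = simulate_states(matrix, n, horizon, rng)

    day_counts = np.zeros((n, len(HealthState)), dtype=np.int64)
    for s in range(len(HealthState)):
        day_counts[:, s] = (states == s).sum(axis=1)

    mean_days = day_counts.mean(axis=0)
    life_days = {s.name: float(mean_days[s]) for s in ALIVE_STATES}
    dead_fraction = float(np.mean(states[:, -1] == int(HealthState.DEAD)))
    return StateTallies(life_days, dead_fraction, horizon), day_counts
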