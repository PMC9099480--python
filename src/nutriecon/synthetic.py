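"""Synthetic patient-level trials with the structure the model assumes.

No patient-level data accompany the published evidence, so this module
generates them: each arm's patients walk the five-state chain day by day
under that arm's transition matrix, producing a long-format trajectory
table (one row per patient-day).  The same table supports the reverse
direction — maximum-likelihood estimation of a transition matrix from
observed day-to-day transition counts — giving the round-trip
(generate, estimate, re-run) that validates calibration and estimation
without external data.

Arms draw from independent RNG substreams spawned off the master seed, so
regenerating one arm never perturbs the other.  Death is recorded as a
single terminal row; days after death are not emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import StateTallies
from .microsim import simulate_states
from .states import ALIVE_STATES, STATE_LABELS, HealthState, TransitionMatrix, default_mask

__all__ = ["generate_trial", "estimate_matrix", "summarize_trial", "MatrixEstimate"]

#: Trial arm sizes: 321 intervention, 324 control patients.
DEFAULT_ARM_SIZES = {"intervention": 321, "control": 324}


def _arm_rows(
    matrix: TransitionMatrix,
    n: int,
    horizon: int,
    arm: str,
    rng: np.random.Generator,
    id_offset: int,
) -> pd.DataFrame:
    states = simulate_states(matrix, n, horizon, rng)
    dead = states == int(HealthState.DEAD)
    ever_dead = dead.any(axis=1)
    first_dead = np.where(ever_dead, dead.argmax(axis=1), horizon - 1)
    # keep alive days plus one terminal DEAD row for decedents
    keep = np.where(ever_dead, first_dead + 1, horizon)

    patient_id = np.repeat(np.arange(n) + id_offset, keep)
    day = np.concatenate([np.arange(k) for k in keep])
    state_idx = states[np.repeat(np.arange(n), keep), day]
    labels = np.array(STATE_LABELS)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "arm": arm,
            "day": day,
            "state": labels[state_idx],
        }
    )


def generate_trial(
    matrix_intv: TransitionMatrix,
    matrix_ctrl: TransitionMatrix,
    n_intv: int = DEFAULT_ARM_SIZES["intervention"],
    n_ctrl: int = DEFAULT_ARM_SIZES["control"],
    horizon: int = 180,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-arm trial as a long patient-day table.

    Columns: ``patient_id`` (unique across arms), ``arm``, ``day`` (0-based)
    and ``state``.  Every patient starts on the ward on day 0; a death
    contributes one terminal DEAD row.  Seed-deterministic, with per-arm
    substreams.
    """
    if n_intv < 1 or n_ctrl < 1:
        raise ValueError("arm sizes must be >= 1")
    ss_intv, ss_ctrl = np.random.SeedSequence(seed).spawn(2)
    intv = _arm_rows(
        matrix_intv, n_intv, horizon, "intervention", np.random.default_rng(ss_intv), 0
    )
    ctrl = _arm_rows(
        matrix_ctrl, n_ctrl, horizon, "control", np.random.default_rng(ss_ctrl), n_intv
    )
    return pd.concat([intv, ctrl], ignore_index=True)


@dataclass
class MatrixEstimate:
    """A maximum-likelihood transition matrix with its evidence.

    ``counts[i, j]`` is the number of observed i-to-j day transitions;
    ``unobserved_states`` lists alive states never departed from, whose rows
    default to self-loops.
    """

    matrix: TransitionMatrix
    counts: np.ndarray
    unobserved_states: tuple[str, ...]


def estimate_matrix(
    trajectories: pd.DataFrame, arm: str, mask: np.ndarray | None = None
) -> MatrixEstimate:
    """Estimate a daily transition matrix from one arm's trajectories.

    Entry (i, j) is the observed count of i-to-j transitions divided by the
    observed departures from i; masked-out cells are forced to zero and rows
    renormalized.  Alive states never observed as a departure point get a
    self-loop row and are flagged.
    """
    if mask is None:
        mask = default_mask()
    if trajectories.empty:
        raise ValueError("empty trajectory table")
    sub = trajectories[trajectories["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no trajectories for arm {arm!r}")

    sub = sub.sort_values(["patient_id", "day"])
    state_code = {label: i for i, label in enumerate(STATE_LABELS)}
    codes = sub["state"].map(state_code).to_numpy()
    pid = sub["patient_id"].to_numpy()
    day = sub["day"].to_numpy()

    same_patient = pid[1:] == pid[:-1]
    consecutive = day[1:] == day[:-1] + 1
    pair = same_patient & consecutive
    frm = codes[:-1][pair]
    to = codes[1:][pair]

    n = len(HealthState)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (frm, to), 1)

    probs = np.zeros((n, n))
    unobserved: list[str] = []
    masked_counts = np.where(mask, counts, 0)
    for s in range(n - 1):
        row_total = masked_counts[s].sum()
        if row_total == 0:
            probs[s, s] = 1.0
            unobserved.append(STATE_LABELS[s])
        else:
            probs[s] = masked_counts[s] / row_total
    probs[HealthState.DEAD, HealthState.DEAD] = 1.0

    # self-loops of unobserved states must be structurally legal for the
    # estimate to validate; widen the mask on just those diagonal cells
    est_mask = mask.copy()
    for label in unobserved:
        est_mask[state_code[label], state_code[label]] = True
    return MatrixEstimate(TransitionMatrix(probs, est_mask), counts, tuple(unobserved))


def summarize_trial(
    trajectories: pd.DataFrame, horizon: int = 180
) -> dict[str, tuple[StateTallies, int]]:
    """Per-arm mean life days per state and mortality.

    Returns ``{arm: (tallies, n_patients)}``; an arm with no rows is simply
    absent from the result.  The DEAD terminal rows count toward mortality,
    never toward life days.
    """
    if trajectories.empty:
        return {}
    out: dict[str, tuple[StateTallies, int]] = {}
    for arm, sub in trajectories.groupby("arm"):
        n = sub["patient_id"].nunique()
        state_days = sub.groupby("state").size()
        life_days = {
            s.name: float(state_days.get(s.name, 0)) / n for s in ALIVE_STATES
        }
        n_dead = sub.loc[sub["state"] == "DEAD", "patient_id"].nunique()
        out[str(arm)] = (StateTallies(life_days, n_dead / n, horizon), n)
    return out
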