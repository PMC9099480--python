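"""Shared fixtures: published base-case figures, calibrated arms, big trials.

Expensive artifacts (arm calibrations, the 50,000-patient recovery trial)
are session-scoped so every test file shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from nutriecon.calibration import CalibrationTargets, calibrate_arm
from nutriecon.cohort import StateTallies
from nutriecon.states import HealthState, TransitionMatrix, default_mask
from nutriecon.synthetic import generate_trial

# ---------------------------------------------------------------------------
# published base-case figures (trial-level inputs for calibration and the
# acceptance surface): per-state life days over 180 days, 180-day mortality,
# and the per-component costs of the base-case tables.

PUBLISHED_LIFE_DAYS = {
    "intervention": {"WARD": 123.84, "COMPLICATION": 10.09, "ICU": 1.88, "DISCHARGED": 18.77},
    "control": {"WARD": 111.24, "COMPLICATION": 14.20, "ICU": 1.90, "DISCHARGED": 21.47},
}
PUBLISHED_MORTALITY = {"intervention": 0.265, "control": 0.315}

PUBLISHED_COSTS = {
    "intervention": {
        "nutrition_inpatient": 679,
        "ward": 204_342,
        "icu": 8733,
        "complication": 15_263,
        "post_discharge": 19,
    },
    "control": {
        "nutrition_inpatient": 0,
        "ward": 183_544,
        "icu": 8857,
        "complication": 21_477,
        "post_discharge": 0,
    },
}
PUBLISHED_TOTALS = {"intervention": 229_036, "control": 213_878}

PUBLISHED_UTILITIES = {
    "intervention": {"WARD": 0.25, "ICU": 0.00, "COMPLICATION": 0.02, "DISCHARGED": 0.04},
    "control": {"WARD": 0.23, "ICU": 0.00, "COMPLICATION": 0.03, "DISCHARGED": 0.04},
}

# incremental table: component -> (delta cost SF, delta life days)
PUBLISHED_INCREMENTAL = {
    "nutrition_inpatient": (679, 0.0),
    "ward": (20_798, 12.60),
    "icu": (-123, -0.03),
    "complication": (-6214, -4.11),
    "post_discharge": (19, -2.70),
}
PUBLISHED_TOTAL_DELTA_COST = 15_159
PUBLISHED_TOTAL_DELTA_DAYS = 5.77
PUBLISHED_TOTAL_ICER = 2625
PUBLISHED_COMPLICATION_ICER = 1513


def published_targets(arm: str, horizon: int = 180) -> CalibrationTargets:
    return CalibrationTargets(
        life_days=dict(PUBLISHED_LIFE_DAYS[arm]),
        dead_fraction=PUBLISHED_MORTALITY[arm],
        horizon=horizon,
    )


def tallies_from(life_days: dict[str, float], dead: float, horizon: int = 180) -> StateTallies:
    return StateTallies(dict(life_days), dead, horizon)


# ---------------------------------------------------------------------------
# toy chains with closed-form behavior

def ward_discharge_toy() -> TransitionMatrix:
    """WARD stays or discharges with probability 1/2; DISCHARGED absorbing."""
    P = np.zeros((5, 5))
    P[HealthState.WARD, HealthState.WARD] = 0.5
    P[HealthState.WARD, HealthState.DISCHARGED] = 0.5
    P[HealthState.DISCHARGED, HealthState.DISCHARGED] = 1.0
    P[HealthState.COMPLICATION, HealthState.COMPLICATION] = 1.0
    P[HealthState.ICU, HealthState.ICU] = 1.0
    P[HealthState.DEAD, HealthState.DEAD] = 1.0
    mask = default_mask()
    mask[HealthState.ICU, HealthState.ICU] = True
    return TransitionMatrix(P, mask)


def random_valid_matrix(seed: int, min_death: float = 0.0) -> TransitionMatrix:
    """A random row-stochastic matrix respecting the default mask."""
    rng = np.random.default_rng(seed)
    mask = default_mask()
    P = np.zeros((5, 5))
    for i in range(4):
        cols = np.flatnonzero(mask[i])
        row = rng.dirichlet(np.ones(len(cols)))
        if min_death > 0:
            row = row * (1.0 - min_death)
            P[i, cols] = row
            P[i, HealthState.DEAD] += min_death + (1.0 - P[i].sum() - min_death)
        else:
            P[i, cols] = row
    P[4, 4] = 1.0
    # re-normalize exactly
    P[:4] /= P[:4].sum(axis=1, keepdims=True)
    return TransitionMatrix(P, mask)


# ---------------------------------------------------------------------------
# session-scoped heavy artifacts

@pytest.fixture(scope="session")
def intervention_calibration():
    return calibrate_arm(published_targets("intervention"), seed=20_220_420)


@pytest.fixture(scope="session")
def control_calibration():
    return calibrate_arm(published_targets("control"), seed=20_220_421)


#: ground-truth matrix for round-trip recovery: every masked transition has
#: appreciable probability so all states are well visited at trial scale.
RECOVERY_TRUTH = TransitionMatrix(
    np.array(
        [
            [0.88, 0.04, 0.02, 0.04, 0.02],
            [0.06, 0.84, 0.04, 0.03, 0.03],
            [0.10, 0.05, 0.80, 0.00, 0.05],
            [0.05, 0.00, 0.00, 0.93, 0.02],
            [0.00, 0.00, 0.00, 0.00, 1.00],
        ]
    )
)


@pytest.fixture(scope="session")
def recovery_trial():
    """50,000 intervention-arm patients simulated from RECOVERY_TRUTH."""
    return generate_trial(
        RECOVERY_TRUTH, RECOVERY_TRUTH, n_intv=50_000, n_ctrl=1, horizon=180, seed=11
    )
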