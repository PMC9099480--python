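"""Probabilistic sensitivity analysis over Gamma-distributed cost inputs.

Each daily unit cost carries a Gamma distribution parameterized by its mean
and standard deviation (moment matching: shape = (mean/sd)^2, scale =
sd^2/mean).  A PSA draw samples all five unit costs independently, holds the
life-day tallies fixed, and recomputes the incremental cost and ICER.
Because cost accrual is linear in unit costs and Gamma sampling is
mean-preserving, the PSA mean converges to the base case — a property the
test suite checks.  Transition probabilities and life days are not varied:
the input-uncertainty specification covers costs only.

Intervals are percentile-based (2.5/97.5), not normal-approximation, since
Gamma draws with large coefficients of variation are strongly skewed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import StateTallies
from .economics import CostInputs, accrue_costs, incremental_table

__all__ = ["GammaSpec", "PsaSummary", "gamma_from_mean_sd", "default_gamma_specs", "run_psa"]

# CostInputs fields that get a Gamma distribution in the PSA.
PSA_FIELDS = (
    "nutrition_inpatient_per_day",
    "nutrition_outpatient_per_day",
    "ward_per_day",
    "icu_per_day",
    "complication_per_day",
)

#: Standard deviations of the daily unit costs (SF) for probabilistic analysis.
DEFAULT_SDS = {
    "nutrition_inpatient_per_day": 1.0,
    "nutrition_outpatient_per_day": 1.0,
    "ward_per_day": 1485.0,
    "icu_per_day": 3900.0,
    "complication_per_day": 1477.0,
}


@dataclass(frozen=True)
class GammaSpec:
    """A Gamma distribution moment-matched to a mean and standard deviation."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    @property
    def shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.gamma(self.shape, self.scale, size=size)


def gamma_from_mean_sd(mean: float, sd: float) -> GammaSpec:
    """Moment-matched Gamma spec for a cost input."""
    return GammaSpec(mean, sd)


def default_gamma_specs(costs: CostInputs) -> dict[str, GammaSpec]:
    """One Gamma spec per unit cost, using the published standard deviations."""
    return {
        name: gamma_from_mean_sd(getattr(costs, name), DEFAULT_SDS[name])
        for name in PSA_FIELDS
    }


@dataclass(frozen=True)
class PsaSummary:
    """Summary of a probabilistic sensitivity analysis run."""

    n_draws: int
    seed: int
    draws: pd.DataFrame
    mean_delta_cost: float
    mean_icer: float
    delta_cost_interval: tuple[float, float]
    icer_interval: tuple[float, float]


def run_psa(
    intv_tallies: StateTallies,
    ctrl_tallies: StateTallies,
    costs: CostInputs,
    n_draws: int,
    seed: int,
    specs: dict[str, GammaSpec] | None = None,
) -> PsaSummary:
    """Monte Carlo propagation of unit-cost uncertainty to incremental results.

    Every draw replaces the five daily unit costs with independent Gamma
    samples, re-accrues both arms on the fixed tallies, and records the
    total incremental cost and the ICER per life day.  Seed-deterministic.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if specs is None:
        specs = default_gamma_specs(costs)
    unknown = set(specs) - set(PSA_FIELDS)
    if unknown:
        raise ValueError(f"unknown PSA inputs: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    samples = {name: spec.sample(rng, n_draws) for name, spec in specs.items()}

    records = []
    for i in range(n_draws):
        draw_costs = replace(costs, **{name: float(samples[name][i]) for name in specs})
        inc = incremental_table(
            (intv_tallies, accrue_costs(intv_tallies, draw_costs, "intervention")),
            (ctrl_tallies, accrue_costs(ctrl_tallies, draw_costs, "control")),
        )
        rec = {name: samples[name][i] for name in specs}
        rec["delta_cost_sf"] = inc.total_delta_cost
        rec["icer_sf_per_life_day"] = inc.total_icer.ratio
        records.append(rec)
    draws = pd.DataFrame(records)

    dc = draws["delta_cost_sf"].to_numpy()
    ic = draws["icer_sf_per_life_day"].to_numpy()
    return PsaSummary(
        n_draws=n_draws,
        seed=seed,
        draws=draws,
        mean_delta_cost=float(dc.mean()),
        mean_icer=float(ic.mean()),
        delta_cost_interval=(float(np.percentile(dc, 2.5)), float(np.percentile(dc, 97.5))),
        icer_interval=(float(np.percentile(ic, 2.5)), float(np.percentile(ic, 97.5))),
    )
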