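"""Cost and utility accrual, incremental tables, ICERs, and scenario analyses.

Costing follows the payer-perspective arithmetic of the underlying model:
each expected day in a state accrues that state's daily unit cost, death
accrues nothing, and nothing is discounted (the horizon is six months to a
year).  The intervention arm additionally accrues nutritional-support
costs — the inpatient supplement price on every in-hospital day (ward,
complication, and ICU alike) and, for the configured fraction of discharged
patients who continue supplements at home, the outpatient price on each
post-discharge day.  The control arm accrues no nutrition costs.

Incremental results are intervention minus control, component by component.
ICERs divide an incremental cost by an incremental effect measured in life
days (or life years after extrapolation to 365 days).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .cohort import StateTallies, run_cohort, tally_life_days
from .states import ALIVE_STATES, TransitionMatrix

__all__ = [
    "ARMS",
    "SF_TO_EUR",
    "CostInputs",
    "UtilityWeights",
    "CostBreakdown",
    "IcerResult",
    "IncrementalResult",
    "ThresholdResult",
    "accrue_costs",
    "accrue_utilities",
    "icer",
    "incremental_table",
    "deterministic_sa",
    "extrapolate",
    "threshold_nutrition_cost",
]

ARMS = ("intervention", "control")

#: Fixed display conversion, Swiss francs to euro.
SF_TO_EUR = 0.95

# Incremental-table component keys, in report order.
COMPONENTS = ("nutrition_inpatient", "ward", "icu", "complication", "post_discharge")


@dataclass(frozen=True)
class CostInputs:
    """Daily unit costs in Swiss francs and the outpatient continuation fraction.

    Defaults are the base-case inputs: 5 SF/day for nutritional support in
    either setting, 1650 SF per ward day, 4654 SF per ICU day, 1513 SF per
    complication day, and 20% of discharged patients continuing supplements.
    """

    nutrition_inpatient_per_day: float = 5.0
    nutrition_outpatient_per_day: float = 5.0
    ward_per_day: float = 1650.0
    icu_per_day: float = 4654.0
    complication_per_day: float = 1513.0
    outpatient_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "nutrition_inpatient_per_day",
            "nutrition_outpatient_per_day",
            "ward_per_day",
            "icu_per_day",
            "complication_per_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.outpatient_fraction <= 1.0:
            raise ValueError("outpatient_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class UtilityWeights:
    """Per-state daily utility weights on a 0-1 scale; DEAD is fixed at 0.

    The default puts the same 0.002/day weight on every alive state, the
    value implied by the reported ward quality-adjusted life days.
    """

    ward: float = 0.002
    complication: float = 0.002
    icu: float = 0.002
    discharged: float = 0.002

    def __post_init__(self) -> None:
        for name in ("ward", "complication", "icu", "discharged"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"utility weight {name} must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "WARD": self.ward,
            "COMPLICATION": self.complication,
            "ICU": self.icu,
            "DISCHARGED": self.discharged,
        }


@dataclass(frozen=True)
class CostBreakdown:
    """Accrued per-component costs (SF) for one arm, plus optional QALDs."""

    nutrition_inpatient: float
    nutrition_outpatient: float
    ward: float
    icu: float
    complication: float
    qald_total: float | None = None

    @property
    def total(self) -> float:
        return (
            self.nutrition_inpatient
            + self.nutrition_outpatient
            + self.ward
            + self.icu
            + self.complication
        )

    def component(self, key: str) -> float:
        """Cost of one incremental-table component (outpatient nutrition sits
        in the post-discharge row, as in the published table)."""
        if key == "post_discharge":
            return self.nutrition_outpatient
        return getattr(self, key)


def accrue_costs(tallies: StateTallies, costs: CostInputs, arm: str) -> CostBreakdown:
    """Accrue the per-state costs of one arm from its expected life days.

    Ward, ICU and complication days cost their daily rates in both arms.
    Nutrition costs accrue only in the intervention arm: the inpatient
    supplement price on every in-hospital day, and the outpatient price on
    the continuing fraction of post-discharge days.  Death accrues nothing.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    days = tallies.life_days
    if any(v < 0 for v in days.values()):
        raise ValueError("life-day tallies must be non-negative")

    ward_days = days["WARD"]
    comp_days = days["COMPLICATION"]
    icu_days = days["ICU"]
    disch_days = days["DISCHARGED"]

    if arm == "intervention":
        in_hospital = ward_days + comp_days + icu_days
        nutrition_in = in_hospital * costs.nutrition_inpatient_per_day
        nutrition_out = (
            costs.outpatient_fraction * disch_days * costs.nutrition_outpatient_per_day
        )
    else:
        nutrition_in = 0.0
        nutrition_out = 0.0

    return CostBreakdown(
        nutrition_inpatient=nutrition_in,
        nutrition_outpatient=nutrition_out,
        ward=ward_days * costs.ward_per_day,
        icu=icu_days * costs.icu_per_day,
        complication=comp_days * costs.complication_per_day,
    )


def accrue_utilities(tallies: StateTallies, weights: UtilityWeights) -> dict[str, float]:
    """Quality-adjusted life days: per-state ``days x weight`` and their total."""
    w = weights.as_dict()
    per_state = {s.name: tallies.life_days[s.name] * w[s.name] for s in ALIVE_STATES}
    per_state["total"] = sum(per_state.values())
    return per_state


@dataclass(frozen=True)
class IcerResult:
    """An incremental cost-effectiveness ratio with its quadrant.

    ``quadrant`` is ``"dominant"`` when the intervention saves money and
    gains effect, ``"dominated"`` when it costs more and loses effect, and
    ``"trade-off"`` otherwise.  A zero effect difference leaves the ratio
    undefined (``defined=False``, ``ratio=nan``).
    """

    ratio: float
    quadrant: str
    defined: bool = True
    delta_cost: float = 0.0
    delta_effect: float = 0.0


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    """Cost difference over effect difference, with dominance classification."""
    if delta_cost < 0 and delta_effect > 0:
        quadrant = "dominant"
    elif delta_cost > 0 and delta_effect < 0:
        quadrant = "dominated"
    else:
        quadrant = "trade-off"
    if delta_effect == 0:
        return IcerResult(math.nan, quadrant, False, delta_cost, delta_effect)
    return IcerResult(delta_cost / delta_effect, quadrant, True, delta_cost, delta_effect)


@dataclass(frozen=True)
class IncrementalResult:
    """Component-wise cost and life-day differences, intervention minus control.

    ``components`` maps each component key to ``(delta_cost, delta_life_days,
    IcerResult)``; inpatient nutrition carries no life days of its own, so
    its ICER is flagged undefined.  ``effect_unit`` is ``"life day"`` for the
    base case and ``"life year"`` after extrapolation.
    """

    components: dict[str, tuple[float, float, IcerResult]]
    total_delta_cost: float
    total_delta_life_days: float
    total_icer: IcerResult
    horizon: int
    effect_unit: str = "life day"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component": key,
                "delta_cost_sf": dc,
                "delta_life_days": dd,
                "icer": res.ratio,
                "quadrant": res.quadrant,
            }
            for key, (dc, dd, res) in self.components.items()
        ]
        rows.append(
            {
                "component": "total",
                "delta_cost_sf": self.total_delta_cost,
                "delta_life_days": self.total_delta_life_days,
                "icer": self.total_icer.ratio,
                "quadrant": self.total_icer.quadrant,
            }
        )
        return pd.DataFrame(rows)


# Which life-day tally feeds each incremental component.
_COMPONENT_STATE = {
    "ward": "WARD",
    "icu": "ICU",
    "complication": "COMPLICATION",
    "post_discharge": "DISCHARGED",
}


def incremental_table(
    intv: tuple[StateTallies, CostBreakdown],
    ctrl: tuple[StateTallies, CostBreakdown],
    *,
    effect_unit: str = "life day",
) -> IncrementalResult:
    """Build the incremental cost/life-day table from both arms' results.

    Components follow the published layout: ward, ICU, complication and
    post-discharge rows each pair the state's cost difference with its
    life-day difference (outpatient nutrition is folded into the
    post-discharge row); inpatient nutrition is its own cost-only row.
    """
    intv_t, intv_c = intv
    ctrl_t, ctrl_c = ctrl
    if intv_t.horizon != ctrl_t.horizon:
        raise ValueError(
            f"arm horizons differ: {intv_t.horizon} vs {ctrl_t.horizon}"
        )

    per_year = effect_unit == "life year"
    divisor = 365.0 if per_year else 1.0

    components: dict[str, tuple[float, float, IcerResult]] = {}
    for key in COMPONENTS:
        d_cost = intv_c.component(key) - ctrl_c.component(key)
        if key in _COMPONENT_STATE:
            state = _COMPONENT_STATE[key]
            d_days = intv_t.life_days[state] - ctrl_t.life_days[state]
        else:
            d_days = 0.0
        res = icer(d_cost, d_days / divisor)
        if key == "complication":
            # days in the complication state are a harm, not a benefit: the
            # row's dominance is judged on avoided complication days, so a
            # cheaper arm with fewer complication days is dominant
            res = replace(res, quadrant=icer(d_cost, -d_days).quadrant)
        components[key] = (d_cost, d_days, res)

    total_cost = intv_c.total - ctrl_c.total
    total_days = intv_t.total_life_days - ctrl_t.total_life_days
    return IncrementalResult(
        components=components,
        total_delta_cost=total_cost,
        total_delta_life_days=total_days,
        total_icer=icer(total_cost, total_days / divisor),
        horizon=intv_t.horizon,
        effect_unit=effect_unit,
    )


def _arm_results(
    intv_tallies: StateTallies,
    ctrl_tallies: StateTallies,
    costs: CostInputs,
    *,
    effect_unit: str = "life day",
) -> IncrementalResult:
    intv_c = accrue_costs(intv_tallies, costs, "intervention")
    ctrl_c = accrue_costs(ctrl_tallies, costs, "control")
    return incremental_table(
        (intv_tallies, intv_c), (ctrl_tallies, ctrl_c), effect_unit=effect_unit
    )


def deterministic_sa(
    intv_tallies: StateTallies,
    ctrl_tallies: StateTallies,
    costs: CostInputs,
    supplement_cost_grid: tuple[float, ...] = (5.0, 100.0, 1000.0),
    fraction_grid: tuple[float, ...] = (0.2, 0.5, 1.0),
) -> pd.DataFrame:
    """One-way/grid sensitivity analysis over supplement price and continuation.

    Re-runs cost accrual for every combination of supplement daily price
    (applied to both the inpatient and outpatient setting) and outpatient
    continuation fraction, holding the life-day tallies fixed.  Returns one
    row per scenario with the nutrition cost components and the total ICER.
    """
    if not supplement_cost_grid or not fraction_grid:
        raise ValueError("scenario grids must be non-empty")
    if any(c < 0 for c in supplement_cost_grid):
        raise ValueError("supplement costs must be >= 0")

    rows = []
    for supp, frac in itertools.product(supplement_cost_grid, fraction_grid):
        scenario_costs = replace(
            costs,
            nutrition_inpatient_per_day=supp,
            nutrition_outpatient_per_day=supp,
            outpatient_fraction=frac,
        )
        intv_c = accrue_costs(intv_tallies, scenario_costs, "intervention")
        inc = _arm_results(intv_tallies, ctrl_tallies, scenario_costs)
        rows.append(
            {
                "supplement_cost_per_day_sf": supp,
                "outpatient_fraction": frac,
                "nutrition_inpatient_sf": intv_c.nutrition_inpatient,
                "nutrition_outpatient_sf": intv_c.nutrition_outpatient,
                "total_delta_cost_sf": inc.total_delta_cost,
                "total_delta_life_days": inc.total_delta_life_days,
                "icer_sf_per_life_day": inc.total_icer.ratio,
            }
        )
    return pd.DataFrame(rows)


def extrapolate(
    matrix_intv: TransitionMatrix,
    matrix_ctrl: TransitionMatrix,
    costs: CostInputs,
    horizon: int = 365,
) -> IncrementalResult:
    """Extend both arms to a longer horizon and report the ICER per life-year.

    The daily transition matrices are unchanged (time-homogeneous
    extrapolation); accrual follows the base case, and the effect
    denominator becomes incremental life days divided by 365.
    """
    intv_t = tally_life_days(run_cohort(matrix_intv, horizon))
    ctrl_t = tally_life_days(run_cohort(matrix_ctrl, horizon))
    return _arm_results(intv_t, ctrl_t, costs, effect_unit="life year")


@dataclass(frozen=True)
class ThresholdResult:
    """Maximum admissible inpatient nutrition cost at a willingness-to-pay.

    ``max_nutrition_cost_sf`` is the total (per-patient, whole-horizon)
    inpatient nutritional-support cost at which the ICER equals the
    willingness-to-pay threshold; ``achieved_icer`` verifies the solve.
    """

    max_nutrition_cost_sf: float
    achieved_icer: float
    wtp_sf_per_life_year: float
    mode: str
    outpatient_fraction: float
    feasible: bool = True


def threshold_nutrition_cost(
    intv_tallies: StateTallies,
    ctrl_tallies: StateTallies,
    costs: CostInputs,
    *,
    wtp: float,
    mode: str = "nutrition-only",
    icer_tol: float = 1.0,
) -> ThresholdResult:
    """Solve for the largest inpatient nutrition cost still cost-effective.

    Finds the total inpatient nutritional-support cost ``c`` at which the
    cost-effectiveness ratio hits ``wtp`` (SF per life-year), by bisection on
    the ratio, which is monotone increasing in ``c``.  Outpatient supplement
    costs stay at their configured price and scale with the continuation
    fraction, so the admissible inpatient budget shrinks as more discharged
    patients continue support.  ``mode`` picks the numerator:

    * ``"nutrition-only"`` — nutrition costs alone are judged against the
      threshold (the default reading);
    * ``"full-incremental"`` — all incremental costs enter, so
      ``c* = wtp x delta_LY - other incremental costs - outpatient nutrition``.
    """
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    if mode not in ("nutrition-only", "full-incremental"):
        raise ValueError(f"unknown threshold mode {mode!r}")

    delta_ly = (intv_tallies.total_life_days - ctrl_tallies.total_life_days) / 365.0
    if delta_ly <= 0:
        return ThresholdResult(
            math.nan, math.nan, wtp, mode, costs.outpatient_fraction, feasible=False
        )

    outpatient = (
        costs.outpatient_fraction
        * intv_tallies.life_days["DISCHARGED"]
        * costs.nutrition_outpatient_per_day
    )
    if mode == "full-incremental":
        no_nutrition = replace(
            costs, nutrition_inpatient_per_day=0.0, nutrition_outpatient_per_day=0.0
        )
        other = _arm_results(intv_tallies, ctrl_tallies, no_nutrition).total_delta_cost
    else:
        other = 0.0

    def ratio(c: float) -> float:
        return (c + outpatient + other) / delta_ly

    # Bracket the root of ratio(c) = wtp, then bisect; ratio is affine in c
    # so the bracket expansion terminates immediately.
    lo, hi = 0.0, max(1.0, wtp * delta_ly)
    while ratio(hi) < wtp:
        hi *= 2.0
    while ratio(lo) > wtp:
        lo = lo * 2.0 - max(1.0, hi)
    while ratio(hi) - ratio(lo) > icer_tol:
        mid = 0.5 * (lo + hi)
        if ratio(mid) < wtp:
            lo = mid
        else:
            hi = mid
    c_star = 0.5 * (lo + hi)
    return ThresholdResult(
        c_star, ratio(c_star), wtp, mode, costs.outpatient_fraction
    )
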