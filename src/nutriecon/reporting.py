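"""Pipeline orchestration and report assembly.

Runs the configured analyses end to end — arm resolution (stored matrix,
calibration, or fixed tallies), cohort propagation, cost/utility accrual,
incremental table, deterministic sensitivity, PSA, extrapolation, and
threshold analysis — and assembles the two headline reports: the per-arm
cost/life-day/utility table and the incremental (ICER) table.

All arithmetic stays unrounded inside the JSON result bundle; rounding
(costs to whole Swiss francs, days and utilities to two decimals) happens
only when a table is rendered, so reports are regenerable byte-identically
from the bundle alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationResult, calibrate_arm
from .cohort import StateTallies, run_cohort, tally_life_days
from .config import ArmConfig, RunConfig
from .economics import (
    COMPONENTS,
    IncrementalResult,
    accrue_costs,
    accrue_utilities,
    deterministic_sa,
    extrapolate,
    incremental_table,
    threshold_nutrition_cost,
)
from .psa import run_psa
from .states import TransitionMatrix, read_matrix, write_matrix

__all__ = [
    "ArmResult",
    "PipelineStageError",
    "resolve_arm",
    "run_base_case",
    "run_full_pipeline",
    "assemble_table2",
    "assemble_table3",
    "render_table2_csv",
    "render_table3_csv",
]

logger = logging.getLogger("nutriecon")

# Report row labels, in publication order.
ROW_LABELS = {
    "nutrition_inpatient": "Nutrition (support)",
    "ward": "Days in normal ward",
    "icu": "Days in ICU",
    "complication": "Complications",
    "post_discharge": "Post-hospital discharge life days",
}

# Which state's life days / utilities feed each report row.
_ROW_STATE = {
    "ward": "WARD",
    "icu": "ICU",
    "complication": "COMPLICATION",
    "post_discharge": "DISCHARGED",
}


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class ArmResult:
    """One arm fully resolved: its tallies, costs, utilities, and provenance."""

    name: str
    tallies: StateTallies
    costs: dict[str, float]          # per report component
    utilities: dict[str, float]      # per alive state + total
    matrix: TransitionMatrix | None
    calibration: CalibrationResult | None


def _arm_seed(master_seed: int, arm: str) -> int:
    """Stable per-arm sub-seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{arm}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def resolve_arm(arm_cfg: ArmConfig, cfg: RunConfig) -> ArmResult:
    """Turn an arm definition into tallies (+ matrix when one exists)."""
    matrix: TransitionMatrix | None = None
    calibration: CalibrationResult | None = None

    if arm_cfg.tallies is not None:
        t = arm_cfg.tallies
        tallies = StateTallies(
            life_days={
                "WARD": t["ward"],
                "COMPLICATION": t["complication"],
                "ICU": t["icu"],
                "DISCHARGED": t["discharged"],
            },
            dead_fraction_at_end=t["dead_fraction"],
            horizon=cfg.horizon,
        )
    elif arm_cfg.matrix_path is not None:
        matrix = read_matrix(arm_cfg.matrix_path)
        tallies = tally_life_days(run_cohort(matrix, cfg.horizon))
    else:
        calibration = calibrate_arm(
            arm_cfg.targets, seed=_arm_seed(cfg.seed, arm_cfg.name)
        )
        matrix = calibration.matrix
        tallies = calibration.achieved

    breakdown = accrue_costs(tallies, cfg.costs, arm_cfg.name)
    costs = {key: breakdown.component(key) for key in COMPONENTS}
    utilities = accrue_utilities(tallies, cfg.utilities)
    return ArmResult(arm_cfg.name, tallies, costs, utilities, matrix, calibration)


# ---------------------------------------------------------------------------
# report assembly (pure functions over plain component mappings)

def assemble_table2(
    intv: dict[str, dict[str, float]], ctrl: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Assemble the per-arm cost/life-day/utility report.

    Each arm is ``{"life_days": {...}, "utilities": {...}, "costs": {...}}``
    keyed by report component.  Appends a Total row (component sums) and a
    Difference row (intervention minus control) — so feeding it any
    per-component values, including already-rounded published ones,
    reproduces their totals by summation.
    """
    rows = []
    for key in COMPONENTS:
        state = _ROW_STATE.get(key)
        rows.append(
            {
                "cost_item": ROW_LABELS[key],
                "life_days_intervention": intv["life_days"].get(state),
                "life_days_control": ctrl["life_days"].get(state),
                "utilities_intervention": intv["utilities"].get(state),
                "utilities_control": ctrl["utilities"].get(state),
                "cost_sf_intervention": intv["costs"][key],
                "cost_sf_control": ctrl["costs"][key],
            }
        )
    frame = pd.DataFrame(rows)
    totals = frame.drop(columns="cost_item").sum(skipna=True)
    totals["cost_item"] = "Total"
    diff = {
        "cost_item": "Difference",
        "life_days_intervention": totals["life_days_intervention"]
        - totals["life_days_control"],
        "utilities_intervention": totals["utilities_intervention"]
        - totals["utilities_control"],
        "cost_sf_intervention": totals["cost_sf_intervention"]
        - totals["cost_sf_control"],
        "life_days_control": np.nan,
        "utilities_control": np.nan,
        "cost_sf_control": np.nan,
    }
    return pd.concat(
        [frame, pd.DataFrame([totals]), pd.DataFrame([diff])], ignore_index=True
    )


def assemble_table3(components: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Assemble the incremental table from ``{component: (d_cost, d_days)}``.

    The Total row sums the components; ICERs divide cost by life days
    (blank where the denominator is zero).
    """
    rows = []
    for key in COMPONENTS:
        d_cost, d_days = components[key]
        ratio = d_cost / d_days if d_days else np.nan
        rows.append(
            {
                "cost_item": ROW_LABELS[key],
                "delta_cost_sf": d_cost,
                "delta_life_days": d_days,
                "icer_sf_per_life_day": ratio,
            }
        )
    total_cost = sum(r["delta_cost_sf"] for r in rows)
    total_days = sum(r["delta_life_days"] for r in rows)
    rows.append(
        {
            "cost_item": "Total",
            "delta_cost_sf": total_cost,
            "delta_life_days": total_days,
            "icer_sf_per_life_day": total_cost / total_days if total_days else np.nan,
        }
    )
    return pd.DataFrame(rows)


def _round_money(frame: pd.DataFrame, money_cols: list[str]) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col == "cost_item":
            continue
        if col in money_cols:
            out[col] = out[col].round(0).astype("Int64")
        else:
            out[col] = out[col].round(2)
    return out


def render_table2_csv(bundle: dict) -> str:
    """Render the per-arm report from a result bundle, rounding at the edge."""
    frame = assemble_table2(bundle["arms"]["intervention"], bundle["arms"]["control"])
    return _round_money(
        frame, ["cost_sf_intervention", "cost_sf_control"]
    ).to_csv(index=False)


def render_table3_csv(bundle: dict) -> str:
    comps = {
        k: (v["delta_cost_sf"], v["delta_life_days"])
        for k, v in bundle["incremental"]["components"].items()
    }
    frame = assemble_table3(comps)
    return _round_money(frame, ["delta_cost_sf"]).to_csv(index=False)


# ---------------------------------------------------------------------------
# pipeline stages

def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {
            "horizon": cfg.horizon,
            "seed": cfg.seed,
            "costs": asdict(cfg.costs),
            "utilities": asdict(cfg.utilities),
            "arms": {
                a: {
                    "n_patients": c.n_patients,
                    "matrix": str(c.matrix_path) if c.matrix_path else None,
                    "targets": asdict(c.targets) if c.targets else None,
                    "tallies": c.tallies,
                }
                for a, c in sorted(cfg.arms.items())
            },
            "grids": [list(cfg.supplement_cost_grid), list(cfg.fraction_grid)],
            "wtp": cfg.wtp_sf_per_life_year,
            "mode": cfg.threshold_mode,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _arm_bundle(arm: ArmResult) -> dict:
    out = {
        "life_days": dict(arm.tallies.life_days),
        "dead_fraction_at_end": arm.tallies.dead_fraction_at_end,
        "utilities": dict(arm.utilities),
        "costs": dict(arm.costs),
        "calibration": None,
    }
    if arm.calibration is not None:
        out["calibration"] = {
            "objective": arm.calibration.objective,
            "relative_errors": dict(arm.calibration.relative_errors),
            "iterations": arm.calibration.iterations,
            "seed": arm.calibration.seed,
            "feasible": arm.calibration.feasible,
        }
    return out


def _incremental_bundle(inc: IncrementalResult) -> dict:
    return {
        "components": {
            k: {
                "delta_cost_sf": dc,
                "delta_life_days": dd,
                "icer": None if not res.defined else res.ratio,
                "quadrant": res.quadrant,
            }
            for k, (dc, dd, res) in inc.components.items()
        },
        "total": {
            "delta_cost_sf": inc.total_delta_cost,
            "delta_life_days": inc.total_delta_life_days,
            "icer": None if not inc.total_icer.defined else inc.total_icer.ratio,
            "quadrant": inc.total_icer.quadrant,
            "effect_unit": inc.effect_unit,
        },
        "horizon": inc.horizon,
    }


@dataclass
class BaseCaseResult:
    arms: dict[str, ArmResult]
    incremental: IncrementalResult
    bundle: dict


def run_base_case(cfg: RunConfig, write: bool = True) -> BaseCaseResult:
    """Resolve both arms, accrue, and build the two headline reports."""
    try:
        arms = {name: resolve_arm(arm_cfg, cfg) for name, arm_cfg in cfg.arms.items()}
    except Exception as exc:  # calibration infeasibility, bad matrix files, ...
        raise PipelineStageError("base-case:arms", exc) from exc

    intv, ctrl = arms["intervention"], arms["control"]
    inc = incremental_table(
        (intv.tallies, accrue_costs(intv.tallies, cfg.costs, "intervention")),
        (ctrl.tallies, accrue_costs(ctrl.tallies, cfg.costs, "control")),
    )
    bundle = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "horizon": cfg.horizon,
        "arms": {name: _arm_bundle(arm) for name, arm in arms.items()},
        "incremental": _incremental_bundle(inc),
    }
    logger.info(
        "base case: config=%s seed=%s version=%s", bundle["config_hash"], cfg.seed, __version__
    )

    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "base_case_table2.csv").write_text(render_table2_csv(bundle))
        (out / "base_case_table3.csv").write_text(render_table3_csv(bundle))
        (out / "bundle.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        for name, arm in arms.items():
            if arm.matrix is not None:
                write_matrix(
                    arm.matrix,
                    out / f"matrix_{name}.csv",
                    metadata={
                        "arm": name,
                        "config_hash": bundle["config_hash"],
                        "seed": cfg.seed,
                        "calibrated": arm.calibration is not None,
                    },
                )
    return BaseCaseResult(arms, inc, bundle)


def run_full_pipeline(cfg: RunConfig, write: bool = True) -> dict:
    """Base case plus every sensitivity analysis; returns the full bundle."""
    base = run_base_case(cfg, write=write)
    intv, ctrl = base.arms["intervention"], base.arms["control"]
    bundle = base.bundle
    out = Path(cfg.out_dir)

    try:
        sa = deterministic_sa(
            intv.tallies, ctrl.tallies, cfg.costs,
            cfg.supplement_cost_grid, cfg.fraction_grid,
        )
        bundle["deterministic_sa"] = sa.to_dict(orient="records")
    except Exception as exc:
        raise PipelineStageError("deterministic-sa", exc) from exc

    try:
        psa = run_psa(
            intv.tallies, ctrl.tallies, cfg.costs, cfg.psa_draws, cfg.seed
        )
        bundle["psa"] = {
            "n_draws": psa.n_draws,
            "seed": psa.seed,
            "mean_delta_cost_sf": psa.mean_delta_cost,
            "mean_icer_sf_per_life_day": psa.mean_icer,
            "delta_cost_interval": list(psa.delta_cost_interval),
            "icer_interval": list(psa.icer_interval),
        }
    except Exception as exc:
        raise PipelineStageError("psa", exc) from exc

    if intv.matrix is not None and ctrl.matrix is not None:
        try:
            extra = extrapolate(
                intv.matrix, ctrl.matrix, cfg.costs, cfg.extrapolation_horizon
            )
            bundle["extrapolation"] = _incremental_bundle(extra)
        except Exception as exc:
            raise PipelineStageError("extrapolation", exc) from exc

        try:
            intv_t = tally_life_days(run_cohort(intv.matrix, cfg.extrapolation_horizon))
            ctrl_t = tally_life_days(run_cohort(ctrl.matrix, cfg.extrapolation_horizon))
            thresholds = []
            for frac in cfg.fraction_grid:
                from dataclasses import replace as _replace

                res = threshold_nutrition_cost(
                    intv_t, ctrl_t, _replace(cfg.costs, outpatient_fraction=frac),
                    wtp=cfg.wtp_sf_per_life_year, mode=cfg.threshold_mode,
                )
                thresholds.append(
                    {
                        "outpatient_fraction": frac,
                        "max_nutrition_cost_sf": res.max_nutrition_cost_sf,
                        "achieved_icer": res.achieved_icer,
                        "mode": res.mode,
                        "feasible": res.feasible,
                    }
                )
            bundle["threshold"] = {
                "wtp_sf_per_life_year": cfg.wtp_sf_per_life_year,
                "horizon": cfg.extrapolation_horizon,
                "results": thresholds,
            }
        except Exception as exc:
            raise PipelineStageError("threshold", exc) from exc
    else:
        logger.warning(
            "arms defined by fixed tallies: extrapolation and threshold skipped"
        )

    if write:
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(bundle["deterministic_sa"]).to_csv(out / "sensitivity.csv", index=False)
        (out / "psa_summary.json").write_text(json.dumps(bundle["psa"], indent=2, sort_keys=True))
        if "extrapolation" in bundle:
            comps = {
                k: (v["delta_cost_sf"], v["delta_life_days"])
                for k, v in bundle["extrapolation"]["components"].items()
            }
            _round_money(assemble_table3(comps), ["delta_cost_sf"]).to_csv(
                out / "extrapolation.csv", index=False
            )
        if "threshold" in bundle:
            pd.DataFrame(bundle["threshold"]["results"]).to_csv(
                out / "threshold.csv", index=False
            )
        (out / "bundle.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
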