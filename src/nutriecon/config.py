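"""Run configuration: the study conditions in one structured object.

A :class:`RunConfig` pins down everything a full analysis needs — horizon,
two arm definitions, unit costs, utility weights, sensitivity grids, the
willingness-to-pay threshold, and seeds.  Configs load from a YAML file
with fail-fast validation (unknown or missing keys are reported with their
full key path), and :func:`default_config` reproduces the base case: a
180-day horizon, the published unit costs, 20% outpatient continuation,
arm sizes 321/324, and per-arm calibration targets taken from the trial's
per-state life days and 180-day mortality (26.5% intervention, 31.5%
control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationTargets
from .economics import CostInputs, UtilityWeights

__all__ = ["ArmConfig", "RunConfig", "default_config", "load_config"]


class ConfigError(ValueError):
    """A configuration problem, reported with its key path."""


#: Base-case calibration targets per arm: expected life days per state over
#: 180 days and 180-day mortality.
BASE_TARGETS = {
    "intervention": {
        "ward": 123.84,
        "complication": 10.09,
        "icu": 1.88,
        "discharged": 18.77,
        "dead_fraction": 0.265,
    },
    "control": {
        "ward": 111.24,
        "complication": 14.20,
        "icu": 1.90,
        "discharged": 21.47,
        "dead_fraction": 0.315,
    },
}

BASE_ARM_SIZES = {"intervention": 321, "control": 324}


@dataclass
class ArmConfig:
    """How one arm's transition structure is specified.

    Exactly one of ``matrix_path`` (a stored matrix), ``targets``
    (calibration targets), or ``tallies`` (fixed per-state life days plus
    mortality, bypassing the Markov model) must be set.
    """

    name: str
    n_patients: int
    matrix_path: Path | None = None
    targets: CalibrationTargets | None = None
    tallies: dict[str, float] | None = None

    def __post_init__(self) -> None:
        provided = [
            x for x in (self.matrix_path, self.targets, self.tallies) if x is not None
        ]
        if len(provided) != 1:
            raise ConfigError(
                f"arms.{self.name}: exactly one of matrix/targets/tallies required"
            )
        if self.n_patients < 1:
            raise ConfigError(f"arms.{self.name}.n_patients must be >= 1")


@dataclass
class RunConfig:
    horizon: int = 180
    seed: int = 2022
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityWeights = field(default_factory=UtilityWeights)
    arms: dict[str, ArmConfig] = field(default_factory=dict)
    supplement_cost_grid: tuple[float, ...] = (5.0, 100.0, 1000.0)
    fraction_grid: tuple[float, ...] = (0.2, 0.5, 1.0)
    wtp_sf_per_life_year: float = 100_000.0
    threshold_mode: str = "nutrition-only"
    psa_draws: int = 10_000
    extrapolation_horizon: int = 365
    out_dir: Path = Path("results")

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        if set(self.arms) and set(self.arms) != {"intervention", "control"}:
            raise ConfigError(
                "arms: exactly the two arms 'intervention' and 'control' are required"
            )


def _targets_from_dict(arm: str, raw: dict, horizon: int) -> CalibrationTargets:
    expected = {"ward", "complication", "icu", "discharged", "dead_fraction"}
    _check_keys(raw, expected, f"arms.{arm}.targets", required=expected)
    return CalibrationTargets(
        life_days={
            "WARD": float(raw["ward"]),
            "COMPLICATION": float(raw["complication"]),
            "ICU": float(raw["icu"]),
            "DISCHARGED": float(raw["discharged"]),
        },
        dead_fraction=float(raw["dead_fraction"]),
        horizon=horizon,
    )


def default_config(seed: int = 2022, out_dir: str | Path = "results") -> RunConfig:
    """The base-case study conditions, with calibration-target arms."""
    cfg = RunConfig(seed=seed, out_dir=Path(out_dir))
    cfg.arms = {
        arm: ArmConfig(
            name=arm,
            n_patients=BASE_ARM_SIZES[arm],
            targets=_targets_from_dict(arm, BASE_TARGETS[arm], cfg.horizon),
        )
        for arm in ("intervention", "control")
    }
    return cfg


def _check_keys(raw: dict, allowed: set[str], path: str, required: set[str] = frozenset()):
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing key(s) {sorted(missing)}")


_COST_KEYS = {
    "nutrition_inpatient_per_day",
    "nutrition_outpatient_per_day",
    "ward_per_day",
    "icu_per_day",
    "complication_per_day",
    "outpatient_fraction",
}

_UTILITY_KEYS = {"ward", "complication", "icu", "discharged"}

_TOP_KEYS = {
    "horizon",
    "seed",
    "costs",
    "utilities",
    "arms",
    "sensitivity",
    "wtp_sf_per_life_year",
    "threshold_mode",
    "psa",
    "extrapolation",
    "out_dir",
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Sections absent from the file fall back to the base-case defaults.
    Every referenced file path must exist at load time.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    horizon = int(raw.get("horizon", 180))
    cfg = RunConfig(horizon=horizon, seed=int(raw.get("seed", 2022)))

    if "costs" in raw:
        _check_keys(raw["costs"], _COST_KEYS, "costs", required=_COST_KEYS)
        cfg.costs = CostInputs(**{k: float(v) for k, v in raw["costs"].items()})
    if "utilities" in raw:
        _check_keys(raw["utilities"], _UTILITY_KEYS, "utilities", required=_UTILITY_KEYS)
        cfg.utilities = UtilityWeights(**{k: float(v) for k, v in raw["utilities"].items()})

    arms_raw = raw.get("arms")
    if arms_raw is None:
        cfg.arms = default_config(cfg.seed).arms
    else:
        _check_keys(
            arms_raw, {"intervention", "control"}, "arms",
            required={"intervention", "control"},
        )
        arms: dict[str, ArmConfig] = {}
        for arm, spec in arms_raw.items():
            _check_keys(
                spec, {"n_patients", "matrix", "targets", "tallies"}, f"arms.{arm}"
            )
            matrix_path = None
            if "matrix" in spec:
                matrix_path = (path.parent / spec["matrix"]).resolve()
                if not matrix_path.exists():
                    raise ConfigError(f"arms.{arm}.matrix: file not found: {matrix_path}")
            targets = (
                _targets_from_dict(arm, spec["targets"], horizon)
                if "targets" in spec
                else None
            )
            tallies = None
            if "tallies" in spec:
                t_keys = {"ward", "complication", "icu", "discharged", "dead_fraction"}
                _check_keys(spec["tallies"], t_keys, f"arms.{arm}.tallies", required=t_keys)
                tallies = {k: float(v) for k, v in spec["tallies"].items()}
            arms[arm] = ArmConfig(
                name=arm,
                n_patients=int(spec.get("n_patients", BASE_ARM_SIZES[arm])),
                matrix_path=matrix_path,
                targets=targets,
                tallies=tallies,
            )
        cfg.arms = arms

    if "sensitivity" in raw:
        _check_keys(
            raw["sensitivity"], {"supplement_cost_grid", "fraction_grid"}, "sensitivity"
        )
        if "supplement_cost_grid" in raw["sensitivity"]:
            cfg.supplement_cost_grid = tuple(
                float(v) for v in raw["sensitivity"]["supplement_cost_grid"]
            )
        if "fraction_grid" in raw["sensitivity"]:
            cfg.fraction_grid = tuple(float(v) for v in raw["sensitivity"]["fraction_grid"])
    if "wtp_sf_per_life_year" in raw:
        cfg.wtp_sf_per_life_year = float(raw["wtp_sf_per_life_year"])
    if "threshold_mode" in raw:
        if raw["threshold_mode"] not in ("nutrition-only", "full-incremental"):
            raise ConfigError("threshold_mode: must be nutrition-only or full-incremental")
        cfg.threshold_mode = raw["threshold_mode"]
    if "psa" in raw:
        _check_keys(raw["psa"], {"n_draws"}, "psa")
        cfg.psa_draws = int(raw["psa"].get("n_draws", cfg.psa_draws))
    if "extrapolation" in raw:
        _check_keys(raw["extrapolation"], {"horizon"}, "extrapolation")
        cfg.extrapolation_horizon = int(raw["extrapolation"].get("horizon", 365))
    if "out_dir" in raw:
        cfg.out_dir = Path(raw["out_dir"])
    return cfg
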