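"""Incremental cost-effectiveness synthesis.

Combines the service-cost summaries with per-consultation travel and
production-loss unit costs, classifies dominance, solves break-even annual
consultation volumes exactly by integer search, and runs the one-way
sensitivity scenarios (equipment alternative, hospital distance, costing
perspective).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .costing import (
    PAYERS,
    AnnuityParams,
    ArmCostSummary,
    CostComponent,
    aggregate_annual_cost,
    round_half_up,
)
from .errors import ConfigError, ParameterError

__all__ = [
    "HEALTH_SECTOR",
    "SOCIETAL",
    "ArmUnitCosts",
    "CEAResult",
    "Perspective",
    "ScenarioSpec",
    "TrialUnitCosts",
    "break_even_volume",
    "breakeven_curves",
    "build_arm_summary",
    "dominance",
    "incremental_cost",
    "per_consultation_cost",
    "relocation_distance_scale",
    "run_scenario",
    "standard_scenarios",
]


@dataclass(frozen=True)
class Perspective:
    """A costing viewpoint: which payers' costs count."""

    name: str
    payers: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.payers - set(PAYERS)
        if unknown:
            raise ConfigError(f"perspective {self.name!r}: unknown payers {sorted(unknown)}")


#: Societal = health sector + patient out-of-pocket + production losses.
SOCIETAL = Perspective("societal", frozenset(PAYERS))
#: Health sector only: excludes patient-paid user fees and production losses.
HEALTH_SECTOR = Perspective("health_sector", frozenset({"health_sector"}))


@dataclass(frozen=True)
class ArmUnitCosts:
    """Per-consultation travel and production-loss cost for one arm.

    ``travel_per_consultation`` includes the patient-paid user fee.
    """

    travel_per_consultation: float
    production_loss_per_consultation: float


@dataclass(frozen=True)
class TrialUnitCosts:
    """Trial-derived per-consultation unit costs for both arms."""

    user_fee: float
    standard: ArmUnitCosts
    telemedicine: ArmUnitCosts
    qaly_gain_standard: float = 0.0
    qaly_gain_telemedicine: float = 0.0
    qaly_p_value: float | None = None

    def for_arm(self, arm: str) -> ArmUnitCosts:
        if arm == "standard":
            return self.standard
        if arm == "telemedicine":
            return self.telemedicine
        raise ConfigError(f"unknown arm {arm!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One-way sensitivity scenario: vary a single assumption at a time."""

    name: str
    equipment_alternative: str = "A"  # 'A' or 'B'
    distance_scale: float = 1.0  # applied to standard-arm distances before pricing
    perspective: Perspective = SOCIETAL
    volume_range: tuple[int, int] = (1, 600)

    def __post_init__(self) -> None:
        if self.equipment_alternative not in {"A", "B"}:
            raise ConfigError(
                f"scenario {self.name!r}: equipment_alternative must be 'A' or 'B'"
            )
        if self.distance_scale <= 0:
            raise ParameterError(f"scenario {self.name!r}: distance_scale must be > 0")
        lo, hi = self.volume_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"scenario {self.name!r}: invalid volume_range")


@dataclass(frozen=True)
class CEAResult:
    """Outcome of a cost-effectiveness comparison under one scenario."""

    scenario: str
    perspective: str
    volume: int
    cost_per_consultation_standard: float
    cost_per_consultation_telemedicine: float
    incremental_cost_per_consultation: float
    incremental_qaly: float
    classification: str
    icer: float | None
    break_even_volume: float  # integer count, or math.inf sentinel
    annual_saving_at_volume: float
    annual_saving_unrounded: float
    summaries: Mapping[str, ArmCostSummary] = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def per_consultation_cost(
    summary: ArmCostSummary, volume: int, perspective: Perspective = SOCIETAL
) -> float:
    """Fixed annual cost spread over ``volume`` plus variable cost, for the
    payers included in the perspective. Unrounded; round for table display."""
    if volume < 1:
        raise ParameterError("volume must be >= 1")
    payers = perspective.payers
    return summary.fixed(payers) / volume + summary.variable(payers)


def incremental_cost(
    std: ArmCostSummary,
    tm: ArmCostSummary,
    volume: int,
    perspective: Perspective = SOCIETAL,
) -> float:
    """Standard minus telemedicine cost per consultation (positive = saving)."""
    return per_consultation_cost(std, volume, perspective) - per_consultation_cost(
        tm, volume, perspective
    )


def break_even_volume(
    std: ArmCostSummary,
    tm: ArmCostSummary,
    perspective: Perspective = SOCIETAL,
    max_volume: int = 10_000,
) -> float:
    """Smallest integer N with total_annual(tm, N) <= total_annual(std, N).

    Ties go to telemedicine. Returns ``math.inf`` when telemedicine never
    catches up within ``max_volume`` (non-positive variable saving with a
    fixed-cost handicap). Closed form, verified against the defining
    inequality at the returned N.
    """
    payers = perspective.payers
    delta_fixed = tm.fixed(payers) - std.fixed(payers)
    delta_variable = std.variable(payers) - tm.variable(payers)  # per-consultation saving
    if delta_fixed <= 0 and delta_variable >= 0:
        return 1
    if delta_variable <= 0:
        # Need delta_fixed <= delta_variable * N; only N = 1 could work and
        # the delta_fixed <= 0 case is handled above.
        return 1 if delta_fixed <= delta_variable else math.inf
    ratio = delta_fixed / delta_variable
    if not math.isfinite(ratio) or ratio > max_volume:
        return math.inf
    n = max(1, math.ceil(ratio - 1e-9))
    assert tm.total_annual(n, payers) <= std.total_annual(n, payers) + 1e-6
    return n


def dominance(
    delta_cost: float, delta_qaly: float, qaly_significant: bool = False
) -> tuple[str, float | None]:
    """Classify an incremental result.

    ``delta_cost`` is telemedicine minus standard (negative = cheaper);
    ``delta_qaly`` is telemedicine minus standard QALYs gained. Returns
    ``(classification, icer)``; the ICER is defined only for trade-offs with
    a nonzero QALY difference.
    """
    if delta_cost < 0 and delta_qaly >= 0:
        return "dominant", None
    if delta_cost > 0 and delta_qaly <= 0:
        return "dominated", None
    icer = delta_cost / delta_qaly if delta_qaly != 0 else None
    return "tradeoff", icer


# ---------------------------------------------------------------------------
# Arm summary construction
# ---------------------------------------------------------------------------


def build_arm_summary(
    components: Sequence[CostComponent],
    arm: str,
    unit_costs: TrialUnitCosts,
    annuity: AnnuityParams,
    volume: int = 300,
    equipment_alternative: str = "A",
    distance_scale: float = 1.0,
) -> ArmCostSummary:
    """Service costs from the component config plus trial-derived travel and
    production-loss variable costs, split by payer.

    ``distance_scale`` rescales the distance-driven part of the arm's travel
    cost (the reimbursed fare) and the production loss; the flat user fee is
    unaffected, matching per-km fare pricing of rescaled distances.
    """
    alternative = arm if arm == "standard" else f"telemedicine_{equipment_alternative}"
    summary = aggregate_annual_cost(components, alternative, volume, annuity)
    arm_costs = unit_costs.for_arm(arm)
    fare_part = arm_costs.travel_per_consultation - unit_costs.user_fee
    if fare_part < -1e-9:
        raise ConfigError("travel cost per consultation below the user fee")
    extra = {
        "health_sector": max(fare_part, 0.0) * distance_scale,
        "patient": unit_costs.user_fee,
        "production": arm_costs.production_loss_per_consultation * distance_scale,
    }
    return ArmCostSummary(
        alternative=summary.alternative,
        fixed_by_payer=summary.fixed_by_payer,
        variable_by_payer={
            p: summary.variable_by_payer.get(p, 0.0) + extra.get(p, 0.0) for p in PAYERS
        },
        volume_assumed=volume,
    )


def relocation_distance_scale(
    new_leg_km: float, clinic_mean_km: float, standard_mean_km: float
) -> float:
    """Distance scale for moving the hospital closer.

    Standard-arm journeys are modelled as the patient's distance to the local
    clinic plus the clinic-to-hospital leg, so a new leg of ``new_leg_km``
    rescales the mean one-way distance to ``(clinic_mean + new_leg) /
    standard_mean``.
    """
    if new_leg_km < 0 or clinic_mean_km < 0 or standard_mean_km <= 0:
        raise ParameterError("distances must be positive")
    return (clinic_mean_km + new_leg_km) / standard_mean_km


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def run_scenario(
    spec: ScenarioSpec,
    components: Sequence[CostComponent],
    unit_costs: TrialUnitCosts,
    annuity: AnnuityParams,
    volume: int = 300,
) -> CEAResult:
    """Re-run costing and the CEA with the scenario's single stated change.

    Only the standard arm's travel is distance-scaled (telemedicine journeys
    go to the local clinic regardless of where the hospital is).
    """
    std = build_arm_summary(
        components, "standard", unit_costs, annuity, volume,
        equipment_alternative=spec.equipment_alternative,
        distance_scale=spec.distance_scale,
    )
    tm = build_arm_summary(
        components, "telemedicine", unit_costs, annuity, volume,
        equipment_alternative=spec.equipment_alternative,
    )
    persp = spec.perspective
    cost_std = per_consultation_cost(std, volume, persp)
    cost_tm = per_consultation_cost(tm, volume, persp)
    saving = cost_std - cost_tm
    delta_qaly = unit_costs.qaly_gain_telemedicine - unit_costs.qaly_gain_standard
    significant = (
        unit_costs.qaly_p_value is not None and unit_costs.qaly_p_value < 0.05
    )
    classification, icer = dominance(-saving, delta_qaly, significant)
    return CEAResult(
        scenario=spec.name,
        perspective=persp.name,
        volume=volume,
        cost_per_consultation_standard=cost_std,
        cost_per_consultation_telemedicine=cost_tm,
        incremental_cost_per_consultation=saving,
        incremental_qaly=delta_qaly,
        classification=classification,
        icer=icer,
        break_even_volume=break_even_volume(std, tm, persp),
        annual_saving_at_volume=float(round_half_up(saving) * volume),
        annual_saving_unrounded=saving * volume,
        summaries={"standard": std, "telemedicine": tm},
    )


def standard_scenarios(
    clinic_mean_km: float = 47.0,
    standard_mean_km: float = 248.0,
    relocated_leg_km: float = 90.0,
) -> list[ScenarioSpec]:
    """The base case plus the three one-way sensitivity scenarios."""
    return [
        ScenarioSpec("base_case"),
        ScenarioSpec("skype_for_business", equipment_alternative="B"),
        ScenarioSpec(
            "shorter_distance_90km",
            distance_scale=relocation_distance_scale(
                relocated_leg_km, clinic_mean_km, standard_mean_km
            ),
        ),
        ScenarioSpec("health_sector_perspective", perspective=HEALTH_SECTOR),
    ]


def breakeven_curves(
    std: ArmCostSummary,
    tm_variants: Mapping[str, ArmCostSummary],
    volume_range: Sequence[int],
    perspective: Perspective = SOCIETAL,
) -> pd.DataFrame:
    """Annual-cost and per-consultation-cost curves over a volume grid.

    One row per (alternative, N); the annual-cost curves of the standard arm
    and a variant cross exactly at their break-even volume.
    """
    volumes = [int(n) for n in volume_range]
    if not volumes:
        raise ConfigError("volume_range must be nonempty")
    if min(volumes) < 1:
        raise ParameterError("volumes must be >= 1")
    rows = []
    arms = {"standard": std, **tm_variants}
    for label, summary in arms.items():
        for n in volumes:
            rows.append(
                {
                    "alternative": label,
                    "volume": n,
                    "annual_cost": summary.total_annual(n, perspective.payers),
                    "cost_per_consultation": per_consultation_cost(
                        summary, n, perspective
                    ),
                }
            )
    return pd.DataFrame(rows)
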