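"""Resource valuation: annuitized investments, annual service costs, travel
fares and production losses.

All amounts are euros. Internal arithmetic is unrounded; published-table
comparisons round half-up to whole euros at the final aggregation step only
(see :func:`round_half_up`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, MissingMainModeError, ParameterError

__all__ = [
    "ALTERNATIVES",
    "CATEGORIES",
    "EMPLOYMENT_STATUSES",
    "MODES",
    "PAYERS",
    "SITES",
    "AnnuityParams",
    "ArmCostSummary",
    "ConsultationRecord",
    "CostComponent",
    "FareSchedule",
    "TravelCost",
    "aggregate_annual_cost",
    "annualize",
    "annuity_factor",
    "arm_unit_costs",
    "price_consultations",
    "production_loss",
    "round_half_up",
    "travel_cost",
]

#: Tagged vocabularies shared by configuration files and trial tables.
CATEGORIES = frozenset({"investment", "recurring_annual", "per_consultation"})
SITES = frozenset({"hospital", "remote_center", "shared"})
ALTERNATIVES = frozenset({"standard", "telemedicine_A", "telemedicine_B", "shared"})
PAYERS = ("health_sector", "patient", "production")
MODES = frozenset(
    {"taxi", "bus", "private_car", "express_boat", "ferry", "airplane", "other"}
)
EMPLOYMENT_STATUSES = frozenset(
    {"full_time", "part_time", "homemaker", "unemployed", "retired_disability", "student"}
)

#: Employment statuses eligible for production-loss valuation.
WORKING_STATUSES = frozenset({"full_time", "part_time"})

#: Fixed currency conversion applied at config load, never downstream.
NOK_PER_EUR = 9.60

_ROUND_EPS = 1e-7


def round_half_up(value: float) -> int:
    """Round to the nearest whole euro, halves away from zero-ward (up).

    A small epsilon absorbs float representation error so that sums whose
    exact value is *.5 (e.g. 148.65 + 33.85) round up as intended.
    """
    return int(math.floor(value + 0.5 + _ROUND_EPS))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnuityParams:
    """Discounting assumptions for spreading an investment over its lifetime."""

    discount_rate: float
    lifetime: int

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.lifetime < 1:
            raise ParameterError(f"lifetime must be >= 1 year, got {self.lifetime}")


@dataclass(frozen=True)
class CostComponent:
    """One priced item from the service cost configuration.

    ``amount`` is euros; its meaning depends on ``category``: a present value
    for investments, euros per year for recurring items, euros per single
    consultation for volume-driven items.
    """

    name: str
    amount: float
    category: str
    site: str
    alternative: str
    payer: str

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ParameterError(f"component {self.name!r}: amount must be >= 0")
        for value, allowed, label in (
            (self.category, CATEGORIES, "category"),
            (self.site, SITES, "site"),
            (self.alternative, ALTERNATIVES, "alternative"),
            (self.payer, frozenset(PAYERS), "payer"),
        ):
            if value not in allowed:
                raise ConfigError(
                    f"component {self.name!r}: unknown {label} {value!r} "
                    f"(allowed: {sorted(allowed)})"
                )


@dataclass(frozen=True)
class FareSchedule:
    """Unit fares for pricing patient journeys.

    ``per_km`` / ``per_trip`` are euros per kilometre / per round trip for each
    transport mode. The patient-paid user fee is a flat per-consultation
    charge; everything else is reimbursed by the health sector.
    """

    per_km: Mapping[str, float]
    per_trip: Mapping[str, float]
    companion_multiplier: float
    extra_transport_surcharge: float
    user_fee: float
    average_hourly_wage: float

    def __post_init__(self) -> None:
        for mapping, label in ((self.per_km, "per_km"), (self.per_trip, "per_trip")):
            for mode, fare in mapping.items():
                if mode not in MODES:
                    raise ConfigError(f"fare schedule: unknown mode {mode!r} in {label}")
                if fare < 0:
                    raise ParameterError(f"fare schedule: {label}[{mode}] must be >= 0")
        for attr in ("companion_multiplier", "extra_transport_surcharge",
                     "user_fee", "average_hourly_wage"):
            if getattr(self, attr) < 0:
                raise ParameterError(f"fare schedule: {attr} must be >= 0")

    def km_rate(self, mode: str) -> float:
        return float(self.per_km.get(mode, 0.0))

    def trip_rate(self, mode: str) -> float:
        return float(self.per_trip.get(mode, 0.0))


@dataclass(frozen=True)
class ConsultationRecord:
    """One attended consultation with its travel and work-absence details."""

    patient_id: str
    arm: str
    main_mode: str | None
    distance_km: float
    travel_time_min: float
    companion: bool
    extra_transport: bool
    employment: str | None
    on_sick_leave: bool
    took_time_off_work: bool
    time_off_hours: float
    modes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.arm not in {"standard", "telemedicine"}:
            raise ParameterError(f"unknown arm {self.arm!r}")
        if self.main_mode is not None and self.main_mode not in MODES:
            raise ParameterError(f"unknown transport mode {self.main_mode!r}")
        if self.employment is not None and self.employment not in EMPLOYMENT_STATUSES:
            raise ParameterError(f"unknown employment status {self.employment!r}")
        if self.distance_km < 0 or self.travel_time_min < 0 or self.time_off_hours < 0:
            raise ParameterError("distance, travel time and time off must be >= 0")
        if self.took_time_off_work and self.employment not in WORKING_STATUSES:
            raise ParameterError(
                "took_time_off_work requires full- or part-time employment"
            )


@dataclass(frozen=True)
class TravelCost:
    """Priced journey, split by payer. ``total = health_sector + patient``."""

    total: float
    health_sector: float
    patient: float
    imputed: bool = False


@dataclass(frozen=True)
class ArmCostSummary:
    """An alternative's fixed annual cost plus variable per-consultation costs,
    both split by payer."""

    alternative: str
    fixed_by_payer: Mapping[str, float]
    variable_by_payer: Mapping[str, float]
    volume_assumed: int | None = None

    def __post_init__(self) -> None:
        for mapping in (self.fixed_by_payer, self.variable_by_payer):
            for payer, amount in mapping.items():
                if payer not in PAYERS:
                    raise ConfigError(f"unknown payer {payer!r}")
                if amount < -1e-9:
                    raise ParameterError(f"negative cost for payer {payer!r}")

    @property
    def fixed_annual(self) -> float:
        return float(sum(self.fixed_by_payer.values()))

    @property
    def variable_per_consultation(self) -> float:
        return float(sum(self.variable_by_payer.values()))

    def fixed(self, payers: Iterable[str] | None = None) -> float:
        payers = PAYERS if payers is None else tuple(payers)
        return float(sum(self.fixed_by_payer.get(p, 0.0) for p in payers))

    def variable(self, payers: Iterable[str] | None = None) -> float:
        payers = PAYERS if payers is None else tuple(payers)
        return float(sum(self.variable_by_payer.get(p, 0.0) for p in payers))

    def total_annual(self, volume: int, payers: Iterable[str] | None = None) -> float:
        if volume < 0:
            raise ParameterError("volume must be >= 0")
        payers = PAYERS if payers is None else tuple(payers)
        return self.fixed(payers) + self.variable(payers) * volume

    def with_variable(self, extra: Mapping[str, float]) -> "ArmCostSummary":
        merged = {p: self.variable_by_payer.get(p, 0.0) + extra.get(p, 0.0)
                  for p in PAYERS}
        return replace(self, variable_by_payer=merged)

    def __add__(self, other: "ArmCostSummary") -> "ArmCostSummary":
        return ArmCostSummary(
            alternative=self.alternative,
            fixed_by_payer={p: self.fixed_by_payer.get(p, 0.0)
                            + other.fixed_by_payer.get(p, 0.0) for p in PAYERS},
            variable_by_payer={p: self.variable_by_payer.get(p, 0.0)
                               + other.variable_by_payer.get(p, 0.0) for p in PAYERS},
            volume_assumed=self.volume_assumed,
        )


# ---------------------------------------------------------------------------
# Annuitization
# ---------------------------------------------------------------------------


def annuity_factor(params: AnnuityParams) -> float:
    """Present value of a 1-euro-per-year annuity: ``(1 - (1+r)^-n) / r``.

    Equals ``n`` in the zero-rate limit.
    """
    r, n = params.discount_rate, params.lifetime
    if r == 0 or 1.0 + r == 1.0:  # exact zero or below float resolution
        return float(n)
    # -expm1(-n*log1p(r)) = 1 - (1+r)^-n without catastrophic cancellation
    return -math.expm1(-n * math.log1p(r)) / r


def annualize(present_value: float, params: AnnuityParams) -> float:
    """Equivalent annual cost of a one-time investment (unrounded)."""
    if present_value < 0:
        raise ParameterError("present_value must be >= 0")
    return present_value / annuity_factor(params)


# ---------------------------------------------------------------------------
# Annual service cost aggregation
# ---------------------------------------------------------------------------


def _selected(components: Sequence[CostComponent], alternative: str):
    if alternative not in ALTERNATIVES - {"shared"}:
        raise ConfigError(f"unknown alternative {alternative!r}")
    if alternative == "standard":
        wanted = {"standard"}
    else:
        # 'shared' components are shared between the two telemedicine
        # equipment alternatives, never with the standard arm.
        wanted = {alternative, "shared"}
    return [c for c in components if c.alternative in wanted]


def aggregate_annual_cost(
    components: Sequence[CostComponent],
    alternative: str,
    volume: int,
    params: AnnuityParams,
) -> ArmCostSummary:
    """Aggregate a component list into an :class:`ArmCostSummary`.

    Investments are annuitized, recurring components pass through, and
    per-consultation components contribute to the variable part (their annual
    total therefore scales with ``volume``).
    """
    if volume < 1:
        raise ParameterError("volume must be >= 1")
    fixed = {p: 0.0 for p in PAYERS}
    variable = {p: 0.0 for p in PAYERS}
    for comp in _selected(components, alternative):
        if comp.category == "investment":
            fixed[comp.payer] += annualize(comp.amount, params)
        elif comp.category == "recurring_annual":
            fixed[comp.payer] += comp.amount
        else:  # per_consultation
            variable[comp.payer] += comp.amount
    return ArmCostSummary(
        alternative=alternative,
        fixed_by_payer=fixed,
        variable_by_payer=variable,
        volume_assumed=volume,
    )


# ---------------------------------------------------------------------------
# Travel pricing
# ---------------------------------------------------------------------------


def travel_cost(rec: ConsultationRecord, fares: FareSchedule) -> TravelCost:
    """Price one consultation's round-trip journey.

    The patient pays the flat user fee; the health sector reimburses the fare
    (per-trip + per-km x round-trip distance, with companion uplift and an
    extra-transport surcharge). Deterministic for fixed inputs.
    """
    if rec.main_mode is None:
        raise MissingMainModeError(
            f"patient {rec.patient_id}: no main transport mode reported"
        )
    fare = fares.trip_rate(rec.main_mode) + fares.km_rate(rec.main_mode) * 2.0 * rec.distance_km
    if rec.companion:
        fare *= 1.0 + fares.companion_multiplier
    if rec.extra_transport:
        fare += fares.extra_transport_surcharge
    return TravelCost(
        total=fare + fares.user_fee,
        health_sector=fare,
        patient=fares.user_fee,
    )


def production_loss(rec: ConsultationRecord, fares: FareSchedule) -> float:
    """Value of work time lost attending the consultation.

    Zero unless the patient is in full- or part-time employment, is not on
    sick leave, and reported taking time off work; part-time counts at 50%.
    """
    if not rec.took_time_off_work or rec.on_sick_leave:
        return 0.0
    if rec.employment not in WORKING_STATUSES:
        return 0.0
    fraction = 0.5 if rec.employment == "part_time" else 1.0
    return rec.time_off_hours * fares.average_hourly_wage * fraction


def price_consultations(consultations: pd.DataFrame, fares: FareSchedule) -> pd.DataFrame:
    """Price every consultation row; impute missing-mode fares from arm means.

    Returns a copy with columns ``travel_total``, ``travel_health_sector``,
    ``travel_patient``, ``production_loss`` and ``travel_imputed``.
    """
    out = consultations.copy()
    totals, hs, patient, prod, imputed = [], [], [], [], []
    for rec in iter_records(out):
        try:
            tc = travel_cost(rec, fares)
            imputed.append(False)
        except MissingMainModeError:
            tc = None
            imputed.append(True)
        if tc is None:
            totals.append(math.nan)
            hs.append(math.nan)
        else:
            totals.append(tc.total)
            hs.append(tc.health_sector)
        patient.append(fares.user_fee)
        prod.append(production_loss(rec, fares))
    out["travel_total"] = totals
    out["travel_health_sector"] = hs
    out["travel_patient"] = patient
    out["production_loss"] = prod
    out["travel_imputed"] = imputed
    # Flagged records take the arm mean of the reimbursed fare.
    for arm, group in out.groupby("arm"):
        mask = group["travel_imputed"]
        if mask.any():
            mean_hs = group.loc[~mask, "travel_health_sector"].mean()
            if math.isnan(mean_hs):
                mean_hs = 0.0
            idx = group.index[mask]
            out.loc[idx, "travel_health_sector"] = mean_hs
            out.loc[idx, "travel_total"] = mean_hs + fares.user_fee
    return out


def arm_unit_costs(consultations: pd.DataFrame, fares: FareSchedule) -> dict[str, dict[str, float]]:
    """Per-arm mean travel and production-loss cost per consultation."""
    priced = price_consultations(consultations, fares)
    result: dict[str, dict[str, float]] = {}
    for arm, group in priced.groupby("arm"):
        result[str(arm)] = {
            "travel_per_consultation": float(group["travel_total"].mean()),
            "production_loss_per_consultation": float(group["production_loss"].mean()),
            "n_consultations": int(len(group)),
        }
    return result


def iter_records(consultations: pd.DataFrame):
    """Yield :class:`ConsultationRecord` objects from a consultations table."""
    for row in consultations.itertuples(index=False):
        mode = getattr(row, "main_mode", None)
        if mode is None or (isinstance(mode, float) and math.isnan(mode)) or mode == "":
            mode = None
        employment = getattr(row, "employment", None)
        if employment is None or (isinstance(employment, float) and math.isnan(employment)) or employment == "":
            employment = None
        yield ConsultationRecord(
            patient_id=str(row.patient_id),
            arm=str(row.arm),
            main_mode=mode,
            distance_km=float(row.distance_km),
            travel_time_min=float(row.travel_time_min),
            companion=bool(row.companion),
            extra_transport=bool(row.extra_transport),
            employment=employment,
            on_sick_leave=bool(row.on_sick_leave),
            took_time_off_work=bool(row.took_time_off_work),
            time_off_hours=float(row.time_off_hours),
            modes=frozenset() if mode is None else frozenset({mode}),
        )
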