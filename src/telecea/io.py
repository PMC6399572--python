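"""Configuration and file I/O.

Formats: YAML for the cost configuration, fare schedule, tariff and run
config; CSV for the patient and consultation tables. Monetary amounts may be
declared in NOK and are converted to EUR once, at load (fixed 9.60 NOK/EUR);
nothing downstream converts currency.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cea import ArmUnitCosts, TrialUnitCosts
from .costing import (
    EMPLOYMENT_STATUSES,
    MODES,
    NOK_PER_EUR,
    AnnuityParams,
    CostComponent,
    FareSchedule,
)
from .errors import ConfigError, SchemaError
from .outcomes import TariffCoefficients

__all__ = [
    "CostConfig",
    "RunConfig",
    "fixture_path",
    "load_cost_config",
    "load_fares",
    "load_run_config",
    "load_tariff",
    "load_trial_unit_costs",
    "read_consultations",
    "read_patients",
    "sha256_of",
    "write_consultations",
    "write_patients",
]

_FIXTURES = {
    "table2_components": "table2_components.yaml",
    "table5_inputs": "table5_inputs.yaml",
    "fares": "fares.yaml",
    "uk_tto_tariff": "uk_tto_tariff.yaml",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture (see ``telecea/data``)."""
    if name not in _FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return Path(str(resources.files("telecea").joinpath("data", _FIXTURES[name])))


def _load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return data


def _currency_factor(data: Mapping, path: Path) -> float:
    currency = str(data.get("currency", "EUR")).upper()
    if currency == "EUR":
        return 1.0
    if currency == "NOK":
        return 1.0 / NOK_PER_EUR
    raise ConfigError(f"{path}: unsupported currency {currency!r}")


def sha256_of(path: str | Path) -> str:
    """Checksum of a configuration file, recorded in run logs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Typed config loaders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostConfig:
    components: tuple[CostComponent, ...]
    annuity: AnnuityParams
    reference_volume: int


def load_cost_config(path: str | Path) -> CostConfig:
    path = Path(path)
    data = _load_yaml(path)
    factor = _currency_factor(data, path)
    try:
        annuity = AnnuityParams(
            discount_rate=float(data["annuity"]["discount_rate"]),
            lifetime=int(data["annuity"]["lifetime_years"]),
        )
        raw = data["components"]
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc
    components = []
    for i, item in enumerate(raw):
        try:
            components.append(
                CostComponent(
                    name=str(item["name"]),
                    amount=float(item["amount"]) * factor,
                    category=str(item["category"]),
                    site=str(item["site"]),
                    alternative=str(item["alternative"]),
                    payer=str(item["payer"]),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: component #{i + 1} missing key {exc}") from exc
    return CostConfig(
        components=tuple(components),
        annuity=annuity,
        reference_volume=int(data.get("reference_volume", 300)),
    )


def load_fares(path: str | Path) -> FareSchedule:
    path = Path(path)
    data = _load_yaml(path)
    factor = _currency_factor(data, path)
    try:
        return FareSchedule(
            per_km={m: float(v) * factor for m, v in data["per_km"].items()},
            per_trip={m: float(v) * factor for m, v in data["per_trip"].items()},
            companion_multiplier=float(data["companion_multiplier"]),
            extra_transport_surcharge=float(data["extra_transport_surcharge"]) * factor,
            user_fee=float(data["user_fee"]) * factor,
            average_hourly_wage=float(data["average_hourly_wage"]) * factor,
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc


def load_tariff(path: str | Path) -> TariffCoefficients:
    return TariffCoefficients.from_dict(_load_yaml(path))


def load_trial_unit_costs(path: str | Path) -> TrialUnitCosts:
    path = Path(path)
    data = _load_yaml(path)
    factor = _currency_factor(data, path)
    try:
        arms = data["arms"]
        return TrialUnitCosts(
            user_fee=float(data["user_fee"]) * factor,
            standard=ArmUnitCosts(
                travel_per_consultation=float(arms["standard"]["travel_per_consultation"]) * factor,
                production_loss_per_consultation=float(
                    arms["standard"]["production_loss_per_consultation"]) * factor,
            ),
            telemedicine=ArmUnitCosts(
                travel_per_consultation=float(
                    arms["telemedicine"]["travel_per_consultation"]) * factor,
                production_loss_per_consultation=float(
                    arms["telemedicine"]["production_loss_per_consultation"]) * factor,
            ),
            qaly_gain_standard=float(arms["standard"].get("qaly_gain", 0.0)),
            qaly_gain_telemedicine=float(arms["telemedicine"].get("qaly_gain", 0.0)),
            qaly_p_value=(None if data.get("qaly_p_value") is None
                          else float(data["qaly_p_value"])),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc


def load_distances(path: str | Path) -> dict[str, float]:
    data = _load_yaml(path)
    distances = data.get("distances", {})
    return {k: float(v) for k, v in distances.items()}


# ---------------------------------------------------------------------------
# Trial tables (CSV)
# ---------------------------------------------------------------------------

_BOOL_COLUMNS = ("companion", "extra_transport", "on_sick_leave", "took_time_off_work")


def read_consultations(path: str | Path) -> pd.DataFrame:
    """Read a consultation table, validating the documented schema.

    Errors carry 1-based data line numbers (header is line 1).
    """
    from .synthetic import CONSULTATION_COLUMNS

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"consultation table not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CONSULTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        mode = row.main_mode
        if not (pd.isna(mode) or mode in MODES):
            raise SchemaError(f"{path}: line {i}: unknown transport mode {mode!r}")
        if row.arm not in ("standard", "telemedicine"):
            raise SchemaError(f"{path}: line {i}: unknown arm {row.arm!r}")
        emp = row.employment
        if not (pd.isna(emp) or emp in EMPLOYMENT_STATUSES):
            raise SchemaError(f"{path}: line {i}: unknown employment status {emp!r}")
        if float(row.distance_km) < 0 or float(row.travel_time_min) < 0:
            raise SchemaError(f"{path}: line {i}: negative distance or travel time")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(int)
    return df[list(CONSULTATION_COLUMNS)]


def write_consultations(df: pd.DataFrame, path: str | Path) -> None:
    from .synthetic import CONSULTATION_COLUMNS

    df[list(CONSULTATION_COLUMNS)].to_csv(path, index=False)


def read_patients(path: str | Path) -> pd.DataFrame:
    from .synthetic import PATIENT_COLUMNS

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"patient table not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    level_cols = [c for c in df.columns if c.startswith("eq5d_") and "vas" not in c]
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.arm not in ("standard", "telemedicine"):
            raise SchemaError(f"{path}: line {i}: unknown arm {row.arm!r}")
    for col in level_cols:
        bad = df[col].dropna()
        if not bad.isin([1, 2, 3]).all():
            raise SchemaError(f"{path}: column {col}: levels must be 1, 2 or 3")
    return df[list(PATIENT_COLUMNS)]


def write_patients(df: pd.DataFrame, path: str | Path) -> None:
    from .synthetic import PATIENT_COLUMNS

    df[list(PATIENT_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    cost_config: Path
    fares: Path
    tariff: Path
    unit_costs: Path
    output_dir: Path
    seed: int = 0
    volume: int = 300
    patients_csv: Path | None = None
    consultations_csv: Path | None = None
    log_level: str = "INFO"
    scenario_names: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        for label in ("cost_config", "fares", "tariff", "unit_costs"):
            p = getattr(self, label)
            if not Path(p).exists():
                raise ConfigError(f"{label} file not found: {p}")
        for label in ("patients_csv", "consultations_csv"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} file not found: {p}")


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    data = _load_yaml(path)
    base = path.parent

    def resolve(key: str, default: str | None = None) -> Path | None:
        value = data.get(key, default)
        if value is None:
            return None
        if str(value).startswith("fixture:"):
            return fixture_path(str(value).split(":", 1)[1])
        p = Path(value)
        return p if p.is_absolute() else base / p

    return RunConfig(
        cost_config=resolve("cost_config", "fixture:table2_components"),
        fares=resolve("fares", "fixture:fares"),
        tariff=resolve("tariff", "fixture:uk_tto_tariff"),
        unit_costs=resolve("unit_costs", "fixture:table5_inputs"),
        output_dir=resolve("output_dir", "output"),
        seed=int(data.get("seed", 0)),
        volume=int(data.get("volume", 300)),
        patients_csv=resolve("patients_csv"),
        consultations_csv=resolve("consultations_csv"),
        log_level=str(data.get("log_level", "INFO")),
        scenario_names=tuple(data.get("scenarios", [])),
    )


def write_json(data, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
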