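"""EQ-5D-3L utility scoring and QALY computation.

Utilities come from a pluggable tariff (additive decrement model anchored at
full health = 1). The bundled default is the UK time-trade-off value set; see
``data/uk_tto_tariff.yaml``. QALYs gained are utility change times the
duration of the health state (1 year by default; no discounting within the
horizon).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import ConfigError, UndefinedMeanError

__all__ = [
    "DIMENSIONS",
    "EQ5DState",
    "QALYRecord",
    "TariffCoefficients",
    "all_states",
    "arm_mean_qaly",
    "qaly_gain",
    "score_eq5d",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


@dataclass(frozen=True)
class EQ5DState:
    """Five dimension levels (1-3, or None when unanswered) plus optional VAS.

    A state is *complete* iff all five dimension levels are present; only
    complete states are scored. VAS is descriptive and never enters QALYs.
    """

    mobility: int | None
    self_care: int | None
    usual_activities: int | None
    pain_discomfort: int | None
    anxiety_depression: int | None
    vas: float | None = None

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level is not None and level not in (1, 2, 3):
                raise ConfigError(f"{dim} level must be 1, 2 or 3, got {level!r}")
        if self.vas is not None and not (0 <= self.vas <= 100):
            raise ConfigError(f"VAS must be in [0, 100], got {self.vas!r}")

    @property
    def levels(self) -> tuple[int | None, ...]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    @property
    def complete(self) -> bool:
        return all(level is not None for level in self.levels)

    @classmethod
    def from_levels(cls, levels: Iterable[int | None], vas: float | None = None) -> "EQ5DState":
        values = tuple(levels)
        if len(values) != 5:
            raise ConfigError(f"expected 5 levels, got {len(values)}")
        return cls(*values, vas=vas)

    def __str__(self) -> str:  # e.g. "11212", "?" for missing
        return "".join("?" if lv is None else str(lv) for lv in self.levels)


@dataclass(frozen=True)
class TariffCoefficients:
    """Additive decrement tariff: utility = 1 - constant(any level > 1)
    - sum of per-dimension level decrements - N3 term (any level = 3)."""

    name: str
    any_dysfunction: float
    n3: float
    decrements: Mapping[str, Mapping[int, float]]

    def __post_init__(self) -> None:
        if self.any_dysfunction < 0 or self.n3 < 0:
            raise ConfigError("tariff constants must be >= 0")
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ConfigError(f"tariff missing decrements for {dim!r}")
            for level in (2, 3):
                dec = self.decrements[dim].get(level)
                if dec is None or dec < 0:
                    raise ConfigError(f"tariff {dim} level {level} decrement invalid")

    @property
    def floor(self) -> float:
        """Utility of the worst state (33333)."""
        return score_eq5d(EQ5DState(3, 3, 3, 3, 3), self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "TariffCoefficients":
        try:
            decrements = {
                dim: {int(k): float(v) for k, v in data["decrements"][dim].items()}
                for dim in data["decrements"]
            }
            return cls(
                name=str(data.get("name", "unnamed tariff")),
                any_dysfunction=float(data["any_dysfunction"]),
                n3=float(data["n3"]),
                decrements=decrements,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed tariff definition: {exc}") from exc


def score_eq5d(state: EQ5DState, tariff: TariffCoefficients) -> float | None:
    """Utility of a health state under ``tariff``; None for incomplete states.

    Incomplete states are excluded from means downstream, never imputed.
    """
    if not state.complete:
        return None
    levels = state.levels
    if all(level == 1 for level in levels):
        return 1.0
    utility = 1.0 - tariff.any_dysfunction
    for dim, level in zip(DIMENSIONS, levels):
        if level > 1:
            utility -= tariff.decrements[dim][level]  # type: ignore[index]
    if any(level == 3 for level in levels):
        utility -= tariff.n3
    return utility


def all_states() -> Iterator[EQ5DState]:
    """Enumerate all 243 complete EQ-5D-3L states in lexicographic order."""
    for levels in itertools.product((1, 2, 3), repeat=5):
        yield EQ5DState(*levels)


@dataclass(frozen=True)
class QALYRecord:
    patient_id: str
    utility_baseline: float | None
    utility_followup: float | None
    duration_years: float = 1.0

    @property
    def qaly_gain(self) -> float | None:
        return qaly_gain(self.utility_baseline, self.utility_followup, self.duration_years)

    @property
    def complete(self) -> bool:
        return self.utility_baseline is not None and self.utility_followup is not None


def qaly_gain(u0: float | None, u1: float | None, duration_years: float = 1.0) -> float | None:
    """QALYs gained: change in utility times duration; None if either utility
    is missing."""
    if u0 is None or u1 is None:
        return None
    return (u1 - u0) * duration_years


def arm_mean_qaly(records: Iterable[QALYRecord]) -> tuple[float, float, int]:
    """Mean, SD (ddof=1) and n of QALY gains over complete pairs only."""
    gains = [r.qaly_gain for r in records if r.complete]
    if not gains:
        raise UndefinedMeanError("no complete baseline/follow-up utility pairs")
    arr = np.asarray(gains, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def utility_table(tariff: TariffCoefficients) -> dict[str, float]:
    """Map every complete state label ('11111'..'33333') to its utility."""
    return {str(s): float(score_eq5d(s, tariff)) for s in all_states()}


def nearest_state_lookup(tariff: TariffCoefficients):
    """Build a latent-utility -> state discretizer for the generator.

    Returns ``(utilities, states)`` sorted ascending by utility, deduplicated
    on utility value (ties resolved to the lexicographically first state), and
    a callable mapping an array of latent utilities to state index arrays.
    """
    pairs = sorted(
        ((float(score_eq5d(s, tariff)), str(s)) for s in all_states()),
        key=lambda p: (p[0], p[1]),
    )
    seen: dict[float, str] = {}
    for utility, label in pairs:
        seen.setdefault(round(utility, 9), label)
    utilities = np.array(sorted(seen), dtype=float)
    states = [seen[u] for u in sorted(seen)]
    midpoints = (utilities[1:] + utilities[:-1]) / 2.0

    def discretize(latent: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(midpoints, np.asarray(latent, dtype=float))
        return idx

    return utilities, states, discretize
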