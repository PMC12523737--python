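"""Compound registry and toxicological reference parameters.

Ten heterocyclic aromatic amines (HAAs) are tracked. The *thermal* class
forms at 150-300 °C through Maillard chemistry (amino-imidazoazarenes such
as IQ, MeIQ and PhIP); the *pyrolytic* class forms above 300 °C from amino
acid pyrolysis (α- and γ-carbolines such as AαC and the Trp-P compounds).

Oral cancer slope factors (CSF, risk per mg kg⁻¹ day⁻¹ of lifetime intake)
exist for seven of the ten compounds; DMIP, 4,8-DiMeIQx and PhIP have no
validated slope factor and are excluded from incremental-lifetime-cancer-
risk sums (they still count toward total intake).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "HAAClass",
    "CompoundInfo",
    "RiskParameters",
    "compound_registry",
    "compound_names",
    "get_compound",
    "AGE_GROUPS",
]


class HAAClass(str, enum.Enum):
    THERMAL = "thermal"
    PYROLYTIC = "pyrolytic"


@dataclass(frozen=True)
class CompoundInfo:
    """One HAA: its formation class and, when defined, its cancer slope factor.

    Attributes
    ----------
    name : str
        Canonical compound label.
    haa_class : HAAClass
        Thermal (Maillard-type) or pyrolytic origin.
    csf : float or None
        Oral cancer slope factor in (mg kg⁻¹ day⁻¹)⁻¹; ``None`` when no
        validated value exists.
    """

    name: str
    haa_class: HAAClass
    csf: float | None = None


_REGISTRY: tuple[CompoundInfo, ...] = (
    CompoundInfo("4,8-DiMeIQx", HAAClass.THERMAL, None),
    CompoundInfo("DMIP", HAAClass.THERMAL, None),
    CompoundInfo("IQ", HAAClass.THERMAL, 1.4),
    CompoundInfo("MeIQ", HAAClass.THERMAL, 1.5),
    CompoundInfo("MeIQx", HAAClass.THERMAL, 1.7),
    CompoundInfo("PhIP", HAAClass.THERMAL, None),
    CompoundInfo("AαC", HAAClass.PYROLYTIC, 0.4),
    CompoundInfo("MeAαC", HAAClass.PYROLYTIC, 1.2),
    CompoundInfo("Trp-P-1", HAAClass.PYROLYTIC, 2.6),
    CompoundInfo("Trp-P-2", HAAClass.PYROLYTIC, 3.2),
)

_BY_NAME = {c.name: c for c in _REGISTRY}

#: Age groups (years) used throughout the exposure assessment.
AGE_GROUPS: tuple[int, ...] = (5, 13, 84)


def compound_registry() -> list[CompoundInfo]:
    """Return the fixed ten-compound registry."""
    return list(_REGISTRY)


def compound_names() -> list[str]:
    """Canonical compound names, registry order."""
    return [c.name for c in _REGISTRY]


def get_compound(name: str) -> CompoundInfo:
    """Look up one compound by canonical name.

    Raises
    ------
    KeyError
        If *name* is not one of the ten registered HAAs.
    """
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown compound {name!r}; known: {', '.join(_BY_NAME)}"
        ) from None


@dataclass(frozen=True)
class RiskParameters:
    """Exposure-assessment constants for the three age groups.

    ``body_weight_by_age`` is in kg, ``exposure_duration_by_age`` in years,
    ``exposure_frequency`` in days per year, ``serving_volume`` in litres.
    Age-dependent adjustment factors (ADAF) default to 3 for the two
    age groups inside the 3-15 year susceptibility window and 1 for adults.
    The averaging time AT (days) is always derived as ED × 365 and never
    stored independently.
    """

    body_weight_by_age: dict[int, float] | None = None
    exposure_duration_by_age: dict[int, float] | None = None
    exposure_frequency: float = 365.0
    serving_volume: float = 0.200
    adaf_by_age: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.body_weight_by_age is None:
            object.__setattr__(self, "body_weight_by_age", {5: 21.0, 13: 49.0, 84: 65.0})
        if self.exposure_duration_by_age is None:
            object.__setattr__(self, "exposure_duration_by_age", {5: 5.0, 13: 13.0, 84: 84.0})
        if self.adaf_by_age is None:
            object.__setattr__(self, "adaf_by_age", {5: 3.0, 13: 3.0, 84: 1.0})
        for mapping, what in (
            (self.body_weight_by_age, "body weight"),
            (self.exposure_duration_by_age, "exposure duration"),
            (self.adaf_by_age, "ADAF"),
        ):
            for age, value in mapping.items():
                if value <= 0:
                    raise ValueError(f"{what} for age {age} must be positive, got {value}")
        if self.exposure_frequency <= 0 or self.serving_volume <= 0:
            raise ValueError("exposure frequency and serving volume must be positive")

    def averaging_time(self, age_group: int) -> float:
        """AT in days: exposure duration × 365."""
        return self.exposure_duration_by_age[age_group] * 365.0
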