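"""Dietary exposure and incremental lifetime cancer risk (ILCR).

Deterministic exposure chain for HAAs in beverages:

    EDI  (mg day⁻¹)        = consumption (L day⁻¹) × C (mg L⁻¹)
    CDI  (mg kg⁻¹ day⁻¹)   = C × IR × ED × EF / (BW × AT)
    ILCR (dimensionless)   = Σ_compounds CDI × CSF × ADAF

With the exposure frequency EF fixed at 365 days year⁻¹ and the averaging
time AT derived as ED × 365 days, the CDI expression collapses algebraically
to C × IR / BW; the full form is kept so the constants remain visible and
auditable. Concentrations enter in µg L⁻¹ and are converted to mg in exactly
one place (:func:`ug_per_l_to_mg_per_l`).

Risk bands follow the usual regulatory reading of ILCR: below 10⁻⁶
negligible, above 10⁻⁴ unacceptable, in between requiring further
evaluation. A separate check compares total daily HAA intake against the
1 µg person⁻¹ day⁻¹ limit used in European food regulation; compounds
without a cancer slope factor count toward that intake even though they
cannot contribute to ILCR.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .data import Base, CensoringPolicy, ConcentrationSet, Treatment, iter_profiles
from .errors import ComputationError
from .registry import AGE_GROUPS, RiskParameters, get_compound

__all__ = [
    "RiskBand",
    "ExposureScenario",
    "RiskResult",
    "ug_per_l_to_mg_per_l",
    "edi",
    "cdi",
    "ilcr_total",
    "classify_risk",
    "ec_limit_check",
    "scenario_grid",
    "EC_DAILY_LIMIT_UG",
    "NEGLIGIBLE_THRESHOLD",
    "UNACCEPTABLE_THRESHOLD",
]

#: European Council intake limit for total HAAs, µg per person per day.
EC_DAILY_LIMIT_UG = 1.0
NEGLIGIBLE_THRESHOLD = 1e-6
UNACCEPTABLE_THRESHOLD = 1e-4

MIN_SERVINGS = 1
MAX_SERVINGS = 5


def ug_per_l_to_mg_per_l(concentration_ug_per_l: float) -> float:
    """The single µg→mg conversion point of the package."""
    return concentration_ug_per_l * 1e-3


class RiskBand(str, enum.Enum):
    NEGLIGIBLE = "negligible"
    FURTHER_EVALUATION = "further_evaluation"
    UNACCEPTABLE = "unacceptable"


@dataclass(frozen=True)
class ExposureScenario:
    """One cell of the exposure grid: age group × daily servings.

    The daily ingestion rate IR is servings × serving volume; the default
    serving is 200 mL.
    """

    age_group: int
    servings_per_day: int
    params: RiskParameters = field(default_factory=RiskParameters)
    serving_volume: float | None = None  # litres; defaults to params.serving_volume

    def __post_init__(self) -> None:
        if self.age_group not in self.params.body_weight_by_age:
            raise ComputationError(
                f"age group {self.age_group} not in parameters "
                f"{sorted(self.params.body_weight_by_age)}"
            )
        if not MIN_SERVINGS <= self.servings_per_day <= MAX_SERVINGS:
            raise ComputationError(
                f"servings per day must be in [{MIN_SERVINGS}, {MAX_SERVINGS}], "
                f"got {self.servings_per_day}"
            )

    @property
    def intake_rate(self) -> float:
        """IR, litres per day."""
        volume = self.serving_volume or self.params.serving_volume
        return self.servings_per_day * volume

    @property
    def body_weight(self) -> float:
        return self.params.body_weight_by_age[self.age_group]

    @property
    def adaf(self) -> float:
        return self.params.adaf_by_age[self.age_group]


@dataclass(frozen=True)
class RiskResult:
    """Per-compound and cumulative risk for one scenario."""

    scenario: ExposureScenario
    edi_by_compound: dict[str, float]  # mg day⁻¹
    cdi_by_compound: dict[str, float]  # mg kg⁻¹ day⁻¹
    ilcr_by_compound: dict[str, float]
    no_csf_compounds: tuple[str, ...]
    ilcr_total: float
    band: RiskBand
    total_intake_ug_per_day: float
    ec_limit_exceeded: bool


def edi(concentration_ug_per_l: float, consumption_l_per_day: float) -> float:
    """Estimated daily intake in mg day⁻¹."""
    if concentration_ug_per_l < 0 or consumption_l_per_day < 0:
        raise ComputationError("concentration and consumption must be non-negative")
    return consumption_l_per_day * ug_per_l_to_mg_per_l(concentration_ug_per_l)


def cdi(concentration_ug_per_l: float, scenario: ExposureScenario) -> float:
    """Chronic daily intake in mg kg⁻¹ day⁻¹.

    Evaluates the full C × IR × ED × EF / (BW × AT) expression; with
    AT = ED × 365 and EF = 365 this equals C × IR / BW exactly.
    """
    if concentration_ug_per_l < 0:
        raise ComputationError("concentration must be non-negative")
    params = scenario.params
    c_mg = ug_per_l_to_mg_per_l(concentration_ug_per_l)
    ed = params.exposure_duration_by_age[scenario.age_group]
    bw = scenario.body_weight
    if bw <= 0:
        raise ComputationError("body weight must be positive")
    at = params.averaging_time(scenario.age_group)
    return c_mg * scenario.intake_rate * ed * params.exposure_frequency / (bw * at)


def ilcr_total(
    profile_ug_per_l: dict[str, float], scenario: ExposureScenario
) -> RiskResult:
    """Cumulative additive ILCR of a per-compound concentration profile.

    Compounds with a cancer slope factor contribute CDI × CSF × ADAF;
    compounds without one contribute zero and are flagged, but their
    intake still counts toward the EC daily-limit check.
    """
    edi_map: dict[str, float] = {}
    cdi_map: dict[str, float] = {}
    ilcr_map: dict[str, float] = {}
    no_csf: list[str] = []
    total = 0.0
    intake_ug = 0.0
    for name, conc in profile_ug_per_l.items():
        info = get_compound(name)
        edi_map[name] = edi(conc, scenario.intake_rate)
        cdi_map[name] = cdi(conc, scenario)
        intake_ug += conc * scenario.intake_rate
        if info.csf is None:
            no_csf.append(name)
            ilcr_map[name] = 0.0
        else:
            contribution = cdi_map[name] * info.csf * scenario.adaf
            ilcr_map[name] = contribution
            total += contribution
    return RiskResult(
        scenario=scenario,
        edi_by_compound=edi_map,
        cdi_by_compound=cdi_map,
        ilcr_by_compound=ilcr_map,
        no_csf_compounds=tuple(no_csf),
        ilcr_total=total,
        band=classify_risk(total),
        total_intake_ug_per_day=intake_ug,
        ec_limit_exceeded=ec_limit_check(intake_ug),
    )


def classify_risk(ilcr: float) -> RiskBand:
    """Band an ILCR value at the 10⁻⁶ / 10⁻⁴ thresholds."""
    if ilcr < 0:
        raise ComputationError(f"ILCR must be non-negative, got {ilcr}")
    if ilcr < NEGLIGIBLE_THRESHOLD:
        return RiskBand.NEGLIGIBLE
    if ilcr >= UNACCEPTABLE_THRESHOLD:
        return RiskBand.UNACCEPTABLE
    return RiskBand.FURTHER_EVALUATION


def ec_limit_check(total_intake_ug_per_day: float) -> bool:
    """True iff total daily HAA intake strictly exceeds 1 µg per person."""
    if total_intake_ug_per_day < 0:
        raise ComputationError("intake must be non-negative")
    return total_intake_ug_per_day > EC_DAILY_LIMIT_UG


def mean_profiles(
    cset: ConcentrationSet,
    policy: CensoringPolicy = CensoringPolicy.ZERO,
    aggregation: str = "mean",
) -> dict[tuple[Base, Treatment], dict[str, float]]:
    """Per-(base, treatment) compound profiles aggregated over replicates.

    ``aggregation`` is ``"mean"`` (default) or ``"max"`` (worst case).
    """
    if aggregation not in ("mean", "max"):
        raise ComputationError(f"unknown aggregation {aggregation!r}")
    profiles = iter_profiles(cset, policy)
    meta = {sid: cset.sample_meta(sid) for sid in profiles.index}
    profiles = profiles.copy()
    profiles["__base"] = [meta[s].base for s in profiles.index]
    profiles["__treatment"] = [meta[s].treatment for s in profiles.index]
    grouped = profiles.groupby(["__base", "__treatment"], sort=False)
    agg = grouped.mean() if aggregation == "mean" else grouped.max()
    return {
        (base, treatment): row.to_dict()
        for (base, treatment), row in agg.iterrows()
    }


def scenario_grid(
    cset: ConcentrationSet,
    params: RiskParameters | None = None,
    policy: CensoringPolicy = CensoringPolicy.ZERO,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Risk results over every (base × treatment × age × servings) cell.

    The layout mirrors a beverage-risk summary table: one row per
    (base, treatment, age_group, servings) with per-compound ILCR columns,
    the cumulative ILCR, its band, and the EC intake flag.
    """
    if not cset.records:
        raise ComputationError("concentration set is empty")
    params = params or RiskParameters()
    rows = []
    for (base, treatment), profile in mean_profiles(cset, policy, aggregation).items():
        for age in AGE_GROUPS:
            for servings in range(MIN_SERVINGS, MAX_SERVINGS + 1):
                scenario = ExposureScenario(age, servings, params)
                result = ilcr_total(profile, scenario)
                row = {
                    "base": base.value,
                    "treatment": treatment.value,
                    "age_group": age,
                    "servings": servings,
                    "intake_rate_L_per_day": scenario.intake_rate,
                }
                for name, value in result.ilcr_by_compound.items():
                    row[f"ilcr_{name}"] = value
                row["ilcr_total"] = result.ilcr_total
                row["band"] = result.band.value
                row["total_intake_ug_per_day"] = result.total_intake_ug_per_day
                row["ec_limit_exceeded"] = result.ec_limit_exceeded
                rows.append(row)
    return pd.DataFrame(rows)
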