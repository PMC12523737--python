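"""Seeded synthetic-data generators for every pipeline input.

The concentration generator emulates a survey of four plant bases (almond,
soy, cashew, peanut) under five preparations (H, HS, HP, HSP, CSP): each
record is

    concentration = base_profile × treatment_multiplier
                    × synergy (sweetened AND pasteurized only)
                    × LogNormal(0, noise_sd)

with left-censoring against per-compound detection limits. Base profiles
weight pyrolytic amines in the protein-rich soy/peanut matrices and thermal
amines in almond/cashew; the commercial preparation (CSP) carries an extra
multiplier so commercial totals stochastically dominate homemade ones, and
the sugar × pasteurization synergy acts multiplicatively on top of the
individual sweetening and pasteurization effects. Default levels are
anchored to the qualitative pattern of a typical survey: sub-µg L⁻¹ leads
under no treatment, low-µg L⁻¹ totals after combined treatment, commercial
soy the most contaminated matrix.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    Base,
    Censor,
    ConcentrationRecord,
    ConcentrationSet,
    SampleMeta,
    Treatment,
)
from .doe import Factor, FactorialDesign, build_face_centered
from .errors import ConfigError, InsufficientDesignError
from .registry import compound_names
from .validation import SN_LOD, SN_LOQ, CalibrationSeries, Medium

__all__ = [
    "GeneratorConfig",
    "generate_concentrations",
    "generate_calibration",
    "generate_doe_responses",
    "generate_recovery_training",
    "DEFAULT_BASE_PROFILES",
    "DEFAULT_LODS",
]

#: Per-compound detection limits, µg L⁻¹ (all within 0.01-0.04).
DEFAULT_LODS: dict[str, float] = {
    "4,8-DiMeIQx": 0.02,
    "DMIP": 0.02,
    "IQ": 0.04,
    "MeIQ": 0.02,
    "MeIQx": 0.01,
    "PhIP": 0.02,
    "AαC": 0.01,
    "MeAαC": 0.01,
    "Trp-P-1": 0.01,
    "Trp-P-2": 0.02,
}

#: Per-compound quantification limits, µg L⁻¹ (0.02-0.05).
DEFAULT_LOQS: dict[str, float] = {
    "4,8-DiMeIQx": 0.04,
    "DMIP": 0.03,
    "IQ": 0.05,
    "MeIQ": 0.04,
    "MeIQx": 0.03,
    "PhIP": 0.04,
    "AαC": 0.03,
    "MeAαC": 0.02,
    "Trp-P-1": 0.03,
    "Trp-P-2": 0.03,
}

#: Geometric-mean concentrations (µg L⁻¹) under the untreated (H) preparation.
#: Thermal amines dominate the low-protein almond/cashew matrices; pyrolytic
#: amines dominate soy/peanut.
DEFAULT_BASE_PROFILES: dict[Base, dict[str, float]] = {
    Base.ALMOND: {
        "4,8-DiMeIQx": 0.10,
        "DMIP": 0.05,
        "IQ": 0.004,
        "MeIQ": 0.06,
        "MeIQx": 0.015,
        "PhIP": 0.07,
        "AαC": 0.004,
        "MeAαC": 0.003,
        "Trp-P-1": 0.004,
        "Trp-P-2": 0.004,
    },
    Base.SOY: {
        "4,8-DiMeIQx": 0.10,
        "DMIP": 0.20,
        "IQ": 0.06,
        "MeIQ": 0.05,
        "MeIQx": 0.08,
        "PhIP": 0.12,
        "AαC": 0.15,
        "MeAαC": 0.10,
        "Trp-P-1": 0.32,
        "Trp-P-2": 0.18,
    },
    Base.CASHEW: {
        "4,8-DiMeIQx": 0.30,
        "DMIP": 0.05,
        "IQ": 0.04,
        "MeIQ": 0.06,
        "MeIQx": 0.05,
        "PhIP": 0.08,
        "AαC": 0.010,
        "MeAαC": 0.005,
        "Trp-P-1": 0.02,
        "Trp-P-2": 0.012,
    },
    Base.PEANUT: {
        "4,8-DiMeIQx": 0.06,
        "DMIP": 0.04,
        "IQ": 0.03,
        "MeIQ": 0.03,
        "MeIQx": 0.05,
        "PhIP": 0.07,
        "AαC": 0.10,
        "MeAαC": 0.06,
        "Trp-P-1": 0.24,
        "Trp-P-2": 0.09,
    },
}

_DEFAULT_MULTIPLIERS: dict[Treatment, float] = {
    Treatment.H: 1.0,
    Treatment.HS: 1.6,
    Treatment.HP: 2.2,
    Treatment.HSP: 1.6 * 2.2,  # sweetening × pasteurization, synergy on top
    Treatment.CSP: 1.6 * 2.2 * 1.35,  # + commercial shift
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the concentration generator.

    ``synergy`` multiplies HSP and CSP only, on top of the sweetening ×
    pasteurization product already in ``treatment_multipliers``;
    ``noise_sd`` is the sigma of the multiplicative lognormal noise.
    """

    seed: int = 0
    n_replicates: int = 3
    base_profiles: dict[Base, dict[str, float]] = field(
        default_factory=lambda: {
            b: dict(p) for b, p in DEFAULT_BASE_PROFILES.items()
        }
    )
    treatment_multipliers: dict[Treatment, float] = field(
        default_factory=lambda: dict(_DEFAULT_MULTIPLIERS)
    )
    synergy: float = 1.8
    noise_sd: float = 0.25
    lods: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LODS))
    loqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOQS))

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.synergy < 0:
            raise ConfigError("synergy must be >= 0")
        for trt, mult in self.treatment_multipliers.items():
            if mult < 0:
                raise ConfigError(f"multiplier for {trt} must be >= 0")
        if set(self.base_profiles) != set(Base):
            raise ConfigError(
                "base_profiles must cover every plant base: "
                + ", ".join(b.value for b in Base)
            )
        for base, profile in self.base_profiles.items():
            for compound, level in profile.items():
                if compound not in DEFAULT_LODS:
                    raise ConfigError(f"unknown compound {compound!r} in profile")
                if level < 0:
                    raise ConfigError(
                        f"profile level for {base}/{compound} must be >= 0"
                    )
        for compound, lod in self.lods.items():
            if lod <= 0:
                raise ConfigError(f"LOD for {compound} must be positive")
            loq = self.loqs.get(compound)
            if loq is not None and loq <= lod:
                raise ConfigError(
                    f"LOQ for {compound} must exceed its LOD ({loq} <= {lod})"
                )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def expected_value(
        self, base: Base, treatment: Treatment, compound: str
    ) -> float:
        """Noise-free concentration for one cell."""
        value = self.base_profiles[base][compound]
        value *= self.treatment_multipliers[treatment]
        if treatment.sweetened and treatment.pasteurized:
            value *= self.synergy
        return value


def generate_concentrations(config: GeneratorConfig) -> ConcentrationSet:
    """Draw one full survey (bases × treatments × replicates × compounds)."""
    rng = np.random.default_rng(config.seed)
    loqs = {
        c: config.loqs.get(c, lod * SN_LOQ / SN_LOD)
        for c, lod in config.lods.items()
    }
    records: list[ConcentrationRecord] = []
    for base in Base:
        for treatment in Treatment:
            for rep in range(1, config.n_replicates + 1):
                meta = SampleMeta(
                    sample_id=f"{base.value}-{treatment.value}-r{rep}",
                    base=base,
                    treatment=treatment,
                    replicate=rep,
                )
                for compound in compound_names():
                    mean = config.expected_value(base, treatment, compound)
                    noise = (
                        rng.lognormal(0.0, config.noise_sd)
                        if config.noise_sd > 0
                        else 1.0
                    )
                    value = mean * noise
                    lod = config.lods[compound]
                    loq = loqs[compound]
                    if value < lod:
                        rec = ConcentrationRecord(
                            meta, compound, lod, Censor.BELOW_LOD
                        )
                    elif value < loq:
                        rec = ConcentrationRecord(
                            meta, compound, loq, Censor.BELOW_LOQ
                        )
                    else:
                        rec = ConcentrationRecord(
                            meta, compound, value, Censor.QUANTIFIED
                        )
                    records.append(rec)
    return ConcentrationSet(records, lod=dict(config.lods), loq=loqs)


def generate_calibration(
    compound: str = "IQ",
    slope: float = 1000.0,
    intercept: float = 50.0,
    noise_sd: float = 5.0,
    levels: tuple[float, ...] = (0.05, 1.0, 5.0, 20.0, 80.0),
    replicates: int = 3,
    matrix_factor: float = 1.0,
    seed: int = 0,
) -> tuple[CalibrationSeries, CalibrationSeries]:
    """Solvent and matrix-spiked calibration series with known truth.

    The spiked-sample slope equals ``matrix_factor × slope`` before noise,
    so the matrix effect recovered downstream is 100 (1 − matrix_factor) %.
    """
    if len(levels) < 5:
        raise InsufficientDesignError(
            f"need >= 5 calibration levels, got {len(levels)}"
        )
    rng = np.random.default_rng(seed)

    def series(eff_slope: float, medium: Medium) -> CalibrationSeries:
        points = []
        for level in levels:
            for rep in range(1, replicates + 1):
                response = intercept + eff_slope * level
                if noise_sd > 0:
                    response += rng.normal(0.0, noise_sd)
                points.append((level, rep, response))
        return CalibrationSeries(compound, tuple(points), medium)

    solvent = series(slope, Medium.SOLVENT)
    spiked = series(matrix_factor * slope, Medium.SPIKED_SAMPLE)
    return solvent, spiked


def generate_doe_responses(
    coefficients: dict[str, float],
    design: FactorialDesign | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    factor_names: list[str] | None = None,
) -> np.ndarray:
    """Linear(+interaction) truth plus seeded Gaussian noise.

    ``coefficients`` maps term labels to model coefficients: ``"intercept"``,
    main effects by factor name (e.g. ``"A"``) and interactions with ``":"``
    (e.g. ``"A:B"``). Note an effect estimated from a two-level design is
    twice the corresponding coefficient.
    """
    if isinstance(design, FactorialDesign):
        X = design.runs
        names = [f.name for f in design.factors]
    else:
        X = np.asarray(design, dtype=float)
        if factor_names is None:
            raise InsufficientDesignError(
                "factor_names required when passing a raw run matrix"
            )
        names = list(factor_names)
    index = {name: j for j, name in enumerate(names)}
    y = np.zeros(X.shape[0])
    for term, coef in coefficients.items():
        if term == "intercept":
            y += coef
            continue
        try:
            cols = [index[part] for part in term.split(":")]
        except KeyError as exc:
            raise InsufficientDesignError(
                f"term {term!r} names unknown factor {exc.args[0]!r}"
            ) from None
        y += coef * np.prod(X[:, cols], axis=1)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return y


def generate_recovery_training(
    seed: int = 0,
    noise_sd: float = 1.0,
    n_center: int = 3,
) -> tuple[np.ndarray, pd.DataFrame, list[Factor]]:
    """27-run, 4-factor recovery training set for surrogate optimization.

    Emulates tuning a miniaturized solid-phase extraction: factors are
    sorbent mass (mg), eluent volume (mL), elution flow rate (mL min⁻¹) and
    eluent acetonitrile fraction (%). The coded layout is a face-centered
    3-level composite (16 cube + 8 axial runs) plus *n_center* center
    points. Each of the ten compounds has a concave true recovery surface
    peaking near the center of the coded domain at 95-105%, so a quadratic
    surrogate with a 100%-target desirability recovers optima inside the
    typical acceptance band.
    """
    factors = [
        Factor("sorbent_mass", 5.0, 20.0, "mg"),
        Factor("eluent_volume", 0.1, 0.9, "mL"),
        Factor("flow_rate", 0.5, 2.0, "mL/min"),
        Factor("acn_fraction", 50.0, 90.0, "%"),
    ]
    X = build_face_centered(factors, n_center=n_center)
    rng = np.random.default_rng(seed)
    responses: dict[str, np.ndarray] = {}
    for compound in compound_names():
        peak = rng.uniform(95.0, 105.0)
        opt = rng.uniform(-0.25, 0.25, size=len(factors))
        curvature = rng.uniform(3.0, 8.0, size=len(factors))
        y = peak - np.sum(curvature * (X - opt) ** 2, axis=1)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
        responses[compound] = y
    return X, pd.DataFrame(responses), factors
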