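"""Analytical figures of merit: calibration, LOD/LOQ, recovery, matrix effect.

Implements the validation calculus of a trace-level quantification method:

* ordinary least-squares calibration with a replicate-based lack-of-fit
  F-test and the squared correlation of fitted vs observed responses;
* detection and quantification limits from the signal-to-noise rule
  (LOD = 3.3 σ / slope, LOQ = 10 σ / slope);
* spike recovery R% = 100 (C_found − C_real) / C_added;
* enrichment factor EF = C_extract / C_sample;
* matrix effect ME% = 100 − 100 · slope_matrix / slope_solvent (positive =
  signal suppression, negative = enhancement);
* precision as percent relative standard deviation of replicates.

The calibration model is a scikit-learn-style estimator
(:class:`CalibrationCurve`); :func:`fit_calibration` is the functional
wrapper returning an immutable :class:`CalibrationFit`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    ComputationError,
    DegenerateFitError,
    DivisionDomainError,
    InsufficientDesignError,
)

__all__ = [
    "Medium",
    "CalibrationSeries",
    "CalibrationFit",
    "CalibrationCurve",
    "fit_calibration",
    "lod_loq",
    "recovery",
    "enrichment_factor",
    "matrix_effect",
    "precision_rsd",
]

#: Signal-to-noise multipliers defining the detection and quantification limits.
SN_LOD = 3.3
SN_LOQ = 10.0

MIN_LEVELS = 5


class Medium(str, enum.Enum):
    SOLVENT = "solvent"
    SPIKED_SAMPLE = "spiked_sample"


@dataclass(frozen=True)
class CalibrationSeries:
    """Spiked-level responses for one compound in one medium.

    ``points`` holds (nominal concentration µg L⁻¹, replicate index,
    instrument response) triples; at least five distinct strictly positive
    levels are required.
    """

    compound: str
    points: tuple[tuple[float, int, float], ...]
    medium: Medium = Medium.SOLVENT

    def __post_init__(self) -> None:
        levels = sorted({p[0] for p in self.points})
        if len(levels) < MIN_LEVELS:
            raise InsufficientDesignError(
                f"calibration for {self.compound!r}: {len(levels)} distinct "
                f"level(s), need >= {MIN_LEVELS}"
            )
        if levels[0] <= 0:
            raise InsufficientDesignError(
                f"calibration for {self.compound!r}: levels must be strictly positive"
            )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([p[2] for p in self.points], dtype=float)


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted calibration line and its figures of merit."""

    compound: str
    medium: Medium
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    lod: float
    loq: float
    linear_range: tuple[float, float]
    lof_f_stat: float
    lof_p_value: float


class CalibrationCurve:
    """Least-squares calibration line with S/N-based limits, sklearn style.

    Parameters
    ----------
    noise_estimator : {"low_level_residual_sd", "blank_sd"}
        How the noise term of the S/N rule is estimated.
        ``low_level_residual_sd`` (default) takes the residual standard
        deviation of an auxiliary fit restricted to the lowest three
        calibration levels, where the noise of a trace method is measured;
        ``blank_sd`` uses the standard deviation of blank replicates passed
        to :meth:`fit`.
    lof_alpha : float
        Significance level of the lack-of-fit F-test used to trim the
        upper end of the linear range.
    n_low_levels : int
        Number of lowest levels entering the noise fit.
    """

    def __init__(
        self,
        noise_estimator: str = "low_level_residual_sd",
        lof_alpha: float = 0.05,
        n_low_levels: int = 3,
    ) -> None:
        self.noise_estimator = noise_estimator
        self.lof_alpha = lof_alpha
        self.n_low_levels = n_low_levels

    def get_params(self, deep: bool = True) -> dict:
        return {
            "noise_estimator": self.noise_estimator,
            "lof_alpha": self.lof_alpha,
            "n_low_levels": self.n_low_levels,
        }

    def set_params(self, **params) -> "CalibrationCurve":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ---------------------------------------------------------

    def fit(
        self, series: CalibrationSeries, blanks: np.ndarray | None = None
    ) -> "CalibrationCurve":
        x = series.concentrations
        y = series.responses
        if np.ptp(y) == 0:
            raise DegenerateFitError(
                f"calibration for {series.compound!r}: zero response variance"
            )

        levels = np.sort(np.unique(x))
        keep = levels
        while True:
            mask = np.isin(x, keep)
            res = stats.linregress(x[mask], y[mask])
            lof_f, lof_p = _lack_of_fit(x[mask], y[mask], res.slope, res.intercept)
            if (
                math.isnan(lof_p)
                or lof_p >= self.lof_alpha
                or len(keep) <= MIN_LEVELS
            ):
                break
            keep = keep[:-1]  # drop the highest level and refit

        fitted = res.intercept + res.slope * x[mask]
        if np.ptp(fitted) == 0:
            raise DegenerateFitError(
                f"calibration for {series.compound!r}: flat fitted line"
            )
        r2 = float(np.corrcoef(fitted, y[mask])[0, 1] ** 2)
        dof = mask.sum() - 2
        residual_sd = float(
            np.sqrt(np.sum((y[mask] - fitted) ** 2) / dof) if dof > 0 else 0.0
        )

        noise = self._noise(x, y, res, blanks)
        if res.slope <= 0:
            raise DegenerateFitError(
                f"calibration for {series.compound!r}: non-positive slope {res.slope}"
            )
        lod, loq = lod_loq(noise, res.slope)

        self.series_ = series
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = r2
        self.residual_sd_ = residual_sd
        self.lod_ = lod
        self.loq_ = loq
        self.linear_range_ = (loq, float(keep[-1]))
        self.lof_f_ = float(lof_f)
        self.lof_p_ = float(lof_p)
        return self

    def _noise(self, x, y, res, blanks) -> float:
        if self.noise_estimator == "blank_sd":
            if blanks is None or len(blanks) < 2:
                raise InsufficientDesignError(
                    "blank_sd noise estimator needs >= 2 blank replicates"
                )
            return float(np.std(np.asarray(blanks, dtype=float), ddof=1))
        if self.noise_estimator != "low_level_residual_sd":
            raise ValueError(f"unknown noise estimator {self.noise_estimator!r}")
        low = np.sort(np.unique(x))[: self.n_low_levels]
        mask = np.isin(x, low)
        if mask.sum() < 3:
            raise InsufficientDesignError("too few low-level points for noise fit")
        low_res = stats.linregress(x[mask], y[mask])
        resid = y[mask] - (low_res.intercept + low_res.slope * x[mask])
        dof = mask.sum() - 2
        return float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        """Predicted instrument response at the given concentrations."""
        self._check_fitted()
        return self.intercept_ + self.slope_ * np.asarray(concentrations, dtype=float)

    def to_fit(self) -> CalibrationFit:
        self._check_fitted()
        return CalibrationFit(
            compound=self.series_.compound,
            medium=self.series_.medium,
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            residual_sd=self.residual_sd_,
            lod=self.lod_,
            loq=self.loq_,
            linear_range=self.linear_range_,
            lof_f_stat=self.lof_f_,
            lof_p_value=self.lof_p_,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise ComputationError("CalibrationCurve is not fitted")


def _lack_of_fit(x, y, slope, intercept) -> tuple[float, float]:
    """Replicate-based lack-of-fit F-test.

    F = MS_lack-of-fit / MS_pure-error with (L − 2, N − L) degrees of
    freedom, where L is the number of distinct levels. Returns (nan, nan)
    when no replicate pure error exists.
    """
    levels = np.unique(x)
    n, L = len(x), len(levels)
    df_pe, df_lof = n - L, L - 2
    if df_pe < 1 or df_lof < 1:
        return math.nan, math.nan
    ss_pe = sum(
        float(np.sum((y[x == lv] - y[x == lv].mean()) ** 2)) for lv in levels
    )
    resid = y - (intercept + slope * x)
    ss_lof = float(np.sum(resid**2)) - ss_pe
    if ss_pe <= 0:
        return math.inf if ss_lof > 0 else math.nan, 0.0 if ss_lof > 0 else math.nan
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    return f, float(stats.f.sf(f, df_lof, df_pe))


def fit_calibration(
    series: CalibrationSeries, blanks: np.ndarray | None = None, **params
) -> CalibrationFit:
    """Fit one calibration series and return its figures of merit."""
    return CalibrationCurve(**params).fit(series, blanks=blanks).to_fit()


def lod_loq(noise: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits from the 3.3/10 signal-to-noise rule."""
    if slope <= 0:
        raise DivisionDomainError(f"slope must be positive, got {slope}")
    if noise < 0:
        raise DivisionDomainError(f"noise must be non-negative, got {noise}")
    return SN_LOD * noise / slope, SN_LOQ * noise / slope


def recovery(c_found: float, c_real: float, c_added: float) -> float:
    """Spike recovery in percent: 100 (C_found − C_real) / C_added."""
    if c_added <= 0:
        raise DivisionDomainError(f"c_added must be positive, got {c_added}")
    if c_found < 0 or c_real < 0:
        raise DivisionDomainError("concentrations must be non-negative")
    return 100.0 * (c_found - c_real) / c_added


def enrichment_factor(c_final_extract: float, c_initial_sample: float) -> float:
    """Concentration ratio extract / initial sample."""
    if c_initial_sample <= 0:
        raise DivisionDomainError(
            f"initial sample concentration must be positive, got {c_initial_sample}"
        )
    return c_final_extract / c_initial_sample


def matrix_effect(slope_spiked_sample: float, slope_solvent: float) -> float:
    """Matrix effect in percent from the two calibration slopes.

    Positive values mean signal suppression by the matrix, negative values
    enhancement.
    """
    if slope_solvent == 0:
        raise DivisionDomainError("solvent slope must be non-zero")
    return 100.0 - (slope_spiked_sample / slope_solvent) * 100.0


def precision_rsd(replicate_values) -> float:
    """Percent relative standard deviation of >= 3 replicate measurements."""
    values = np.asarray(list(replicate_values), dtype=float)
    if values.size < 3:
        raise InsufficientDesignError(
            f"precision needs >= 3 replicates, got {values.size}"
        )
    mean = values.mean()
    if mean == 0:
        raise DivisionDomainError("mean of replicates is zero")
    return 100.0 * float(values.std(ddof=1)) / float(mean)
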