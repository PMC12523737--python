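"""Long-form concentration tables with left-censoring.

The measurement unit of the whole pipeline is the long-form record: one
(sample, compound) pair carrying a concentration in µg L⁻¹ and a censoring
flag. Values below the limit of quantification are never stored as measured
numbers — a censored record carries the relevant bound (LOQ or LOD) and the
flag, and downstream totals substitute according to an explicit policy.

CSV dialect: comma-separated, UTF-8, ``.`` decimal separator, header
required. Required columns: ``sample_id, base, treatment, replicate,
compound, concentration_ug_per_L, censor``. Optional per-compound
``lod_ug_per_L`` / ``loq_ug_per_L`` columns survive a write/read round trip.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DataValidationError, FormatError
from .registry import compound_names

__all__ = [
    "Base",
    "Treatment",
    "Source",
    "Censor",
    "CensoringPolicy",
    "SampleMeta",
    "ConcentrationRecord",
    "ConcentrationSet",
    "read_concentrations",
    "write_concentrations",
    "total_haa",
]


class Base(str, enum.Enum):
    ALMOND = "almond"
    SOY = "soy"
    CASHEW = "cashew"
    PEANUT = "peanut"


class Treatment(str, enum.Enum):
    """Preparation code.

    H homemade untreated; HS homemade sweetened; HP homemade pasteurized;
    HSP homemade sweetened + pasteurized; CSP commercial (sweetened +
    pasteurized by definition).
    """

    H = "H"
    HS = "HS"
    HP = "HP"
    HSP = "HSP"
    CSP = "CSP"

    @property
    def sweetened(self) -> bool:
        return self in (Treatment.HS, Treatment.HSP, Treatment.CSP)

    @property
    def pasteurized(self) -> bool:
        return self in (Treatment.HP, Treatment.HSP, Treatment.CSP)


class Source(str, enum.Enum):
    HOMEMADE = "homemade"
    COMMERCIAL = "commercial"


class Censor(str, enum.Enum):
    QUANTIFIED = "quantified"
    BELOW_LOQ = "below_LOQ"
    BELOW_LOD = "below_LOD"


class CensoringPolicy(str, enum.Enum):
    """Substitution rule for censored values in totals.

    ``ZERO`` substitutes 0 (conservative for totals reported as ranges);
    ``HALF_LOD`` substitutes LOD/2, the other common convention.
    """

    ZERO = "zero"
    HALF_LOD = "half_lod"


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one beverage sample.

    The source is derived, never stored: commercial iff treatment is CSP.
    """

    sample_id: str
    base: Base
    treatment: Treatment
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise DataValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1, got {self.replicate}"
            )

    @property
    def source(self) -> Source:
        return Source.COMMERCIAL if self.treatment is Treatment.CSP else Source.HOMEMADE


@dataclass(frozen=True)
class ConcentrationRecord:
    meta: SampleMeta
    compound: str
    concentration: float  # µg L⁻¹; for censored records this is the bound
    censor: Censor = Censor.QUANTIFIED

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DataValidationError(
                f"sample {self.meta.sample_id!r}, compound {self.compound!r}: "
                f"negative concentration {self.concentration}"
            )


@dataclass
class ConcentrationSet:
    """Validated collection of concentration records.

    Invariants enforced at construction: no duplicate (sample_id, compound)
    keys; known compounds only; when an LOQ is known for a compound, its
    quantified records sit at or above it.
    """

    records: list[ConcentrationRecord]
    lod: dict[str, float] = field(default_factory=dict)
    loq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(compound_names())
        seen: set[tuple[str, str]] = set()
        for i, rec in enumerate(self.records):
            if rec.compound not in known:
                raise DataValidationError(
                    f"record {i}: unknown compound {rec.compound!r}"
                )
            key = (rec.meta.sample_id, rec.compound)
            if key in seen:
                raise DataValidationError(
                    f"duplicate (sample, compound) key {key!r}"
                )
            seen.add(key)
            loq = self.loq.get(rec.compound)
            if (
                rec.censor is Censor.QUANTIFIED
                and loq is not None
                and rec.concentration < loq
            ):
                raise DataValidationError(
                    f"sample {rec.meta.sample_id!r}, compound {rec.compound!r}: "
                    f"quantified value {rec.concentration} below LOQ {loq}"
                )

    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.meta.sample_id not in out:
                out.append(rec.meta.sample_id)
        return out

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for rec in self.records:
            if rec.meta.sample_id == sample_id:
                return rec.meta
        raise KeyError(f"unknown sample id {sample_id!r}")

    def records_for(self, sample_id: str) -> list[ConcentrationRecord]:
        recs = [r for r in self.records if r.meta.sample_id == sample_id]
        if not recs:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return recs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "sample_id": rec.meta.sample_id,
                    "base": rec.meta.base.value,
                    "treatment": rec.meta.treatment.value,
                    "replicate": rec.meta.replicate,
                    "compound": rec.compound,
                    "concentration_ug_per_L": rec.concentration,
                    "censor": rec.censor.value,
                    "lod_ug_per_L": self.lod.get(rec.compound),
                    "loq_ug_per_L": self.loq.get(rec.compound),
                }
            )
        return pd.DataFrame(rows)


REQUIRED_COLUMNS = (
    "sample_id",
    "base",
    "treatment",
    "replicate",
    "compound",
    "concentration_ug_per_L",
    "censor",
)


def _parse_enum(cls, raw: str, row: int, what: str):
    try:
        return cls(raw)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise DataValidationError(
            f"row {row}: invalid {what} {raw!r} (valid: {valid})"
        ) from None


def read_concentrations(path: str | Path) -> ConcentrationSet:
    """Read a long-form concentration CSV into a validated ConcentrationSet.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[ConcentrationRecord] = []
    lod: dict[str, float] = {}
    loq: dict[str, float] = {}
    known = set(compound_names())
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        compound = str(row.compound)
        if compound not in known:
            raise DataValidationError(f"row {idx}: unknown compound {compound!r}")
        conc = float(row.concentration_ug_per_L)
        if conc < 0:
            raise DataValidationError(f"row {idx}: negative concentration {conc}")
        meta = SampleMeta(
            sample_id=str(row.sample_id),
            base=_parse_enum(Base, str(row.base), idx, "base"),
            treatment=_parse_enum(Treatment, str(row.treatment), idx, "treatment"),
            replicate=int(row.replicate),
        )
        censor = _parse_enum(Censor, str(row.censor), idx, "censor flag")
        records.append(ConcentrationRecord(meta, compound, conc, censor))
        for attr, store in (("lod_ug_per_L", lod), ("loq_ug_per_L", loq)):
            value = getattr(row, attr, None)
            if value is not None and pd.notna(value):
                store[compound] = float(value)
    return ConcentrationSet(records, lod=lod, loq=loq)


def write_concentrations(cset: ConcentrationSet, path: str | Path) -> None:
    """Write the set in the same CSV schema :func:`read_concentrations` accepts."""
    cset.to_frame().to_csv(path, index=False, encoding="utf-8")


def _censored_contribution(
    rec: ConcentrationRecord, policy: CensoringPolicy, lod: dict[str, float]
) -> float:
    if policy is CensoringPolicy.ZERO:
        return 0.0
    bound = lod.get(rec.compound)
    if bound is None:
        # fall back to the bound the record itself carries
        bound = rec.concentration
    return bound / 2.0


def total_haa(
    cset: ConcentrationSet,
    sample_id: str,
    policy: CensoringPolicy = CensoringPolicy.ZERO,
) -> float:
    """Total HAA concentration (µg L⁻¹) of one sample.

    Quantified records contribute their value; censored records contribute
    per *policy* (0 by default, LOD/2 under ``HALF_LOD``). An empty sample —
    one that exists but whose records are all absent — is impossible by
    construction, but a sample whose records are all censored totals 0
    under the default policy.
    """
    total = 0.0
    for rec in cset.records_for(sample_id):
        if rec.censor is Censor.QUANTIFIED:
            total += rec.concentration
        else:
            total += _censored_contribution(rec, policy, cset.lod)
    return total


def totals_by_sample(
    cset: ConcentrationSet, policy: CensoringPolicy = CensoringPolicy.ZERO
) -> pd.Series:
    """Total HAA per sample, indexed by sample_id (first-occurrence order)."""
    ids = cset.sample_ids()
    return pd.Series(
        [total_haa(cset, sid, policy) for sid in ids], index=ids, name="total_haa"
    )


def iter_profiles(
    cset: ConcentrationSet, policy: CensoringPolicy = CensoringPolicy.ZERO
) -> pd.DataFrame:
    """Samples × compounds concentration matrix with censoring substituted.

    Row index: sample_id. Columns: the ten compounds, registry order.
    """
    ids = cset.sample_ids()
    cols = compound_names()
    mat = pd.DataFrame(0.0, index=ids, columns=cols)
    for rec in cset.records:
        if rec.censor is Censor.QUANTIFIED:
            value = rec.concentration
        else:
            value = _censored_contribution(rec, policy, cset.lod)
        mat.loc[rec.meta.sample_id, rec.compound] = value
    return mat
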