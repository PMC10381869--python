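"""Patient-level data containers and cohort CSV input/output.

A :class:`PatientRecord` holds the raw clinical measurements feeding every
composite index: joint counts, acute-phase reactant (CRP), enthesitis and
dactylitis counts, psoriasis severity (PASI), disability (HAQ), the 0-10
numerical-rating-scale items (pain, patient and physician global assessment),
SF-36 component summaries (consumed as inputs, never recomputed here), the
five PsA-5Ts thermometer responses and the twelve PsAID-12 responses.

Missing values are represented as ``None``.  No score is ever imputed: an
index whose inputs are incomplete raises :class:`MissingDataError`, so a
validity analysis cannot silently shift its n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "MissingDataError",
    "ThermometerResponses",
    "PsaidResponses",
    "PatientRecord",
    "THERMOMETER_COLUMNS",
    "PSAID_COLUMNS",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
]


class ValidationError(ValueError):
    """A field value lies outside its instrument's range."""


class MissingDataError(ValueError):
    """A score was requested whose required inputs are absent."""

    def __init__(self, index_name: str, missing: Iterable[str]):
        self.index_name = index_name
        self.missing = sorted(missing)
        super().__init__(
            f"{index_name}: missing required input(s): {', '.join(self.missing)}"
        )


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def _check(name: str, value, lo: float, hi: Optional[float], *, integer: bool = False):
    """Validate one optional numeric field; return the cleaned value."""
    if _is_missing(value):
        return None
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValidationError(f"{name}: expected a number, got {value!r}")
    if integer and float(value) != int(value):
        raise ValidationError(f"{name}: expected an integer count, got {value!r}")
    if value < lo or (hi is not None and value > hi):
        top = "inf" if hi is None else hi
        raise ValidationError(f"{name}: value {value} outside [{lo}, {top}]")
    return int(value) if integer else float(value)


@dataclass(frozen=True)
class ThermometerResponses:
    """The five PsA-5Ts thermometer marks, each on a 0-10 scale.

    The sheet is graphical (a thermometer combining a numerical rating scale
    with verbal descriptors), so any real value in [0, 10] is accepted.
    """

    pain: float
    fatigue: float
    physical_function: float
    skin_problems: float
    depression: float

    def __post_init__(self):
        for f in fields(self):
            value = getattr(self, f.name)
            if _is_missing(value):
                raise MissingDataError("PsA-5Ts", [f.name])
            object.__setattr__(self, f.name, _check(f"thermometers.{f.name}", value, 0, 10))

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, f.name) for f in fields(self))


#: PsAID-12 item names in questionnaire order (item 1 .. item 12).
PSAID_ITEMS = (
    "pain",
    "fatigue",
    "skin",
    "work_leisure",
    "function",
    "discomfort",
    "sleep",
    "coping",
    "anxiety",
    "embarrassment",
    "social_life",
    "depression",
)


@dataclass(frozen=True)
class PsaidResponses:
    """The twelve PsAID-12 numerical-rating-scale responses, each 0-10."""

    pain: float
    fatigue: float
    skin: float
    work_leisure: float
    function: float
    discomfort: float
    sleep: float
    coping: float
    anxiety: float
    embarrassment: float
    social_life: float
    depression: float

    def __post_init__(self):
        for f in fields(self):
            value = getattr(self, f.name)
            if _is_missing(value):
                raise MissingDataError("PsAID-12", [f.name])
            object.__setattr__(self, f.name, _check(f"psaid.{f.name}", value, 0, 10))

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, f.name) for f in fields(self))


# (field, lo, hi, integer) validation table for the scalar record fields.
_FIELD_RANGES = {
    "tjc68": (0, 68, True),
    "sjc66": (0, 66, True),
    "crp": (0, None, False),
    "lei": (0, 6, True),
    "dactylitis_count": (0, None, True),
    "pasi": (0, 72, False),
    "haq": (0, 3, False),
    "pain_nrs": (0, 10, False),
    "ptga": (0, 10, False),
    "phga": (0, 10, False),
    "gh": (0, 100, False),
    "pcs": (0, 100, False),
    "mcs": (0, 100, False),
    "basdai": (0, 10, False),
    "comorbidity_count": (0, None, True),
}


@dataclass
class PatientRecord:
    """One patient's raw measurements.

    All fields are optional; each scoring operation declares the subset it
    needs and raises :class:`MissingDataError` when any is absent.  ``basdai``
    is only meaningful for patients with axial involvement and is ``None``
    otherwise (the CPDAI spinal domain then contributes 0).  ``gh``,
    ``mcs`` and ``comorbidity_count`` are housed as inputs only.
    """

    patient_id: Optional[str] = None
    tjc68: Optional[int] = None
    sjc66: Optional[int] = None
    crp: Optional[float] = None  # mg/dL
    lei: Optional[int] = None
    dactylitis_count: Optional[int] = None
    pasi: Optional[float] = None
    haq: Optional[float] = None
    pain_nrs: Optional[float] = None
    ptga: Optional[float] = None
    phga: Optional[float] = None
    gh: Optional[float] = None
    pcs: Optional[float] = None
    mcs: Optional[float] = None
    basdai: Optional[float] = None
    thermometers: Optional[ThermometerResponses] = None
    psaid: Optional[PsaidResponses] = None
    comorbidity_count: Optional[int] = None

    def __post_init__(self):
        for name, (lo, hi, integer) in _FIELD_RANGES.items():
            setattr(self, name, _check(name, getattr(self, name), lo, hi, integer=integer))

    def require(self, index_name: str, names: Sequence[str]) -> None:
        """Raise :class:`MissingDataError` naming every absent field."""
        missing = [n for n in names if _is_missing(getattr(self, n))]
        if missing:
            raise MissingDataError(index_name, missing)


THERMOMETER_COLUMNS = tuple(f"t_{f.name}" for f in fields(ThermometerResponses))
PSAID_COLUMNS = tuple(f"psaid_{i:02d}" for i in range(1, 13))

_SCALAR_COLUMNS = (
    "patient_id",
    "tjc68",
    "sjc66",
    "crp",
    "lei",
    "dactylitis_count",
    "pasi",
    "haq",
    "pain_nrs",
    "ptga",
    "phga",
    "gh",
    "pcs",
    "mcs",
    "basdai",
    "comorbidity_count",
)

#: Canonical cohort CSV column order.
COHORT_COLUMNS = _SCALAR_COLUMNS + THERMOMETER_COLUMNS + PSAID_COLUMNS


def _row_to_record(row: pd.Series) -> PatientRecord:
    kwargs = {}
    for name in _SCALAR_COLUMNS:
        if name in row.index:
            value = row[name]
            kwargs[name] = None if _is_missing(value) else value
    pid = kwargs.get("patient_id")
    if pid is not None:
        kwargs["patient_id"] = str(pid)
    t_vals = [row.get(c) for c in THERMOMETER_COLUMNS]
    if all(not _is_missing(v) for v in t_vals):
        kwargs["thermometers"] = ThermometerResponses(*t_vals)
    p_vals = [row.get(c) for c in PSAID_COLUMNS]
    if all(not _is_missing(v) for v in p_vals):
        kwargs["psaid"] = PsaidResponses(*p_vals)
    return PatientRecord(**kwargs)


def read_cohort(
    path,
    *,
    crp_unit: str = "mg/dL",
    convert_crp: bool = False,
) -> list[PatientRecord]:
    """Read a cohort CSV (one row per patient) into validated records.

    DAPSA is defined on CRP in mg/dL.  A file declared as ``crp_unit='mg/L'``
    is rejected unless ``convert_crp=True``, in which case values are divided
    by 10 on ingest.
    """
    if crp_unit not in ("mg/dL", "mg/L"):
        raise ValidationError(f"crp_unit must be 'mg/dL' or 'mg/L', got {crp_unit!r}")
    df = pd.read_csv(path)
    if crp_unit == "mg/L":
        if not convert_crp:
            raise ValidationError(
                "CRP declared in mg/L; DAPSA requires mg/dL "
                "(pass convert_crp=True to convert on ingest)"
            )
        if "crp" in df.columns:
            df["crp"] = df["crp"] / 10.0
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(_row_to_record(row))
        except ValueError as exc:
            raise ValidationError(f"row {i + 2} ({path}): {exc}") from exc
    return records


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records into the canonical cohort CSV layout."""
    rows = []
    for rec in records:
        row = {name: getattr(rec, name) for name in _SCALAR_COLUMNS}
        if rec.thermometers is not None:
            row.update(dict(zip(THERMOMETER_COLUMNS, rec.thermometers.as_tuple())))
        if rec.psaid is not None:
            row.update(dict(zip(PSAID_COLUMNS, rec.psaid.as_tuple())))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
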