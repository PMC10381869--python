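"""Instrument scoring: PsA-5Ts, DAPSA, CPDAI, PASDAS, PsAID-12, MDA, LEI,
PASI and HAQ, with their published activity bands.

Each operation validates its inputs, computes the published formula exactly
(no rounding before band classification) and raises a typed error rather than
imputing anything.

Scale conventions
-----------------
* PsA-5Ts: five 0-10 thermometer items weighted 3 (pain), 2 (fatigue),
  2 (physical function), 2 (skin problems), 1 (depression); range 0-100.
* DAPSA: TJC68 + SJC66 + pain NRS + PtGA + CRP (mg/dL).
* PASDAS: the published regression equation with natural logarithms; the
  global assessments enter on a 0-100 VAS.  Records carry 0-10 NRS globals,
  so the default ``global_scale='vas100'`` multiplies them by 10 first
  (``'nrs10'`` uses them as stored).
* PsAID-12: twelve 0-10 items weighted 3,2,2,2,2,2,2,1,1,1,1,1 and divided
  by 20, hence a 0-10 range with the all-equal fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import (
    MissingDataError,
    PatientRecord,
    PsaidResponses,
    ThermometerResponses,
    ValidationError,
)

__all__ = [
    "ActivityBand",
    "MdaResult",
    "PasiRegion",
    "PasiComponents",
    "CpdaiDomainRule",
    "CpdaiGrid",
    "CpdaiConfigError",
    "ScorePanel",
    "PSA5TS_WEIGHTS",
    "PSAID_WEIGHTS",
    "default_cpdai_grid",
    "score_psa5ts",
    "score_dapsa",
    "classify_dapsa",
    "score_pasdas",
    "score_cpdai",
    "score_psaid12",
    "classify_psaid12",
    "classify_mda",
    "score_lei",
    "score_pasi",
    "score_haq",
    "score_panel",
]


@dataclass(frozen=True)
class ActivityBand:
    """A half-open disease-activity interval for one instrument."""

    label: str  # REM, LDA, MDA or HDA
    instrument: str
    lower: float  # exclusive (except at the scale minimum)
    upper: float  # inclusive

    def __contains__(self, score: float) -> bool:
        return (self.lower < score or (score == self.lower == 0)) and score <= self.upper


def _band(label, instrument, lower, upper):
    return ActivityBand(label, instrument, lower, upper)


#: DAPSA cut-offs: <=4 REM, (4, 14] LDA, (14, 28] MDA, >28 HDA.
DAPSA_BANDS = (
    _band("REM", "DAPSA", 0.0, 4.0),
    _band("LDA", "DAPSA", 4.0, 14.0),
    _band("MDA", "DAPSA", 14.0, 28.0),
    _band("HDA", "DAPSA", 28.0, math.inf),
)

#: PsAID-12 cut-offs: <=1.4 REM, (1.4, 4.1] LDA, (4.1, 6.7] MDA, >6.7 HDA.
PSAID_BANDS = (
    _band("REM", "PsAID-12", 0.0, 1.4),
    _band("LDA", "PsAID-12", 1.4, 4.1),
    _band("MDA", "PsAID-12", 4.1, 6.7),
    _band("HDA", "PsAID-12", 6.7, 10.0),
)


# ---------------------------------------------------------------------------
# PsA-5Ts
# ---------------------------------------------------------------------------

#: PsA-5Ts item weights (sum 10, so the maximum score is 100).
PSA5TS_WEIGHTS = {
    "pain": 3.0,
    "fatigue": 2.0,
    "physical_function": 2.0,
    "skin_problems": 2.0,
    "depression": 1.0,
}


def score_psa5ts(t: ThermometerResponses) -> float:
    """Weighted sum of the five thermometer responses, range 0-100."""
    if not isinstance(t, ThermometerResponses):
        t = ThermometerResponses(*t)
    return sum(w * getattr(t, item) for item, w in PSA5TS_WEIGHTS.items())


# ---------------------------------------------------------------------------
# DAPSA
# ---------------------------------------------------------------------------

def score_dapsa(r: PatientRecord) -> float:
    """Algebraic sum TJC68 + SJC66 + pain NRS + PtGA + CRP (mg/dL)."""
    r.require("DAPSA", ("tjc68", "sjc66", "pain_nrs", "ptga", "crp"))
    return float(r.tjc68 + r.sjc66 + r.pain_nrs + r.ptga + r.crp)


def classify_dapsa(score: float) -> ActivityBand:
    if score < 0:
        raise ValidationError(f"DAPSA score must be non-negative, got {score}")
    for band in DAPSA_BANDS:
        if score in band:
            return band
    raise AssertionError("unreachable: DAPSA bands cover [0, inf)")


# ---------------------------------------------------------------------------
# PASDAS
# ---------------------------------------------------------------------------

def score_pasdas(r: PatientRecord, *, global_scale: str = "vas100") -> float:
    """Published PASDAS regression equation.

    ``(0.18*sqrt(PhGA) + 0.159*sqrt(PtGA) - 0.253*sqrt(PCS)
    + 0.101*ln(SJC+1) + 0.048*ln(TJC+1) + 0.23*ln(LEI+1)
    + 0.377*ln(dactylitis+1) + 0.102*ln(CRP+1) + 2) * 1.5``

    with the global assessments on a 0-100 VAS.
    """
    if global_scale not in ("vas100", "nrs10"):
        raise ValidationError(f"global_scale must be 'vas100' or 'nrs10', got {global_scale!r}")
    r.require(
        "PASDAS",
        ("phga", "ptga", "pcs", "sjc66", "tjc68", "lei", "dactylitis_count", "crp"),
    )
    factor = 10.0 if global_scale == "vas100" else 1.0
    phga = r.phga * factor
    ptga = r.ptga * factor
    return 1.5 * (
        0.18 * math.sqrt(phga)
        + 0.159 * math.sqrt(ptga)
        - 0.253 * math.sqrt(r.pcs)
        + 0.101 * math.log(r.sjc66 + 1)
        + 0.048 * math.log(r.tjc68 + 1)
        + 0.23 * math.log(r.lei + 1)
        + 0.377 * math.log(r.dactylitis_count + 1)
        + 0.102 * math.log(r.crp + 1)
        + 2.0
    )


# ---------------------------------------------------------------------------
# CPDAI
# ---------------------------------------------------------------------------

class CpdaiConfigError(ValueError):
    """A CPDAI grid rule does not cover a measurement."""


@dataclass(frozen=True)
class CpdaiDomainRule:
    """Maps one domain's severity measurement to a 0-3 grade.

    ``thresholds`` is an ordered sequence of ``(upper_bound, grade)`` pairs;
    the first pair whose bound is >= the measurement supplies the base grade
    (``math.inf`` as a final bound makes the rule total).  When
    ``function_bump`` is set, an active domain (measurement > 0) in a patient
    with impaired function (HAQ > ``haq_threshold``) is raised one grade,
    capped at 3 — the structure of the original grid, where functional
    impairment escalates each involved domain.
    """

    thresholds: tuple  # ((bound, grade), ...), bounds ascending
    function_bump: bool = False
    haq_threshold: float = 0.5

    def grade(self, value: float, haq: Optional[float] = None) -> int:
        base = None
        for bound, grade in self.thresholds:
            if value <= bound:
                base = grade
                break
        if base is None:
            raise CpdaiConfigError(f"no grid rule covers measurement {value}")
        if not 0 <= base <= 3:
            raise CpdaiConfigError(f"grid grade {base} outside 0-3")
        if self.function_bump and value > 0 and haq is not None and haq > self.haq_threshold:
            base = min(base + 1, 3)
        return base


@dataclass(frozen=True)
class CpdaiGrid:
    """Per-domain grading rules for the five CPDAI domains."""

    arthritis: CpdaiDomainRule
    skin: CpdaiDomainRule
    enthesitis: CpdaiDomainRule
    dactylitis: CpdaiDomainRule
    spine: CpdaiDomainRule


def default_cpdai_grid() -> CpdaiGrid:
    """Default grid adapted from the original instrument's published cut-offs.

    Externally sourced, not part of this package's validation data.  The
    original grades skin with both PASI and DLQI; DLQI is not collected here,
    so the skin rule is a PASI-only adaptation (0 / <=10 / <=20 / >20).
    Arthritis is graded on the larger of the tender and swollen joint counts.
    """
    return CpdaiGrid(
        arthritis=CpdaiDomainRule(((0, 0), (4, 1), (math.inf, 2)), function_bump=True),
        skin=CpdaiDomainRule(((0, 0), (10, 1), (20, 2), (math.inf, 3))),
        enthesitis=CpdaiDomainRule(((0, 0), (3, 1), (math.inf, 2)), function_bump=True),
        dactylitis=CpdaiDomainRule(((0, 0), (3, 1), (math.inf, 2)), function_bump=True),
        spine=CpdaiDomainRule(((0, 0), (4, 1), (math.inf, 2)), function_bump=True),
    )


def score_cpdai(r: PatientRecord, grid: Optional[CpdaiGrid] = None) -> int:
    """Sum of five 0-3 domain grades, range 0-15.

    The spinal domain is graded on BASDAI when axial disease is present
    (``basdai`` set) and contributes 0 otherwise.
    """
    if grid is None:
        grid = default_cpdai_grid()
    r.require("CPDAI", ("tjc68", "sjc66", "pasi", "lei", "dactylitis_count"))
    haq = r.haq
    total = (
        grid.arthritis.grade(max(r.tjc68, r.sjc66), haq)
        + grid.skin.grade(r.pasi, haq)
        + grid.enthesitis.grade(r.lei, haq)
        + grid.dactylitis.grade(r.dactylitis_count, haq)
        + (grid.spine.grade(r.basdai, haq) if r.basdai is not None else 0)
    )
    return int(total)


# ---------------------------------------------------------------------------
# PsAID-12
# ---------------------------------------------------------------------------

#: PsAID-12 item weights in questionnaire order (sum 20).
PSAID_WEIGHTS = {
    "pain": 3.0,
    "fatigue": 2.0,
    "skin": 2.0,
    "work_leisure": 2.0,
    "function": 2.0,
    "discomfort": 2.0,
    "sleep": 2.0,
    "coping": 1.0,
    "anxiety": 1.0,
    "embarrassment": 1.0,
    "social_life": 1.0,
    "depression": 1.0,
}


def score_psaid12(p: PsaidResponses) -> float:
    """Weighted sum of the twelve items divided by 20; range 0-10."""
    if not isinstance(p, PsaidResponses):
        p = PsaidResponses(*p)
    return sum(w * getattr(p, item) for item, w in PSAID_WEIGHTS.items()) / 20.0


def classify_psaid12(score: float) -> ActivityBand:
    if not 0 <= score <= 10:
        raise ValidationError(f"PsAID-12 score must be in [0, 10], got {score}")
    for band in PSAID_BANDS:
        if score in band:
            return band
    raise AssertionError("unreachable: PsAID-12 bands cover [0, 10]")


# ---------------------------------------------------------------------------
# MDA
# ---------------------------------------------------------------------------

#: The seven minimal-disease-activity criteria: (name, record field, cut-off),
#: each evaluated inclusively.
MDA_CRITERIA = (
    ("tjc", "tjc68", 1.0),
    ("sjc", "sjc66", 1.0),
    ("pasi", "pasi", 1.0),
    ("pain", "pain_nrs", 1.5),
    ("ptga", "ptga", 2.0),
    ("haq", "haq", 0.5),
    ("entheseal", "lei", 1.0),
)


@dataclass(frozen=True)
class MdaResult:
    """Outcome of the 7-criterion minimal-disease-activity assessment."""

    criteria_met: dict
    n_met: int
    verdict: bool  # True iff at least 5 of 7 criteria hold


def classify_mda(r: PatientRecord) -> MdaResult:
    """Evaluate the seven MDA criteria; the verdict is never guessed, so all
    seven inputs must be present."""
    r.require("MDA", tuple(fld for _, fld, _ in MDA_CRITERIA))
    met = {name: getattr(r, fld) <= cut for name, fld, cut in MDA_CRITERIA}
    n_met = sum(met.values())
    return MdaResult(criteria_met=met, n_met=n_met, verdict=n_met >= 5)


# ---------------------------------------------------------------------------
# LEI
# ---------------------------------------------------------------------------

def score_lei(sites: Sequence) -> int:
    """Count of tender entheseal sites out of six dichotomous assessments."""
    sites = list(sites)
    if len(sites) != 6:
        raise ValidationError(f"LEI requires exactly 6 site assessments, got {len(sites)}")
    for s in sites:
        if s not in (0, 1, True, False):
            raise ValidationError(f"LEI site assessments are dichotomous (0/1), got {s!r}")
    return int(sum(bool(s) for s in sites))


# ---------------------------------------------------------------------------
# PASI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PasiRegion:
    """Severity grades (0-4) and area grade (0-6) for one body region."""

    erythema: int
    induration: int
    desquamation: int
    area: int

    def __post_init__(self):
        for name in ("erythema", "induration", "desquamation"):
            v = getattr(self, name)
            if not (isinstance(v, int) and 0 <= v <= 4):
                raise ValidationError(f"PASI {name} grade must be an integer 0-4, got {v!r}")
        if not (isinstance(self.area, int) and 0 <= self.area <= 6):
            raise ValidationError(f"PASI area grade must be an integer 0-6, got {self.area!r}")

    @property
    def severity_sum(self) -> int:
        return self.erythema + self.induration + self.desquamation


@dataclass(frozen=True)
class PasiComponents:
    head: PasiRegion
    upper_limbs: PasiRegion
    trunk: PasiRegion
    lower_limbs: PasiRegion


#: Standard body-surface weights per region.
PASI_REGION_WEIGHTS = {
    "head": 0.1,
    "upper_limbs": 0.2,
    "trunk": 0.3,
    "lower_limbs": 0.4,
}


def score_pasi(components: PasiComponents) -> float:
    """Standard weighted regional sum: weight * (E+I+D) * area, summed over
    the four regions; range 0-72 in 0.1 steps."""
    total = sum(
        w * getattr(components, region).severity_sum * getattr(components, region).area
        for region, w in PASI_REGION_WEIGHTS.items()
    )
    return round(total, 10)


# ---------------------------------------------------------------------------
# HAQ
# ---------------------------------------------------------------------------

#: The eight HAQ categories and how many of the 20 items each contains.
HAQ_CATEGORIES = (
    ("dressing_grooming", 2),
    ("arising", 2),
    ("eating", 3),
    ("walking", 2),
    ("hygiene", 3),
    ("reach", 2),
    ("grip", 3),
    ("activities", 3),
)

_HAQ_MIN_CATEGORIES = 6  # standard allowance: at least 6 of 8 categories


def score_haq(items: Sequence) -> float:
    """Standard 8-category aggregation of the 20 difficulty ratings (0-3).

    The category score is the maximum of its items; the total is the mean of
    the category scores (hence 0-3 in 0.125 steps when all 8 are present).
    Items given as ``None`` are missing; a category with any missing item is
    dropped, and fewer than 6 scorable categories is an error.  No
    aids/devices adjustment is applied.
    """
    items = list(items)
    if len(items) != 20:
        raise ValidationError(f"HAQ requires exactly 20 item ratings, got {len(items)}")
    category_scores = []
    pos = 0
    for name, size in HAQ_CATEGORIES:
        chunk = items[pos:pos + size]
        pos += size
        if any(v is None for v in chunk):
            continue
        for v in chunk:
            if v not in (0, 1, 2, 3):
                raise ValidationError(f"HAQ item rating must be 0-3, got {v!r} in {name}")
        category_scores.append(max(chunk))
    if len(category_scores) < _HAQ_MIN_CATEGORIES:
        raise MissingDataError(
            "HAQ", [f"only {len(category_scores)} complete categories (need >= 6)"]
        )
    return sum(category_scores) / len(category_scores)


# ---------------------------------------------------------------------------
# Score panel
# ---------------------------------------------------------------------------

@dataclass
class ScorePanel:
    """All derived indices for one patient, with activity bands."""

    patient_id: Optional[str]
    psa5ts: float
    dapsa: float
    dapsa_band: str
    cpdai: int
    pasdas: float
    psaid12: float
    psaid12_band: str
    mda: MdaResult
    haq: Optional[float]
    pasi: Optional[float]
    lei: Optional[int]
    pcs: Optional[float]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "psa5ts": round(self.psa5ts, 2),
            "dapsa": round(self.dapsa, 2),
            "dapsa_band": self.dapsa_band,
            "cpdai": self.cpdai,
            "pasdas": round(self.pasdas, 2),
            "psaid12": round(self.psaid12, 2),
            "psaid12_band": self.psaid12_band,
            "mda_n_met": self.mda.n_met,
            "mda": self.mda.verdict,
            "haq": self.haq,
            "pasi": self.pasi,
            "lei": self.lei,
            "pcs": self.pcs,
        }


def score_panel(
    r: PatientRecord,
    *,
    grid: Optional[CpdaiGrid] = None,
    pasdas_global_scale: str = "vas100",
) -> ScorePanel:
    """Score every instrument for one complete record.

    Band classification uses the unrounded scores.
    """
    if r.thermometers is None:
        raise MissingDataError("PsA-5Ts", ["thermometers"])
    if r.psaid is None:
        raise MissingDataError("PsAID-12", ["psaid"])
    dapsa = score_dapsa(r)
    psaid = score_psaid12(r.psaid)
    return ScorePanel(
        patient_id=r.patient_id,
        psa5ts=score_psa5ts(r.thermometers),
        dapsa=dapsa,
        dapsa_band=classify_dapsa(dapsa).label,
        cpdai=score_cpdai(r, grid),
        pasdas=score_pasdas(r, global_scale=pasdas_global_scale),
        psaid12=psaid,
        psaid12_band=classify_psaid12(psaid).label,
        mda=classify_mda(r),
        haq=r.haq,
        pasi=r.pasi,
        lei=r.lei,
        pcs=r.pcs,
    )
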