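"""Delphi item-reduction computations behind the PsA-5Ts instrument.

Seventeen candidate health domains were rated by a panel of 22 rheumatologists
on two scales: Lynn's 4-point relevance scale (4 = extremely relevant ...
1 = irrelevant) and a 0-3 importance scale.  The quantitative reduction then
uses three numbers per domain:

* CVI (Content Validity Index): the proportion of experts rating the domain
  2, 3 or 4 on the relevance scale.
* mean importance: the panel mean of the 0-3 importance ratings.
* FIP (Frequency Importance Product): ``100 * CVI * mean importance``, used
  to rank the domains.

Domains with CVI <= 0.69 have unacceptable content validity and are
eliminated; a retained domain additionally needs a mean importance of at
least 2.0.  On the development panel's data this keeps exactly five domains
(pain, fatigue, functional capacity, skin problems, depressive mood), which
became the five thermometers.

The published panel summary ships with the package
(:func:`load_expert_panel`) as the fixture for tests and for the ``delphi``
CLI subcommand.  Two of its printed values are anomalous and are carried
as printed: the functional-capacity FIP (193.60, vs 191.84 recomputed from
the rounded CVI) and the sexual-life row's position (its FIP exceeds the row
above it).  This module always recomputes FIP and ranks strictly by it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import ValidationError

__all__ = [
    "ExpertRatingMatrix",
    "DomainSummary",
    "compute_cvi",
    "mean_importance",
    "compute_fip",
    "band_content_validity",
    "retain_items",
    "rank_by_fip",
    "summarize_ratings",
    "summaries_from_table",
    "load_expert_panel",
    "read_ratings_csv",
]

#: CVI bands: adequate >= 0.88; unacceptable <= 0.69; questionable between
#: (the published bands leave (0.69, 0.70) undefined; it is assigned to
#: questionable for continuity with the 70-88% band).
ADEQUATE_CVI = 0.88
UNACCEPTABLE_CVI = 0.69

#: Retention: CVI above the elimination cut AND mean importance >= this floor.
DEFAULT_IMPORTANCE_FLOOR = 2.0


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass
class ExpertRatingMatrix:
    """Rater x domain ratings on both panel scales.

    ``relevance`` holds Lynn's 1-4 ratings (feeds CVI only); ``importance``
    holds the 0-3 ratings (feeds mean importance only).  Cells may be ``None``
    (explicit missing) and are excluded from denominators.
    """

    raters: list
    domains: list
    relevance: list  # rows = raters, columns = domains
    importance: list

    def __post_init__(self):
        n_r, n_d = len(self.raters), len(self.domains)
        for name, matrix, lo, hi in (
            ("relevance", self.relevance, 1, 4),
            ("importance", self.importance, 0, 3),
        ):
            if len(matrix) != n_r or any(len(row) != n_d for row in matrix):
                raise ValidationError(f"{name} matrix must be {n_r} raters x {n_d} domains")
            for row in matrix:
                for v in row:
                    if _is_missing(v):
                        continue
                    if not lo <= v <= hi:
                        raise ValidationError(f"{name} rating {v!r} outside {lo}-{hi}")

    def domain_relevance(self, domain: str) -> list:
        j = self.domains.index(domain)
        return [row[j] for row in self.relevance if not _is_missing(row[j])]

    def domain_importance(self, domain: str) -> list:
        j = self.domains.index(domain)
        return [row[j] for row in self.importance if not _is_missing(row[j])]


@dataclass(frozen=True)
class DomainSummary:
    """One domain's content-validity numbers (one table row)."""

    domain: str
    cvi: float
    mean_importance: float
    fip: float
    band: str
    retained: bool


def compute_cvi(ratings: Sequence) -> float:
    """Proportion of experts rating the domain 2, 3 or 4 on the 1-4 scale."""
    ratings = [r for r in ratings if not _is_missing(r)]
    if not ratings:
        raise ValidationError("CVI requires at least one rating")
    for r in ratings:
        if not 1 <= r <= 4:
            raise ValidationError(f"relevance rating {r!r} outside Lynn's 1-4 scale")
    return sum(1 for r in ratings if r >= 2) / len(ratings)


def mean_importance(ratings: Sequence) -> float:
    """Panel mean of the 0-3 importance ratings."""
    ratings = [r for r in ratings if not _is_missing(r)]
    if not ratings:
        raise ValidationError("mean importance requires at least one rating")
    for r in ratings:
        if not 0 <= r <= 3:
            raise ValidationError(f"importance rating {r!r} outside the 0-3 scale")
    return sum(ratings) / len(ratings)


def compute_fip(cvi: float, mean_imp: float) -> float:
    """Frequency Importance Product: ``100 * CVI * mean importance``."""
    if not 0 <= cvi <= 1:
        raise ValidationError(f"CVI must be in [0, 1], got {cvi}")
    if not 0 <= mean_imp <= 3:
        raise ValidationError(f"mean importance must be in [0, 3], got {mean_imp}")
    return 100.0 * cvi * mean_imp


def band_content_validity(cvi: float) -> str:
    """'adequate' (>= 88%), 'questionable' (70-88%, plus the undefined
    (69%, 70%) sliver) or 'unacceptable' (<= 69%)."""
    if not 0 <= cvi <= 1:
        raise ValidationError(f"CVI must be in [0, 1], got {cvi}")
    if cvi >= ADEQUATE_CVI:
        return "adequate"
    if cvi <= UNACCEPTABLE_CVI:
        return "unacceptable"
    return "questionable"


def _make_summary(domain: str, cvi: float, mean_imp: float,
                  importance_floor: float = DEFAULT_IMPORTANCE_FLOOR) -> DomainSummary:
    return DomainSummary(
        domain=domain,
        cvi=cvi,
        mean_importance=mean_imp,
        fip=compute_fip(cvi, mean_imp),
        band=band_content_validity(cvi),
        retained=(cvi > UNACCEPTABLE_CVI and mean_imp >= importance_floor),
    )


def summarize_ratings(
    matrix: ExpertRatingMatrix,
    importance_floor: float = DEFAULT_IMPORTANCE_FLOOR,
) -> list[DomainSummary]:
    """Full per-domain reduction from raw panel ratings, ranked by FIP."""
    summaries = [
        _make_summary(
            d,
            compute_cvi(matrix.domain_relevance(d)),
            mean_importance(matrix.domain_importance(d)),
            importance_floor,
        )
        for d in matrix.domains
    ]
    return rank_by_fip(summaries)


def summaries_from_table(
    table: pd.DataFrame,
    importance_floor: float = DEFAULT_IMPORTANCE_FLOOR,
) -> list[DomainSummary]:
    """Build summaries from precomputed per-domain CVI and mean importance
    (columns ``domain``, ``cvi``, ``mean_importance``); FIP is recomputed."""
    required = {"domain", "cvi", "mean_importance"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"summary table missing column(s): {', '.join(sorted(missing))}")
    summaries = [
        _make_summary(str(row.domain), float(row.cvi), float(row.mean_importance),
                      importance_floor)
        for row in table.itertuples()
    ]
    return rank_by_fip(summaries)


def retain_items(
    summaries: Iterable[DomainSummary],
    importance_floor: float = DEFAULT_IMPORTANCE_FLOOR,
) -> list[DomainSummary]:
    """Domains surviving the reduction: CVI above the elimination cut
    (> 0.69) and mean importance at or above the floor."""
    return [
        s for s in summaries
        if s.cvi > UNACCEPTABLE_CVI and s.mean_importance >= importance_floor
    ]


def rank_by_fip(summaries: Iterable[DomainSummary]) -> list[DomainSummary]:
    """Descending FIP; ties broken by descending CVI, then by label."""
    return sorted(summaries, key=lambda s: (-s.fip, -s.cvi, s.domain))


def load_expert_panel() -> pd.DataFrame:
    """Packaged development-panel summary: per-domain CVI, mean importance
    and (for reference) the FIP as originally printed."""
    with resources.files("psa5ts.data").joinpath("expert_panel_summary.csv").open() as fh:
        return pd.read_csv(fh)


def read_ratings_csv(path) -> ExpertRatingMatrix:
    """Read long-format panel ratings
    (``rater, domain, relevance_1to4, importance_0to3``)."""
    df = pd.read_csv(path)
    required = {"rater", "domain", "relevance_1to4", "importance_0to3"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ratings file missing column(s): {', '.join(sorted(missing))}")
    raters = list(dict.fromkeys(df["rater"]))
    domains = list(dict.fromkeys(df["domain"]))
    rel = [[None] * len(domains) for _ in raters]
    imp = [[None] * len(domains) for _ in raters]
    for row in df.itertuples():
        i, j = raters.index(row.rater), domains.index(row.domain)
        rel[i][j] = None if _is_missing(row.relevance_1to4) else row.relevance_1to4
        imp[i][j] = None if _is_missing(row.importance_0to3) else row.importance_0to3
    return ExpertRatingMatrix(raters=raters, domains=domains, relevance=rel, importance=imp)
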