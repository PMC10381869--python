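"""End-to-end validation pipeline.

``run_validation`` scores a cohort, then assembles the three analysis blocks
of a convergent/discriminant validity study:

* descriptive statistics per instrument;
* the Spearman correlation matrix across the six instruments (convergent
  validity — SF-36 PCS is inverse-coded, so its correlations come out
  negative);
* ROC analyses per instrument with the MDA criterion as external standard
  (discriminant validity; the positive class is the *active*, non-MDA state,
  and the SF-36 column is negated before the ROC so that higher predicts
  active for every instrument);
* MDA-stratified contrasts of the five thermometer subscales
  (median per group, Kruskal-Wallis p).

The report is deterministic given the cohort and configuration, and invariant
to record order.  Records with incomplete inputs are excluded as complete
cases; the exclusion count is always reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .records import MissingDataError, PatientRecord
from .scoring import CpdaiGrid, score_panel
from .validation_stats import (
    SingleClassError,
    auc_band,
    correlation_matrix,
    describe,
    group_compare,
    roc,
)

__all__ = ["ValidationReport", "run_validation", "INSTRUMENTS", "REPORT_SCHEMA_VERSION"]

logger = logging.getLogger("psa5ts")

REPORT_SCHEMA_VERSION = "1"

#: Instrument display names mapped to score-panel columns.  SF-36 enters the
#: analyses through its physical component summary.
INSTRUMENTS = {
    "DAPSA": "dapsa",
    "CPDAI": "cpdai",
    "PASDAS": "pasdas",
    "PsA-5Ts": "psa5ts",
    "PsAID-12": "psaid12",
    "SF-36": "pcs",
}

#: Instruments whose scale is inverse-coded (higher = better health); these
#: are negated before the ROC so every AUC is read in the same orientation.
INVERSE_CODED = ("SF-36",)

_SUBSCALES = ("pain", "fatigue", "physical_function", "skin_problems", "depression")


@dataclass
class ValidationReport:
    """Machine-readable analog of the study's result tables."""

    descriptives: dict  # instrument -> DescriptiveSummary as dict
    correlations: list  # [{a, b, rho, p, band, n}, ...]
    roc: dict  # instrument -> {auc, se, ci95, band, n_pos, n_neg}
    subscales: dict  # thermometer -> {median_mda, median_active, p, test}
    metadata: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True, default=_jsonify)

    def write(self, outdir) -> None:
        """Emit report.json plus CSV tables mirroring the study's layout."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        pd.DataFrame(self.descriptives).to_csv(out / "descriptives.csv")
        pd.DataFrame(self.correlations).round(
            {"rho": 3, "p": 4}
        ).to_csv(out / "correlations.csv", index=False)
        roc_rows = [
            {
                "instrument": name,
                "auc": round(r["auc"], 3),
                "se": round(r["se"], 3),
                "ci95_low": round(r["ci95"][0], 3),
                "ci95_high": round(r["ci95"][1], 3),
                "band": r["band"],
            }
            for name, r in self.roc.items()
        ]
        pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False)
        sub_rows = [{"subscale": k, **v} for k, v in self.subscales.items()]
        pd.DataFrame(sub_rows).to_csv(out / "subscales.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.ndarray, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(grid: Optional[CpdaiGrid], pasdas_global_scale: str) -> str:
    payload = json.dumps(
        {"grid": repr(grid), "pasdas_global_scale": pasdas_global_scale},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_validation(
    cohort: Iterable[PatientRecord],
    *,
    grid: Optional[CpdaiGrid] = None,
    pasdas_global_scale: str = "vas100",
    seed: Optional[int] = None,
) -> ValidationReport:
    """Score a cohort and assemble the full validity report.

    Raises :class:`SingleClassError` when every complete record falls on the
    same side of the MDA criterion (the external criterion then cannot anchor
    a discriminant analysis).
    """
    panels = []
    kept_records = []
    n_excluded = 0
    for i, rec in enumerate(cohort):
        try:
            panels.append(score_panel(rec, grid=grid, pasdas_global_scale=pasdas_global_scale))
            kept_records.append(rec)
        except MissingDataError as exc:
            n_excluded += 1
            logger.warning("record %s excluded: %s", rec.patient_id or f"#{i}", exc)
    if not panels:
        raise ValueError("no complete records to analyse")

    scores = pd.DataFrame(
        {name: [getattr(p, col) for p in panels] for name, col in INSTRUMENTS.items()},
        dtype=float,
    )
    # stable case order so the report is invariant to input row order
    order = np.lexsort(
        [scores[c].to_numpy() for c in reversed(list(scores.columns))]
    )
    scores = scores.iloc[order].reset_index(drop=True)
    panels = [panels[i] for i in order]

    mda_flags = np.array([p.mda.verdict for p in panels])
    active = ~mda_flags  # ROC positive class: active (non-MDA) patients
    if active.all() or not active.any():
        raise SingleClassError(
            "MDA criterion: every complete record is in the same class "
            f"({'active' if active.all() else 'MDA'})"
        )

    descriptives = {name: asdict(describe(scores[name])) for name in INSTRUMENTS}

    corr = correlation_matrix(scores)
    corr_cells = [
        {"a": a, "b": b, **asdict(corr.loc[a, b])}
        for i, a in enumerate(corr.index)
        for b in corr.columns[i + 1:]
    ]

    roc_block = {}
    for name in INSTRUMENTS:
        col = scores[name].to_numpy()
        oriented = -col if name in INVERSE_CODED else col
        r = roc(oriented, active)
        roc_block[name] = {
            "auc": r.auc,
            "se": r.se,
            "ci95": list(r.ci95),
            "band": auc_band(max(r.auc, 0.5)),
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
        }

    subscales = {}
    for item in _SUBSCALES:
        vals = np.array([getattr(rec.thermometers, item) for rec in kept_records])[order]
        cmp = group_compare(vals, np.where(mda_flags, "mda", "active"), force="kruskal")
        subscales[item] = {
            "median_mda": float(np.median(vals[mda_flags])),
            "median_active": float(np.median(vals[~mda_flags])),
            "statistic": cmp["statistic"],
            "p": cmp["p"],
            "test": cmp["test"],
        }

    if n_excluded:
        logger.warning("%d record(s) excluded from the complete-case analysis", n_excluded)

    metadata = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n": int(len(panels)),
        "n_excluded": int(n_excluded),
        "n_mda": int(mda_flags.sum()),
        "seed": seed,
        "config_hash": _config_hash(grid, pasdas_global_scale),
    }
    return ValidationReport(
        descriptives=descriptives,
        correlations=corr_cells,
        roc=roc_block,
        subscales=subscales,
        metadata=metadata,
    )
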