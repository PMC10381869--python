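"""Seeded synthetic PsA cohort generator.

The validation analyses assume a particular statistical structure: a cohort
mixing a minority of near-remission patients with a majority of active ones,
with a single underlying severity driving correlated responses across every
instrument (which is why the composite indices intercorrelate strongly, the
score distributions are bimodal, and every index discriminates MDA status).
The generator reproduces exactly that structure:

* a two-component latent-severity mixture (low-activity weight 0.22, the
  observed MDA prevalence in the development cohort);
* each raw input ``x = location + scale * loading * z + noise``, a
  one-factor model with per-input loadings in [0, 1], then mapped onto its
  instrument scale (counts by rounding and truncation, bounded scales by
  clipping; SF-36 summaries load negatively, encoding their inverse coding);
* marginal targets (mean/SD per input) taken from the development cohort's
  descriptive table; channel locations are calibrated analytically
  (mixture-normal expectations, root-finding) so the post-transform means hit
  the targets.  SDs are matched through the pre-transform scale and can
  shrink where a bound truncates a wide target (notably the 0-6 enthesitis
  count).

MDA class labels are *not* the mixture component: downstream analyses apply
:func:`psa5ts.scoring.classify_mda` to the generated records, so the external
criterion is exactly the clinical one.  The low-activity component is
parameterized so that most of its draws satisfy the MDA criteria.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .records import (
    PSAID_COLUMNS,
    THERMOMETER_COLUMNS,
    PatientRecord,
    PsaidResponses,
    ThermometerResponses,
    write_cohort,
)

__all__ = [
    "GeneratorConfigError",
    "InputChannel",
    "GeneratorConfig",
    "SyntheticCohort",
    "default_config",
    "generate",
]


class GeneratorConfigError(ValueError):
    """The generator configuration is invalid or its targets are infeasible."""


@dataclass(frozen=True)
class InputChannel:
    """Marginal target and factor loading for one raw input.

    ``mean``/``sd`` are the target marginal moments (pre-truncation scale);
    ``loading`` is the correlation of the input with the latent severity;
    ``noise_sd`` defaults to ``sd * sqrt(1 - loading**2)`` so the marginal SD
    equals ``sd``.  ``kind`` is ``'count'`` (round + clip to integers) or
    ``'scale'`` (clip, then round to ``step``).  ``inverse`` channels load
    negatively (higher severity, lower value)."""

    mean: float
    sd: float
    loading: float
    kind: str  # 'count' | 'scale'
    lo: float
    hi: Optional[float]
    step: Optional[float] = None
    inverse: bool = False
    noise_sd: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.loading <= 1:
            raise GeneratorConfigError(f"loading must be in [0, 1], got {self.loading}")
        if self.sd <= 0:
            raise GeneratorConfigError("sd must be positive")
        if self.kind not in ("count", "scale"):
            raise GeneratorConfigError(f"kind must be 'count' or 'scale', got {self.kind!r}")

    @property
    def effective_noise(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return self.sd * math.sqrt(1 - self.loading**2)


def _default_channels() -> dict:
    """Default per-input targets.

    Counts, CRP, PASI, HAQ and the SF-36 PCS use the development cohort's
    published means/SDs; the NRS items (not tabulated there) use values
    consistent with the published composite means.  PsAID item SDs are set to
    a realistic 2.6 rather than backing them out of the published PsAID-12 SD,
    which is internally inconsistent with its own median/IQR.
    """
    ch = {
        "tjc68": InputChannel(6.73, 6.66, 0.95, "count", 0, 68),
        "sjc66": InputChannel(3.71, 3.87, 0.95, "count", 0, 66),
        "crp": InputChannel(3.62, 2.95, 0.60, "scale", 0, None, 0.01),
        "lei": InputChannel(1.41, 3.38, 0.80, "count", 0, 6),
        "dactylitis_count": InputChannel(2.19, 2.42, 0.70, "count", 0, 20),
        "pasi": InputChannel(5.41, 5.09, 0.90, "scale", 0, 72, 0.1),
        "haq": InputChannel(1.08, 0.70, 0.90, "scale", 0, 3, 0.125),
        "pain_nrs": InputChannel(4.10, 2.60, 0.95, "scale", 0, 10, 0.1),
        "ptga": InputChannel(4.20, 2.60, 0.95, "scale", 0, 10, 0.1),
        "phga": InputChannel(3.80, 2.40, 0.85, "scale", 0, 10, 0.1),
        "gh": InputChannel(45.0, 22.0, 0.70, "scale", 0, 100, 1.0),
        "pcs": InputChannel(41.14, 9.55, 0.70, "scale", 5, 75, 0.01, inverse=True),
        "mcs": InputChannel(45.0, 11.0, 0.40, "scale", 5, 75, 0.01, inverse=True),
        "basdai": InputChannel(4.50, 2.20, 0.70, "scale", 0, 10, 0.1),
        "comorbidity_count": InputChannel(2.61, 1.91, 0.20, "count", 0, 12),
        "t_pain": InputChannel(3.94, 2.28, 0.90, "scale", 0, 10, 0.1),
        "t_fatigue": InputChannel(3.94, 2.28, 0.85, "scale", 0, 10, 0.1),
        "t_physical_function": InputChannel(3.94, 2.28, 0.85, "scale", 0, 10, 0.1),
        "t_skin_problems": InputChannel(3.94, 2.28, 0.85, "scale", 0, 10, 0.1),
        "t_depression": InputChannel(3.94, 2.28, 0.80, "scale", 0, 10, 0.1),
    }
    for i, col in enumerate(PSAID_COLUMNS, start=1):
        loading = 0.85 if i == 1 else 0.80
        ch[col] = InputChannel(4.90, 2.60, loading, "scale", 0, 10, 0.1)
    return ch


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings.

    The latent severity is a two-component Gaussian mixture, standardized so
    the default overall mean/variance are 0/1: the low-activity component
    sits at -1.55 (SD 0.35) with weight ``prev_lowactivity`` and the active
    component at +0.437 (SD 0.616).  Scaling both component means apart
    increases every instrument's class separation.
    """

    n: int = 155
    prev_lowactivity: float = 0.22
    seed: int = 0
    axial_prev: float = 0.30
    latent_low: tuple = (-1.55, 0.35)
    latent_active: tuple = (0.437, 0.616)
    channels: dict = field(default_factory=_default_channels)
    sf36_inverse: bool = True

    def __post_init__(self):
        if self.n < 10:
            raise GeneratorConfigError(f"n must be >= 10, got {self.n}")
        if not 0 < self.prev_lowactivity < 1:
            raise GeneratorConfigError("prev_lowactivity must be in (0, 1)")
        if not 0 <= self.axial_prev <= 1:
            raise GeneratorConfigError("axial_prev must be in [0, 1]")
        for name, ch in self.channels.items():
            if not isinstance(ch, InputChannel):
                raise GeneratorConfigError(f"channel {name!r} is not an InputChannel")

    def with_separation(self, factor: float) -> "GeneratorConfig":
        """Scale the distance between the latent mixture components."""
        lo_m, lo_s = self.latent_low
        hi_m, hi_s = self.latent_active
        return replace(
            self,
            latent_low=(lo_m * factor, lo_s),
            latent_active=(hi_m * factor, hi_s),
        )


def default_config(n: int = 155, seed: int = 0, prev: float = 0.22) -> GeneratorConfig:
    """The study-condition defaults (n = 155, low-activity weight 0.22)."""
    return GeneratorConfig(n=n, seed=seed, prev_lowactivity=prev)


@dataclass
class SyntheticCohort:
    """Generated records plus the generating truth (component and latent)."""

    records: list
    truth: pd.DataFrame  # columns: patient_id, component, latent, axial
    config: GeneratorConfig

    def write_csv(self, path) -> None:
        write_cohort(self.records, path)


# ---------------------------------------------------------------------------
# Location calibration
# ---------------------------------------------------------------------------

def _post_transform_mean(ch: InputChannel, components) -> float:
    """Expected value after the scale transform, given mixture-normal
    pre-transform components ``[(weight, mean, sd), ...]``."""
    total = 0.0
    for w, m, s in components:
        if ch.kind == "count":
            hi = int(ch.hi) if ch.hi is not None else int(math.ceil(m + 12 * s))
            ks = np.arange(1, hi + 1)
            e = float(norm.sf((ks - 0.5 - m) / s).sum())
        else:
            lo, hi = ch.lo, ch.hi
            alpha = (lo - m) / s
            if hi is None:
                e = lo * norm.cdf(alpha) + m * norm.sf(alpha) + s * norm.pdf(alpha)
            else:
                beta = (hi - m) / s
                e = (
                    lo * norm.cdf(alpha)
                    + hi * norm.sf(beta)
                    + m * (norm.cdf(beta) - norm.cdf(alpha))
                    - s * (norm.pdf(beta) - norm.pdf(alpha))
                )
        total += w * e
    return total


def _calibrated_location(ch: InputChannel, cfg: GeneratorConfig) -> float:
    """Solve for the channel location such that the post-transform marginal
    mean equals the channel's target mean."""
    sign = -1.0 if (ch.inverse and cfg.sf36_inverse) else 1.0
    slope = ch.sd * ch.loading * sign
    noise = ch.effective_noise
    p = cfg.prev_lowactivity
    comps = [
        (p, slope * cfg.latent_low[0], math.hypot(slope * cfg.latent_low[1], noise)),
        (1 - p, slope * cfg.latent_active[0], math.hypot(slope * cfg.latent_active[1], noise)),
    ]

    def gap(delta):
        return (
            _post_transform_mean(ch, [(w, delta + m, max(s, 1e-9)) for w, m, s in comps])
            - ch.mean
        )

    span = 10 * ch.sd + abs(ch.mean) + 1
    try:
        return brentq(gap, ch.mean - span, ch.mean + span, xtol=1e-8)
    except ValueError as exc:
        raise GeneratorConfigError(
            f"marginal target mean {ch.mean} is infeasible for this channel "
            f"(bounds [{ch.lo}, {ch.hi}])"
        ) from exc


def _transform(ch: InputChannel, raw: np.ndarray) -> np.ndarray:
    if ch.kind == "count":
        out = np.rint(raw)
    else:
        out = raw if ch.step is None else np.round(raw / ch.step) * ch.step
    hi = np.inf if ch.hi is None else ch.hi
    return np.clip(out, ch.lo, hi)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(config: Optional[GeneratorConfig] = None) -> SyntheticCohort:
    """Draw one synthetic cohort; bit-identical for identical config."""
    cfg = config if config is not None else default_config()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    low = rng.random(n) < cfg.prev_lowactivity
    u = rng.standard_normal(n)
    mu = np.where(low, cfg.latent_low[0], cfg.latent_active[0])
    sd = np.where(low, cfg.latent_low[1], cfg.latent_active[1])
    z = mu + sd * u
    axial = rng.random(n) < cfg.axial_prev

    values = {}
    for name, ch in cfg.channels.items():  # insertion order fixes the stream
        sign = -1.0 if (ch.inverse and cfg.sf36_inverse) else 1.0
        eps = rng.standard_normal(n)
        loc = _calibrated_location(ch, cfg)
        raw = loc + ch.sd * ch.loading * sign * z + ch.effective_noise * eps
        values[name] = _transform(ch, raw)

    records = []
    for i in range(n):
        def v(name):
            return float(values[name][i]) if name in values else None

        thermometers = ThermometerResponses(*(v(c) for c in THERMOMETER_COLUMNS))
        psaid = PsaidResponses(*(v(c) for c in PSAID_COLUMNS))
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                tjc68=int(values["tjc68"][i]),
                sjc66=int(values["sjc66"][i]),
                crp=v("crp"),
                lei=int(values["lei"][i]),
                dactylitis_count=int(values["dactylitis_count"][i]),
                pasi=v("pasi"),
                haq=v("haq"),
                pain_nrs=v("pain_nrs"),
                ptga=v("ptga"),
                phga=v("phga"),
                gh=v("gh"),
                pcs=v("pcs"),
                mcs=v("mcs"),
                basdai=v("basdai") if axial[i] else None,
                thermometers=thermometers,
                psaid=psaid,
                comorbidity_count=int(values["comorbidity_count"][i]),
            )
        )

    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "component": np.where(low, "low", "active"),
            "latent": z,
            "axial": axial,
        }
    )
    return SyntheticCohort(records=records, truth=truth, config=cfg)
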