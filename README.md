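# psa5ts

Composite disease-activity and patient-reported-outcome (PRO) scoring for
psoriatic arthritis (PsA), built around the **PsA-5Ts** five-thermometer
composite, together with the content-validity computations that produced the
instrument and the statistical pipeline used to validate it.

It is aimed at clinimetrics researchers and rheumatology trialists who need
reproducible implementations of the standard PsA indices, a transparent
Delphi/Lynn item-reduction calculator, and a convergent/discriminant validity
workflow that can be exercised end-to-end on synthetic cohorts — no patient
data required.

## What it computes

**Instrument scores** (module `psa5ts.scoring`), each from a validated
`PatientRecord`:

- **PsA-5Ts** — five 0–10 thermometer scales (pain, fatigue, physical
  function, skin problems, depression) combined as
  `3·pain + 2·fatigue + 2·function + 2·skin + 1·depression`, a 0–100 score.
- **DAPSA** = TJC68 + SJC66 + pain NRS + PtGA + CRP (mg/dL), banded at
  ≤4 / ≤14 / ≤28 (REM / LDA / MDA / HDA).
- **PASDAS** — the published regression equation
  `(0.18√PhGA + 0.159√PtGA − 0.253√PCS + 0.101 ln(SJC+1) + 0.048 ln(TJC+1)
  + 0.23 ln(LEI+1) + 0.377 ln(dact+1) + 0.102 ln(CRP+1) + 2) × 1.5`
  with globals on the 0–100 VAS (configurable).
- **CPDAI** — five domains (arthritis, skin, enthesitis, dactylitis, spine)
  each graded 0–3 by a configurable cut-off grid, total 0–15.
- **PsAID-12** — twelve 0–10 items weighted 3,2,2,2,2,2,2,1,1,1,1,1 and
  divided by 20, banded at ≤1.4 / ≤4.1 / ≤6.7.
- **MDA criteria** — minimal disease activity: at least 5 of
  {TJC ≤ 1, SJC ≤ 1, PASI ≤ 1, pain ≤ 1.5, PtGA ≤ 2, HAQ ≤ 0.5, LEI ≤ 1}.
- Supporting instruments: LEI (0–6), PASI (0–72 from per-region grades) and
  HAQ (8-category max-then-mean, 0–3).

**Content validity** (`psa5ts.content_validity`): CVI (proportion of experts
rating a domain 2–4 on Lynn's 1–4 relevance scale), mean importance (0–3
scale), the Frequency Importance Product `FIP = 100 · CVI · mean importance`,
the adequate/questionable/unacceptable bands (≥88% / 70–88% / ≤69%) and the
retention rule (CVI > 69% and mean importance ≥ 2.0). The development
panel's summary table ships with the package.

**Validation statistics** (`psa5ts.validation_stats`): Spearman correlations
with interpretation bands, ROC analysis with the tie-corrected Mann–Whitney
AUC, Hanley–McNeil standard errors and exact-binomial-shaped confidence
intervals, DeLong's paired AUC comparison, Mann–Whitney / Kruskal–Wallis /
chi-square group contrasts, and full descriptive panels including an exact
order-statistic confidence interval for the median.

**Synthetic cohorts** (`psa5ts.cohort`): a seeded one-factor latent-severity
generator with a two-component (low-activity / active) mixture, calibrated
to the development cohort's marginal means, that reproduces the qualitative
validity structure — bimodal score distributions, strong positive
intercorrelations, negative SF-36 correlations, and high MDA discrimination.

## Worked example

```bash
psa5ts synth --n 155 --seed 1 --prev 0.22 --out cohort.csv
psa5ts validate --in cohort.csv --out report/
```

prints nothing on success and writes `report/report.json` plus CSV tables.
For this seed the discriminant-validity block is:

```
DAPSA:    AUC 1.000 (SE 0.001, 95% CI 0.983-1.000) high
CPDAI:    AUC 0.996 (SE 0.004, 95% CI 0.976-1.000) high
PASDAS:   AUC 0.998 (SE 0.003, 95% CI 0.981-1.000) high
PsA-5Ts:  AUC 0.992 (SE 0.006, 95% CI 0.970-0.999) high
PsAID-12: AUC 0.999 (SE 0.003, 95% CI 0.981-1.000) high
SF-36:    AUC 0.839 (SE 0.033, 95% CI 0.762-0.899) useful
```

Each AUC is the probability that a randomly drawn *active* (non-MDA) patient
scores above a randomly drawn MDA patient on that instrument; of 155
generated patients, 33 met the MDA criteria here. Every composite index
discriminates strongly, the generic SF-36 least — the ordering expected of a
disease-specific instrument. The convergent-validity block shows the same
sign structure (PsA-5Ts vs DAPSA rho = 0.919, vs PsAID-12 rho = 0.903, vs
SF-36 rho = −0.564, negative because SF-36 is inverse-coded).

The content-validity table behind the instrument's five thermometers:

```bash
psa5ts delphi
```

```
 rank              domain  cvi  mean_importance    fip         band  retained
    1                pain 0.98             2.93 287.14     adequate      True
    2             fatigue 0.90             2.16 194.40     adequate      True
    3 functional capacity 0.88             2.18 191.84     adequate      True
    4       skin problems 0.87             2.20 191.40 questionable      True
    5     depressive mood 0.71             2.01 142.71 questionable      True
    ...
```

Five of the seventeen candidate domains survive the reduction (CVI > 69%,
mean importance ≥ 2.0); the remaining twelve are eliminated.

## Layout

- `src/psa5ts/records.py` — data containers, cohort CSV I/O
- `src/psa5ts/scoring.py` — all instrument scores and bands
- `src/psa5ts/content_validity.py` — CVI / FIP / retention / ranking
- `src/psa5ts/validation_stats.py` — correlations, ROC, group contrasts
- `src/psa5ts/cohort.py` — synthetic cohort generator
- `src/psa5ts/pipeline.py`, `src/psa5ts/cli.py` — end-to-end report and CLI
- `docs/methods.md` — models, assumptions, numerical choices
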