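# pvsignal

Pharmacovigilance signal detection and time-to-onset modelling for
FAERS-style spontaneous reporting data.

`pvsignal` is a tested, reusable implementation of the standard
disproportionality workflow applied to the FDA Adverse Event Reporting
System (FAERS), built around the safety profile of pentosan polysulfate
sodium (PPS, ELMIRON) — a drug whose reports are heavily female-skewed and
dominated by long-latency retinal toxicity — but usable for any suspect
drug given a synonym list. It is aimed at pharmacoepidemiologists and
biostatisticians who want the full pipeline (ingestion, deduplication,
signal statistics, sex-difference screening, outcome seriousness, onset
modelling) as composable, unit-tested library code rather than ad-hoc SAS
or spreadsheet steps.

Because the raw FAERS quarterly extracts are large and MedDRA is licensed,
the package ships a synthetic FAERS generator with known, configurable
statistical structure (injected drug–event multipliers, sex-differential
reporting, duplicated case versions, missing/partial dates,
Weibull-distributed onsets). Every downstream stage is validated against
that generator's ground truth.

## What it computes

For a target drug and each adverse-event preferred term (PT), the
case-level 2×2 table against the all-other-drugs comparator

|                 | target AE | other AE |
|-----------------|-----------|----------|
| target drug     | a         | b        |
| all other drugs | c         | d        |

gives the reporting odds ratio **ROR = ad/bc** with Wald 95% CI
`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`, the proportional reporting ratio
**PRR = [a/(a+b)]/[c/(c+d)]**, and the Pearson χ². A PT is a *signal*
when jointly a ≥ 3, the ROR CI lower bound exceeds 1, and PRR ≥ 2 with
χ² ≥ 4. Zero cells get the Haldane–Anscombe +0.5 correction. The same
machinery applied female-vs-male within the target drug's reports, with
Benjamini–Hochberg FDR control, yields sex-differential signals and
volcano-plot coordinates.

Time to onset (TTO = EVENT_DT − earliest START_DT, in days; missing,
partial or negative intervals excluded) is summarized by the Kaplan–Meier
estimator and by maximum-likelihood Weibull, log-normal and log-logistic
fits compared via AIC/BIC and the Anderson–Darling statistic. The Weibull
shape β classifies the hazard regime: β < 1 with CI above-bound < 1 is a
decreasing hazard (early-failure pattern), β > 1 with CI lower bound > 1
an increasing one.

## Worked example

```python
import pvsignal as pv
from pvsignal.faers_io import target_caseids

cfg = pv.SimulationConfig(n_reports=20_000, seed=1)   # default study conditions
cases = pv.assemble_cases(pv.generate(cfg), restrict=False)
ids = target_caseids(cases, [cfg.target_drug])

res = pv.DisproportionalityModel(cases, ids, pt_to_soc=dict(cfg.pt_catalog)).fit()
print(res.summary(5))
```

```
Disproportionality screen: 1016 target cases, 20000 cases total, 30 PTs (7 signals)
                    pt                                    soc   a  reporting_pct   ror  ror_low  ror_high   prr    chi2  is_signal
           Maculopathy                          Eye disorders 327          32.19 21.24    18.03     25.01 14.72 2429.46       True
Pigmentary maculopathy                          Eye disorders 301          29.63 19.51    16.51     23.06 14.03 2155.56       True
              Alopecia Skin and subcutaneous tissue disorders 105          10.33  2.36     1.91      2.92  2.22   66.33       True
  Retinal pigmentation                          Eye disorders  88           8.66 12.67     9.63     16.67 11.66  534.26       True
            Depression                  Psychiatric disorders  68           6.69  1.57     1.22      2.03  1.53   12.18      False
```

The injected ocular signals dominate (maculopathy in 32% of target cases,
ROR ≈ 21 with CI well above 1); depression, with PRR below 2, correctly
fails the joint criteria. Continuing with the target-drug cases only:

```python
tgt = [c for c in cases if c.caseid in ids]
print(pv.SexDifferenceModel(tgt).fit().summary())
print(pv.TimeToOnsetModel.from_cases(tgt, [cfg.target_drug]).fit().summary())
```

```
Sex-difference screen: 883 female / 84 male cases, 30 PTs tested, 4 significant at FDR 0.05
                         pt  a_f  c_m    ror     low   high    p_adj direction
                Maculopathy  309    7  5.922   2.698     13 0.000276    female
     Pigmentary maculopathy  283    9  3.931   1.941  7.961 0.002157    female
       Abdominal discomfort   21    8 0.2314 0.09917 0.5401 0.007124      male
Urinary bladder haemorrhage    7    4 0.1598  0.0458 0.5576   0.0302      male

Time-to-onset analysis: n = 253 included events
  median 1422 d, IQR 383-4906 d
  latency bins: <=30d 11 (4.3%), 31-365d 48 (19.0%), >365d 194 (76.7%)
     family     scale  shape       loglik         aic         bic  ad_stat     mu  sigma
    weibull 2898.0522 0.6175 -2304.832485 4613.664971 4620.731750 0.454526    NaN    NaN
loglogistic 1322.4320 0.9334 -2311.546988 4627.093976 4634.160755 0.856995    NaN    NaN
  lognormal       NaN    NaN -2313.558906 4631.117813 4638.184592 1.333701 7.0729 1.9207
  best by AIC: weibull
  Weibull shape = 0.62 (95% CI 0.56-0.68) -> hazard decreasing/early-failure
```

The maculopathy terms come out female-skewed and the gastrointestinal /
bladder terms male-skewed — the configured sex-differential pattern — and
the Weibull model (the generating family, shape 0.62) wins the AIC
comparison with a decreasing-hazard classification.

The same run is available from the shell:

```bash
pvsignal run-all --out run1 --seed 1          # writes CSVs + manifest.json
pvsignal simulate --out data --seed 1         # just the ASCII tables
pvsignal ingest --data-dir data --out cases.csv --all-cases
```

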