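# lgiscore

Analysis pipeline for the **low-grade inflammation (LGI) score** in acute
ischemic stroke: a composite of four routine admission blood markers —
C-reactive protein (CRP), the leukocyte count (WBC), the platelet count
(PLT), and the neutrophil/lymphocyte ratio (NLR = neutrophils /
lymphocytes). It is aimed at clinical epidemiologists who want a tested,
reproducible implementation of decile-based composite scoring, stroke
endpoint derivation, quartile logistic association models, and
added-predictive-value statistics — together with a synthetic cohort
generator so the whole pipeline can be exercised and validated without
access to registry data.

## The score and the analysis

Each marker is ranked within the analyzed cohort and assigned a decile via
mid-ranks: observation *i* with mid-rank *r<sub>i</sub>* in a cohort of *n*
falls in decile ⌈10·*r<sub>i</sub>*/*n*⌉. Deciles map to per-marker scores

| decile | 1 | 2 | 3 | 4 | 5 | 6 | 7 | 8 | 9 | 10 |
|--------|---|---|---|---|---|---|---|---|---|----|
| score  | −4| −3| −2| −1| 0 | 0 | 1 | 2 | 3 | 4  |

and the LGI score is the sum over the four markers, ranging −16…16; higher
means more intense low-grade inflammation.

Downstream, the pipeline derives stroke endpoints (severity: NIHSS > 5 at
baseline and day 7; early neurological deterioration END: NIHSS rise ≥ 2
points within 7 days; 90-day outcome: excellent mRS 0–1 vs poor mRS 2–6),
fits logistic models of each endpoint on LGI-score quartiles (crude;
model 1: + gender, age; model 2: + vascular risk factors, and baseline
NIHSS for the 90-day outcome) with Wald ORs/CIs and a p-for-trend, runs
stratified analyses with likelihood-ratio interaction tests, and
quantifies the score's added value over a conventional model (age +
baseline NIHSS) via AUC with DeLong intervals, the continuous net
reclassification improvement (NRI) and the integrated discrimination
improvement (IDI).

## Worked example

```bash
lgiscore simulate --n 876 --seed 42 --out cohort.csv
lgiscore run --input cohort.csv --out rep
```

This writes `rep/` with `scored.csv`, `table1.json`, `associations.jsonl`,
`stratified.jsonl`, `discrimination.json`, `roc_curve.csv` and
`run_log.json`. On this seed the synthetic cohort yields (from
`run_log.json`, `associations.jsonl` and `discrimination.json`):

```
LGI quartile cuts:        Q1 <= -5, Q2 <= 0, Q3 <= 4, Q4 > 4
Spearman LGI ~ NIHSS:     rho = 0.271, p = 3.4e-16
poor 90-day outcome, Q4 vs Q1:
  crude    OR 3.12 (2.01, 4.85), p for trend 3.9e-09
  model 1  OR 3.31 (2.12, 5.18), p for trend 1.0e-09
  model 2  OR 2.04 (1.25, 3.32), p for trend 8.7e-04
AUC (LGI score alone)     0.641 (0.599, 0.682)
AUC conventional / add-on 0.762 / 0.771
continuous NRI            0.206, p = 0.006
IDI                       0.0156, p = 0.0006
```

Read: patients in the top inflammation quartile have about three times the
odds of a poor 90-day outcome of the bottom quartile, attenuating to ~2
after full adjustment; adding the LGI score to age + NIHSS nudges the
C-statistic upward and significantly improves reclassification — the same
qualitative pattern the score shows on real registry data.

The same steps are available as a library:

```python
from lgiscore import CohortConfig, generate_cohort, records_to_frame
from lgiscore import LGIScorer, add_endpoint_columns, compare_models

df = records_to_frame(generate_cohort(CohortConfig(n_patients=876, seed=42)))
scored = add_endpoint_columns(LGIScorer().fit(df).transform(df))
report = compare_models(scored, outcome="poor_90d")
print(report.continuous_nri.value, report.idi.value)
```

`LGIScorer`, `QuartileLogisticModel` and `AddedValueComparison` follow
scikit-learn estimator conventions (`fit`/`transform`, `get_params`,
trailing-underscore fitted attributes) and compose with sklearn tooling.

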