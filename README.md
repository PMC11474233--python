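# akiplanner

Decision support for cardiac anesthesiologists: recommend intraoperative
anesthesia parameters that carry a low risk of postoperative **acute
kidney injury (AKI)**, and quantify how risky any physician-chosen plan
is.

AKI is one of the most common complications after open-heart surgery, and
several of its drivers — cardiopulmonary bypass (CPB) time, fluid and
transfusion management, diuretic dosing — are anesthetic choices.
`akiplanner` implements a dual-regression approach:

- the **AKI− Planner**, a feed-forward regression network trained only on
  patients who stayed injury-free, maps eight preoperative features
  (age, BMI, CCB use, creatinine, albumin, blood sugar, HbA1C,
  hematocrit) to the six intraoperative parameters (anesthesia time, CPB
  time, diuretic dose, crystalloid dose, PC and FFP transfusion) such a
  patient typically received — a patient-specific *low-risk prototype*;
- the **AKI+ Planner**, identically structured but trained on patients who
  developed AKI (KDIGO stage ≥ 1 on postoperative day 1 or 7, staged from
  serum creatinine), yields the *high-risk prototype* to keep a safety
  margin from.

A proposed plan **t** is placed at the point
(d₋, d₊) = (‖z(t) − z(f₋(x))‖, ‖z(t) − z(f₊(x))‖) of standardized
distances to the two prototypes. Plans on or below the y = x line
(d₊ ≤ d₋, nearer the high-risk prototype) are classified **AKI-risky**;
the *safety margin* d₊ − d₋ ranks candidate plans, and the recommender
returns the highest-margin settings inside a physician-specified slider
box. The package also ships KDIGO creatinine staging, a stratified 85/15
splitter, gradient-boosted feature ranking, k-means candidate treatments
with majority-vote scaffolding for expert panels, and a seeded synthetic
cohort generator that reproduces the published 998-patient cohort's
marginal structure (the original dataset is not public). See
`docs/methods.md` for the model details.

## Worked example

```python
from akiplanner import run_pipeline, recommend

res = run_pipeline()  # generate 998 patients, label, split 85/15, train, evaluate
print(res.report_test.to_dict())
```

```
{'confusion': {'TP': 74, 'FP': 4, 'FN': 4, 'TN': 69}, 'n': 151,
 'rounding_mode': 'truncate',
 'precision': 0.948, 'recall': 0.948, 'accuracy': 0.947, 'f1': 0.948}
```

On the default synthetic cohort — AKI+ and AKI− plan means separated by
1 SD per parameter — classifying each held-out patient's administered plan
by the y = x rule recovers the true outcome for 94.7% of test patients
(74 true AKI+, 69 true AKI−, 4 errors each way). For one patient (a
66-year-old with creatinine 1.96 mg/dL and blood sugar 212 mg/dL), the two
planners and the recommender give:

```python
x = res.cohort[res.model_minus.feature_names].iloc[0].to_numpy()
res.model_minus.predict_plan(x).to_dict()
# {'AnesthesiaTime': 302.6, 'CPBTime': 96.4, 'DiureticDose': 32.3,
#  'CrystalloidDose': 1.23, 'PC': 0.36, 'FFP': 0.51}   <- low-risk prototype
res.model_plus.predict_plan(x).to_dict()
# {'AnesthesiaTime': 407.2, 'CPBTime': 138.3, 'DiureticDose': 57.8,
#  'CrystalloidDose': 1.77, 'PC': 0.73, 'FFP': 0.56}   <- high-risk prototype
recommend(x, res.model_minus, res.model_plus, res.plan_scaler, seed=0).head(1)
#  AnesthesiaTime  CPBTime  DiureticDose  CrystalloidDose   PC  FFP  d_minus  d_plus  margin risk_tag
#          302.57    96.41         32.29             1.23 0.36 0.51      0.0   3.046   3.046 low-risk
```

The top recommendation is the AKI− Planner's own proposal (d₋ = 0; its
margin, 3.05, is the full prototype separation — provably maximal), and
for this high-creatinine patient it means shorter anesthesia/CPB times,
less diuretic and less fluid than the high-risk prototype. k-means on the
training plans (`res.clusters`) yields three candidate treatments — two
low-risk, one high-risk — mirroring how survey options are built for
expert review.

The same stages are available as a CLI:

```bash
akiplanner cohort --n 998 --seed 7 --out cohort.csv
akiplanner run --seed 7 --outdir out/          # full pipeline + artifacts
akiplanner recommend --patient patient.json --neg out/planner_neg.json \
    --pos out/planner_pos.json --train-csv out/labeled.csv --grid 2000 --seed 7
```

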