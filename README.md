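# ruleout

Cost-consequence decision modelling for **rule-out triage tests** placed
before an invasive confirmatory procedure.

The motivating application is the Prostate Health Index (PHI), a blood
test combining total PSA, free PSA and [−2]proPSA, proposed as a
rule-out test before TRUS prostate biopsy for men with PSA 4–10 ng/ml
and a normal digital rectal examination. Biopsy is expensive and
carries an adverse-event cascade (A&E attendance, sometimes
hospitalisation); positive biopsy rates in this population are low, so
a test that safely rules men out can avoid cost and harm — at the price
of some missed (delayed) cancer diagnoses. The package evaluates that
trade-off for any such setting, and ships the Hong Kong PHI cohort and
costs as its built-in example.

## The model

Two strategies are compared as expected cost per eligible patient over
the diagnostic episode (no discounting):

* **procedure-for-all** — every patient is biopsied;
* **rule-out-first** — every patient takes the test at cost
  `C_test`; only test positives are biopsied.

With prevalence `π`, sensitivity `Se` and specificity `Sp`, the
rule-out-first biopsy rate is

```
r = π·Se + (1 − π)·(1 − Sp)
```

Each biopsy carries expected adverse-event cost
`c_AE = p_AE·(C_A&E + p_hosp|AE·C_hosp)` (a hospitalised patient pays
both the attendance and the stay, `C_hosp = LOS × daily rate`). Total
per-patient costs are

```
procedure-for-all:  C_biopsy + c_AE
rule-out-first:     C_test + r·(C_biopsy + c_AE)
```

so the net saving is `(1 − r)·(C_biopsy + c_AE) − C_test`. Alongside
the costs, the model reports the consequences: the fraction of the
population whose cancer is wrongly ruled out, `π·(1 − Se)`, for
any-grade and for high-grade (Gleason ≥ 7) disease.

Test performance itself is derived from *banded cohort counts* (men /
any-grade cancers / high-grade cancers per score band) with exact
rational arithmetic: any cut-off on a band boundary yields exact
Se/Sp/prevalence fractions. One-way ±50% sensitivity analysis, tornado
ordering, cost-neutrality threshold solving (closed-form, verified by
bisection) and a patient-level microsimulation of the full event
cascade complete the toolkit.

## Worked example

```python
from ruleout.datasets import hong_kong_model

res = hong_kong_model(cutoff=35).fit()
print(res.summary())
```

```
Rule-out decision model results
======================================================
Cut-off                                             35
Prevalence (decision grade)                     10.9%
Sensitivity                                     61.3%
Specificity                                     77.5%
------------------------------------------------------
Biopsy rate (rule-out-first)                   26.71%
Total cost, rule-out-first                       6,098
Total cost, procedure-for-all                   11,599
Net saving per patient                           5,500
------------------------------------------------------
  saving from avoided biopsies                   7,988
  saving from avoided adverse events               512
  cost of testing everyone                      -3,000
------------------------------------------------------
Missed cancers, any grade                       4.22%
Missed cancers, high grade                      0.53%
======================================================
```

Reading: testing all 569-cohort-like patients at HK$3,000 each and
biopsying only the 26.71% with PHI ≥ 35 saves HK$7,988 in biopsies and
HK$512 in adverse events per patient, for a net saving of HK$5,500 —
while 4.22% of the population (0.53% with high-grade disease) would
have their cancer ruled out incorrectly and detected only later.

Threshold analysis from the same object:

```python
res.threshold("specificity").neutral_value   # 0.2429  -> cost-neutral at ~24%
res.threshold("test_cost").neutral_value     # 8500.1  -> break-even test price
res.threshold("biopsy_cost").neutral_value   # 3395.0  -> break-even biopsy cost
```

The command-line tool exposes the same analyses
(`ruleout evaluate`, `ruleout performance`, `ruleout sweep`,
`ruleout threshold`, `ruleout simulate`, `ruleout report`); `ruleout
report --out DIR` writes the full CSV/JSON bundle — performance,
cost-consequence, base-case decomposition, sensitivity, threshold and
tornado tables plus a run manifest — byte-identically on re-runs.

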