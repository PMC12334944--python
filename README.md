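# persoref

Personalized reference intervals, reference change values and longitudinal
result flagging from biological-variation data.

Population-based reference intervals (popRIs) answer "is this value unusual
for people like this?" — a weak question when monitoring one person whose
homeostatic set point sits well inside the population range. `persoref`
implements the individual-centred alternatives used in laboratory medicine:

- **prRI** — a personalized reference interval around the individual's
  homeostatic set point (HSP, the mean of n steady-state results), by two
  routes:

  ```
  prRI_pop = HSP ± z      · HSP · √(CV_I² + CV_A²)/100 · √(1 + 1/n)
  prRI_ind = HSP ± t(n−1) · HSP · CV_T/100             · √(1 + 1/n)
  ```

  where CV_I is the population within-subject biological variation, CV_A the
  laboratory's analytical variation, and CV_T = 100·SD/mean the individual's
  own total variation;
- **RCV** — the delta-check threshold `z·√2·CV` for the change between two
  consecutive results, on either the population (`√(CV_I²+CV_A²)`) or the
  individual (`CV_T`) basis;
- **II** — the index of individuality CV_I/CV_G, which gauges how poorly
  population limits track one person;
- applicability screening (CV_I ≤ 30%, CV_A ≤ 0.5·CV_I, n ≥ 5) with a
  recommended route per measurand;
- flagging of longitudinal series under popRI / prRI / RCV criteria with
  pooled `k/N` ratios, and a seeded generator of synthetic blood-count
  panels with known ground truth for validating the pipeline.

It ships a fully worked 10-measurand CBC/differential case (a four-month,
11-time-point observation around a SARS-CoV-2 reinfection, with a 3-result
steady-state history) as packaged data.

## A worked example

```python
from persoref import BVProfile, HSPEstimate, bv_core

# erythrocytes: population BV, laboratory imprecision, and the patient's
# three steady-state results summarized as mean ± SD
profile = BVProfile("erythrocytes", "x10^12/L", cv_i=2.80, cv_g=7.00,
                    cv_a=0.67, pop_ri_lower=3.8, pop_ri_upper=5.1)
hsp = HSPEstimate(mean=4.45, sd=0.17, n=3)

iv = bv_core.round_interval(bv_core.prri_pop(hsp, profile), 2)
print(iv.lower, iv.upper)                              # 4.16 4.74
print(round(bv_core.rcv_pop(profile).threshold, 2))    # 7.98
print(round(bv_core.index_of_individuality(profile), 2))  # 0.4
```

The personalized interval 4.16–4.74 ×10¹²/L is far narrower than the
population interval 3.8–5.1: values that are "normal for the population"
but abnormal *for this patient* become visible. The 7.98% RCV says two
consecutive results must differ by more than ~8% before the change exceeds
combined biological and analytical noise at 95% probability; the index of
individuality of 0.4 confirms population limits are a blunt instrument for
this measurand.

The `examples/` scripts each exercise one capability and print annotated
output: `compute_case_parameters.py` (the full derived table for the
packaged case), `reproduce_case_table.py` (per-cell agreement with the
published values), `flag_longitudinal_panel.py` (criterion-by-criterion
flag ratios on a simulated infection episode — the personalized criteria
flag several-fold more points than the population interval),
`simulate_and_export.py` (the generator contract and CSV interfaces), and
`small_history_study.py` (why a 3-result history routes to the population
formula).

The same pipeline is scriptable from the shell:

```sh
persoref simulate --outdir panel --seed 7
persoref compute bv_table.csv hsp_history.csv --out parameters.csv
persoref flag panel/results.csv bv_table.csv hsp_history.csv
persoref case-demo
```

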