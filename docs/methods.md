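# Methods

## The model

A laboratory result for one person in steady state is modelled as
fluctuation around a fixed **homeostatic set point** (HSP): the value the
individual regulates the analyte towards. Departures from the set point have
two sources, both expressed as coefficients of variation in percent:

- biological variation — `CV_I` is the population-average within-subject
  variation (from biological-variation databases), `CV_P` the same quantity
  for one specific individual, and `CV_G` the between-subject variation of
  set points;
- analytical variation — `CV_A`, the imprecision of the measuring system.

The individual's observable steady-state dispersion is the **total
variation** `CV_T = sqrt(CV_P² + CV_A²)`, estimated as `100·SD/mean` of n
repeated steady-state results; the mean of those results estimates the HSP.

### Personalized reference intervals

Both routes build a symmetric interval around the estimated set point,
inflated by `sqrt(1 + 1/n)` for the sampling error of the set-point
estimate:

```
prRI_pop = HSP ± z        · HSP · sqrt(CV_I² + CV_A²)/100 · sqrt(1 + 1/n)
prRI_ind = HSP ± t(n−1)   · HSP · CV_T/100                · sqrt(1 + 1/n)
```

The population route borrows the dispersion from population data and uses a
normal quantile; the individual route uses the person's own `CV_T`, whose
estimation from n results costs a Student-t quantile with n−1 degrees of
freedom. At n = 3, `t(0.95, 2) = 4.30` against `z = 1.96`: the individual
route is then typically about twice as wide (see
`examples/small_history_study.py`), which is why the applicability check
routes short histories to the population formula.

### Reference change values and the index of individuality

The delta-check threshold between two consecutive results is
`RCV = z·sqrt(2)·CV`, with `CV = sqrt(CV_I² + CV_A²)` (population basis) or
`CV_T` (individual basis — no extra `CV_A` term, since `CV_T` already
contains it). The index of individuality `II = CV_I/CV_G` (a
noise-adjusted variant `sqrt(CV_I² + CV_A²)/CV_G` is provided) gauges how
poorly population limits track one person: the case panel ranges 0.24–0.65,
all below the ~0.6 rule-of-thumb where population intervals lose
sensitivity.

### Applicability rules

`check_applicability` encodes the field's screening rules: `CV_I ≤ 30%`
(above that, BV-based personalized limits are considered unsuitable),
`CV_A ≤ 0.5·CV_I` (otherwise analytical noise swamps the biological signal
and only change-based monitoring remains informative), and `n ≥ 5`
steady-state results before the individual route is trusted. The routing is:
all pass → individual; only n fails → population; the CV_A rule fails →
RCV-only; the CV_I rule fails → none.

## Numerical conventions

- Quantiles are used at full precision (z = 1.959964 at 95% two-sided
  coverage); 1.96 appears only in prose. Several published values in the
  packaged case reproduce only with the full-precision quantile.
- Coverage defaults to 0.95 two-sided everywhere.
- Internal math never rounds; display rounding is a separate half-up step
  (`round_interval`, decimal arithmetic, 0.5 away from zero) that keeps the
  unrounded limits alongside.
- Negative lower limits are reported as computed (the symmetric form can
  produce them at high CV_T; the packaged case prints one for monocytes); a
  clamp-at-zero option flags the clamp in the output.
- Degenerate inputs degrade to warnings, not errors: `CV_T = 0` collapses
  the individual-route interval to the set point and yields an RCV of 0%
  with a "not applicable" warning; `CV_A > CV_T` sets `CV_P = 0` with a
  warning.
- Flag boundaries are strict by default: a value exactly on a limit, or a
  change exactly equal to the RCV, is in-range (configurable).
- RCV flags attach to the later point of each consecutive pair; pooled
  ratios use the full point count as denominator so all criteria share one
  scale. A zero previous value makes the relative change undefined: the
  pair is skipped with a log entry.

## The packaged case

`persoref.data/case_cbc.csv` carries a published 10-measurand
CBC/differential case: per measurand the set point (mean ± SD of an n = 3
steady-state history), `CV_I`, `CV_A`, `CV_T`, the index of individuality,
population reference limits, and the published derived values.
`CV_G` is not published and is stored back-derived as `CV_I/II` (4
significant digits), marked derived. `reproduce_case_table()` recomputes every
derived cell from the printed inputs and compares at printed precision.

Five of 80 cells cannot be recovered from the printed inputs because the
source computed them from unrounded patient data (or, for the platelet
population-basis RCV, from a CV_I inconsistent with the printed one); they
are frozen in `case_table.KNOWN_DISCREPANCIES` and reported honestly rather
than absorbed into a loose tolerance. Recomputed CV_T is compared with a
tolerance that propagates half a unit of the printed mean and SD, since the
published summaries are printed coarser than the CV they came from.

## The synthetic panel generator

`simulate_panel` emulates the data the analysis assumes: per measurand,

```
value(day) = true_hsp · fold(day) · (1 + e_P) · (1 + e_A)
```

with `e_P ~ N(0, cv_p/100)`, `e_A ~ N(0, cv_a/100)` independent across
points, and `fold(day)` a piecewise-constant fold-change inside excursion
windows (1 elsewhere). Negative draws — possible only at extreme CVs — are
truncated at zero with a warning. A log-normal noise option matches the CV
on each component for users who prefer strictly positive multiplicative
noise. A ramped excursion is deliberately not the default: the emulated
episode is not mechanistically modelled, so the simplest shape is used.

The default configuration mirrors the motivating observation: 10 measurands
at 11 time points from day −10 to day 115 around a respiratory-infection
episode (110 results), with a 3-result steady-state history. The exact
sampling days are not published; the grid
(−10, 0, 3, 7, 10, 14, 21, 30, 60, 90, 115) spaces points densely through
the acute phase and sparsely through recovery, as such follow-ups are
scheduled. Set points and CVs are the case's own (`cv_p` back-derived as
`sqrt(CV_T² − CV_A²)`). The acute-phase excursions (days 0–14: neutrophils
×1.6, leukocytes ×1.35, monocytes ×1.5, lymphocytes ×0.55, eosinophils
×0.4) encode the textbook hematological response to a viral respiratory
infection — transient neutrophilia and monocytosis with lymphopenia and
eosinopenia — since the real per-day values are not redistributable.

What the generator does **not** emulate: autocorrelation between time
points (the real series' autocorrelation is unknown; draws are
independent), correlation between measurands (leukocyte differentials are
compositionally linked in reality), drift of the set point, and outliers
beyond the configured excursions. Tests passing on this generator therefore
validate the statistics and the flagging logic, not the clinical behaviour
of real longitudinal data.

`recovery_experiment` is the validation harness: across replicates it draws
short (n = 3) and longer (n = 10) histories, compares individual-route
interval widths, and measures the fraction of fresh steady-state points
covered by each interval type, returning means with Monte-Carlo standard
errors.

## Problem sizes used in validation

The test suite checks large-sample CV recovery with a 10⁵-point steady
panel (1% relative tolerance), the t→z route agreement at n = 10⁶ (relative
difference < 10⁻³), and interval coverage with 1000 replicates of the
3-result-history design; the whole suite runs in a few seconds.

## Known limitations

- The symmetric interval rests on a small-CV linearization (half-width
  proportional to `HSP·CV`). Under multiplicative noise its steady-state
  coverage is nominal to within Monte-Carlo error at CVs below ~5%, slips by
  a few tenths of a percent around CV 10–15%, and reaches ~2 percentage
  points of under-coverage at eosinophil-like `CV_T ≈ 37%` — the same
  regime the `CV_I ≤ 30%` applicability rule excludes. The coverage
  validation therefore runs on the low-CV measurands; asymmetric
  (log-normal) intervals are out of scope.
- `CV_I` estimates from meta-analyses may themselves be inflated by
  between-run analytical variation for unstable specimens (blood counts are
  measured immediately); the package takes the supplied `CV_I` at face
  value.
- The case's published flag ratios cannot be recomputed here because the
  per-day results are not redistributable; flagging is validated by
  brute-force equivalence on synthetic panels instead, and a user-supplied
  series CSV reproduces the published pipeline end to end.
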