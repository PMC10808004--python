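# Methods

## The decomposition

A monthly series `Y_t` (t = 1..n) is split as `Y_t = T_t + S_t + R_t`
with the seasonal component centred (`mean(S) = 0`).  The algorithm is
the classical STL nesting:

Inner loop (per iteration):

1. *Detrend*: `Y - T`.
2. *Cycle-subseries smoothing*: for each of the 12 calendar-month
   subseries, LOESS over year index with span `seasonal_span`, evaluated
   at every member plus one extrapolated year before and after.  The
   interleaved result `C` has length `n + 24`.
3. *Low-pass filtering*: moving averages of length 12, 12 and 3 over `C`
   (consuming the 24-point margin), then LOESS with span `lowpass_span`,
   giving `L` of length `n`.  A 12-month moving average annihilates any
   zero-sum monthly pattern, so `L` is the trend leakage inside `C`.
4. *Deseasonalise the candidate*: `S = C[12 : 12+n] - L`.
5. *Deseasonalise the series*: `Y - S`.
6. *Trend smoothing*: `T` = LOESS of `Y - S` with span `trend_span`.

Outer loop: residuals `R = Y - T - S` are converted to bisquare weights
`B(R; 6·R_med)` with `R_med = median(|R|)`, and the inner loop is rerun
with those weights multiplying the tricube distance weights in every
LOESS fit.  When `R_med = 0` the residuals carry no scale and all
weights are one.

After the final pass the seasonal mean is moved into the trend and the
residual is recomputed as `R = Y - T - S`, so additivity is exact (to
floating point) at every observed month and `mean(S)` is exactly zero.

Assumptions: additive structure (no multiplicative seasonality), a
12-month period, residuals roughly symmetric around zero.  Nothing is
assumed about the *shape* of the seasonal pattern — the point of using
STL rather than seasonal means or cosinor fits is precisely that monthly
patterns with multiple peaks survive the estimation.

### Robustness initialisation

The textbook schedule starts the first inner pass with unit weights and
lets the outer loop discover outliers from model residuals.  We found
this unreliable for the gross (10×) outliers this package must tolerate:
the first unweighted pass lets the outlier contaminate its entire
cycle-subseries, the first bisquare update then zeroes the *innocent*
same-month points (their residuals exceed `6·R_med`), and with 4 of 6
subseries points locked out the iteration converges to a distorted
seasonal.  The reference implementation in statsmodels shows the same
basin-dependence in this regime.

We therefore seed the first pass (only when `outer_iterations ≥ 1`) with
*pilot weights*: residuals against a centred moving median (window = one
period) are converted to bisquare weights before any smoothing runs.  A
moving median is insensitive to isolated gross outliers, so they enter
the first fit already down-weighted and the lock never forms.  In a
100-seed experiment (69-month series, amplitude ≈ 6, noise SD 0.2, one
10× outlier at a random month) the worst-case seasonal shift is 5 % of
amplitude; the criterion threshold is 10 %.  With `outer_iterations = 0`
the decomposition is the plain non-robust STL.

Two safeguards accompany this: a LOESS window whose neighbours all carry
zero robustness weight falls back to distance weights alone (an all-zero
window conveys no information, and failing the fit there would abort an
otherwise healthy decomposition); and locally linear fits require at
least three supported points — thinner windows use the weighted mean, so
two surviving points cannot launch a wild extrapolated slope.  A
consequence: exact reproduction of affine data needs ≥ 3 points.

### Parameters

| parameter | default | meaning / why |
|---|---|---|
| `period` | 12 | months per cycle |
| `seasonal_span` | 7 | LOESS span (years) for cycle-subseries; the classical recommendation |
| `trend_span` | 23 | smallest odd ≥ 1.5·12/(1 − 1.5/7) |
| `lowpass_span` | 13 | smallest odd ≥ period |
| `inner_iterations` | 2 | classical recommendation |
| `outer_iterations` | 5 | robustness rounds; 0 disables robustness |
| `degree` | 1 | locally linear everywhere |

Spans must be odd and ≥ 3.  `d_{c,q}` for `q > n` is inflated by `q/n`.
The exact spans used in the original analyses of checkup data are not
published; these are the library-default values that reference
implementations share, which is what makes the cross-implementation
comparison meaningful.

### Missing values

Missing observations are skipped in every LOESS fit (weights renormalise
automatically), so `T` and `S` are estimated at every month; the
residual is missing where the observation is.  A calendar month with
*no* observations in any year is an error — its seasonal offset is not
estimable.  Decomposition requires `n ≥ 2·period`.

## The cleaning pipeline

Order: sex/birth-date consistency → fiscal-year dedup → medication
exclusion → blood-pressure resolution → per-marker sentinel and tail
cleaning.  Each stage returns a report whose counts balance exactly.

* Fiscal year runs April 1 – March 31; within a subject-year the newest
  record wins, exact-date ties keep the record appearing last in file
  order (logged; an arbitrary but deterministic choice).
* A record is excluded when any of the three medication self-reports is
  "yes" **or missing** — an unreported medication status cannot be
  distinguished from treatment.
* BP uses the first measurement when present and not a sentinel,
  otherwise the second; two invalid readings leave BP missing for that
  record without removing it from non-BP analyses.
* Sentinels (default `{0, 9.999}`, configurable since real tables use
  various codes) are blanked first; then values at or beyond the
  `trim_percentile` (default 0.005, i.e. quantile 5·10⁻⁵) from **each**
  end are blanked, using linear-interpolation quantiles, inclusive of
  the boundary.  The printed convention "0.005 percentiles" is ambiguous
  (0.005 % vs 0.5 %); we read it as the 0.005th percentile and expose it
  as configuration.  Columns with fewer than `1/fraction` values skip
  the tail trim (the quantile would be set by single observations).
  Trimming is whole-table by default with a per-sex option.
* Note the interaction between trim fraction and gross outliers: a trim
  at fraction f can blank at most ≈ n·f values per tail, so validation
  experiments that require *every* planted outlier gone must plant fewer
  than n·f of them per column (or trim at a coarser percentile).

## Classification

Flags use the component cut-offs exactly as printed: all comparisons
inclusive (≥) except HDL-C, which is strict (<).  SBP and DBP are
flagged separately; the out-of-range prevalence analyses use the JCCMS
component thresholds.

Missing markers propagate through three-valued logic: a record is
labelled MetS or not-MetS only when the observed markers force that
label under *every* completion of the missing ones (e.g. WC below the
cut forces not-MetS under JCCMS regardless of anything else; a missing
WC with two positive factors is indeterminate).  Indeterminate records
are excluded from prevalence denominators — the conservative
epidemiological default; treating them as negative would bias monthly
prevalence downward in months with more missing labs.

## Seasonal statistics

The seasonal component is grouped by calendar month across years:
mean, sample SD (n−1; the denominator is not stated in the conventions
this follows, and sample SD is the unbiased default) and contributing
year count — 5 (January–March) or 6 (April–December) for the April 2012
– December 2017 window.  The peak and trough months are fixed from the
across-year means; the per-year differences `S(year, peak) − S(year,
trough)` are then taken at those two fixed months (not per-year argmax,
which would bias the difference upward), and reported as mean ± SD over
years.  Seasons are spring = March–May, summer = June–August, autumn =
September–November, winter = December–February; descriptives are median
and IQR per sex × season.  Age bands split at 65 completed years on the
visit date (the reference date for the cut is a design choice; fiscal
age would shift a small fraction of records).

## The synthetic cohort

Each subject receives one visit per fiscal year inside the window, in a
preferred month drawn once per subject (uniform by default; the true
visit-month distribution of real programmes is unknown and is exposed
as a parameter) with a ±1-month jitter at rate 0.2.  Markers follow
`intercept + slope·t + offset(month) + N(0, sd)`, rounded to one
decimal and floored at 1.0 (markers are physically positive; the floor
binds only under extreme parameters).  Defaults: intercepts near
checkup-population medians, seasonal amplitudes of the order reported
for these markers (0.5 cm WC … 9.5 mg/dL TG), noise SDs ≈ IQR/1.35.
Second BP readings are simulated, with 2 % of visits missing the first
reading.  Artifact rates default to dup 0.0025 and medication/missing
report 0.44 (the orders observed in real checkup selection flows),
sentinels 10⁻³ per cell, gross outliers (×10) 2·10⁻⁵ per cell.
Artifacts are planted in fixed order on disjoint targets — duplicates,
then medication on duplicate-free subjects, then sentinels and outliers
on records that survive the earlier filters — so each filter stage has
an exact expected removal set.  BP sentinels invalidate both readings
(a sentinel first reading with a valid second would be silently
repaired by the resolution rule, not removed).

What the generator does **not** emulate: within-subject correlation of
marker levels across years, covariate structure (weather, SES,
group-vs-individual checkups), month-dependent participation by age or
risk level, skewed marker distributions (TG in particular is
log-normal-ish in reality), and medication effects on marker values.
Passing recovery tests therefore show that the *pipeline machinery* is
correct and well-calibrated, not that real-data seasonal estimates are
unbiased — the selection effects discussed in the epidemiological
literature (who attends in which month) are outside what synthetic
validation can address.

## Validation problem sizes

The test battery uses 69-month series (the April-start window),
random LOESS instances of n ≤ 15 against a brute-force oracle, 10⁵
random records against naive rule-interpreter classifiers, a ~52 000
record cohort for filter fidelity, and a 4 000-subject cohort for
end-to-end recovery, with planted amplitudes set to 12× the monthly-mean
standard error (the recovery invariant is stated for amplitudes ≥ 5×
that error; the sharper profile gives unique, well-separated peak and
trough months so month identification is not a coin flip between
near-tied neighbours).  The demo config runs 6 000 subjects in ~15 s;
all validation together stays within a few minutes on one CPU.

## Known limitations

* Robustness is reliable for isolated gross outliers; adversarial
  patterns (many outliers in one cycle-subseries) can still defeat the
  bisquare scheme, as they defeat any median-scale rule.
* With noise comparable to seasonal amplitude, removing an outlier
  necessarily shifts the contaminated subseries fit by O(noise) — the
  10 %-of-amplitude robustness guarantee applies in the low-noise
  regime (documented above), not universally.
* The `q/n` window inflation and the pilot-weight initialisation differ
  in detail from the Fortran-lineage reference implementations; on
  clean benchmarks the per-month seasonal means agree to well under 1 %
  of amplitude, but individual robustness weights can differ.
* Monthly prevalence treats records as independent; repeat visits by
  the same subject across years are not modelled (consistent with the
  per-record analyses this mirrors).
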