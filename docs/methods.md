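# Methods

## Data model and censoring

A survey is a set of samples (each of one mushroom variety) by analytes
matrix of measurements, each carrying a censoring state relative to the
analytical limits: `nondetect` (< LOD), `trace` (≥ LOD, < LOQ), or
`quantified` (≥ LOQ). Concentrations are mg/kg fresh weight; conversion of
dried-sample results to a fresh-weight basis is the data producer's
responsibility. **Detection is operationally defined as quantified
(≥ LOQ)**; trace values count as not detected and are substituted like
non-detects. This single rule keeps detection counts, frequencies and
summary statistics mutually consistent; it means "detection frequency" here
is an "N > LOQ" frequency, which can differ from a below-LOD occurrence
rate quoted elsewhere for the same data.

Censored values enter numeric computations through a substitution policy:
`zero` (best-case lower bound), `half_lod`, `lod`, `loq`. Substitution is
elementwise monotone in that order, a property the test suite checks on
random and generated datasets. Sodium nitrophenolate is modelled as one
analyte: if congener-level records (sodium 2-/4-nitrophenoxide, sodium
5-nitroguaiacolate) are supplied they are summed per sample at load time
(quantified if any congener is quantified; LOD/LOQ the most conservative
across congeners).

Survey CSV is comma-separated UTF-8 with a header and decimal points;
`write_survey` → `load_survey` is lossless, and a second write is
byte-identical (canonical column order and `%.17g` floats).

## Occurrence statistics

Per-(variety, analyte) summaries (min/max/mean/median) are computed on the
policy-substituted vector, so medians of 0.000 arise naturally in
low-detection cells under the zero policy. The survey-wide mean of an
analyte is assembled from per-variety means as Σ(means)/n_varieties, valid
only when per-variety sample counts are equal (here 7 × 15); pairs with no
reported measurements contribute zero. This is an algebraic identity with
the sample-level grand mean, tested as such. Overall detection frequency
divides quantified counts by the full sample count, so varieties never
measured for an analyte dilute its frequency.

One-way ANOVA across varieties runs on zero-substituted values — the
source analyses do not state their substitution, and the lower-bound
scenario keeps it consistent with the deterministic screen — delegating to
`scipy.stats.f_oneway`, with an independent sums-of-squares oracle in the
tests. Tukey HSD grouping letters (via statsmodels, α = 0.05, greedy letter
assignment by descending mean) are a reporting convenience, not an
inference surface.

## Deterministic hazard quotients

Chronic: %ADI = C·F/(bw·ADI)·100; acute: %ARfD = LP·HR/(bw·ARfD)·100, with
units fixed as mg/kg × kg-food/day ÷ (kg-bw × mg/kg-bw/day); the g→kg
conversion of F and LP is centralized in these two functions. HR is the
maximum quantified concentration in the survey (0 when nothing was
quantified). A quotient of exactly 100 is classified **unacceptable** (the
acceptability criterion is strictly "< 100"). Analytes without the needed
reference value (e.g. no ARfD for thidiazuron or sodium nitrophenolate)
are reported as skipped, never silently dropped. The default chronic screen
uses zero substitution and the mean residue; p95/p99/max statistics are
available for pessimistic screening.

Consumption profiles (label, F g/day, bw kg, LP g) are user input: the
survey-specific intake data behind published absolute risk values are
generally unpublished, so the package ships only a clearly labelled
illustrative profile set (East-Asian-survey-like magnitudes: adults ~8
g/day at 56–66 kg, children 4 g/day at 16 kg; LP 46.3 g general / 12.7 g
children from Australian consumption data). Absolute published %ADI/%ARfD
values are therefore not reproduction targets; what is reproducible — and
tested — is their internal structure: the ratio of two acute quotients
equals (HR₁/ARfD₁)/(HR₂/ARfD₂), and the body weight implied by inverting
the acute equation agrees across analytes within a subpopulation.

## Probabilistic (Monte Carlo) tier

Residues are modelled lognormal. Fitting is substitute-then-fit: censored
values are replaced by the LOD (pessimistic convention for this tier) and
(mu, sigma) are the mean and standard deviation (denominator n) of the
logs — the closed-form MLE. A zero-substitution policy is rejected since a
lognormal cannot carry zeros. Residues are pooled across varieties per
analyte by default. Censored-likelihood MLE would use the censoring
information more efficiently but is deliberately not the default: the
substitute-then-fit convention matches how spreadsheet-based probabilistic
assessments are actually run, and the LOD floor makes the fitted upper tail
conservative.

Each simulation consumes one seeded `numpy.random.Generator` in a fixed
order — residue vector, then consumption, then body weight — making runs
bit-reproducible from (config, seed). Consumption and body weight default
to fixed values from the profile (a one-dimensional forecast, matching the
structure of typical single-assumption spreadsheet simulations); normal
(truncated at 0 by redraw), lognormal, and empirical-bootstrap models are
available per input. Default 10,000 iterations, percentiles 95 and 99.

Percentiles use linear interpolation between closest order statistics (the
spreadsheet convention; `numpy.percentile(..., method="linear")`), verified
against a hand-written sort-based oracle. The Monte Carlo standard error of
a percentile splits the draw vector into `blocks` (default 10) consecutive
blocks, computes the percentile per block, and reports sd/√blocks; it
scales roughly as 1/√iterations and is the yardstick for the closed-form
agreement tests (simulated q-th percentile within 3 MC standard errors of
k·exp(mu + z_q·sigma) when all other inputs are fixed).

## Synthetic data generator

The generator emulates the survey structure the analysis assumes: per
variety, a fixed sample count; per (sample, analyte), detection with
probability p and, if detected, a lognormal(mu, sigma) concentration
truncated below at the LOQ by rejection (re-draw; a degenerate sigma = 0
collapses to max(exp(mu), LOQ)). Truncation keeps generated data consistent
with the detection rule. Seeds are mandatory; there is no global hidden
randomness. Default reporting limits are LOD = 0.001, LOQ = 0.002 mg/kg,
inside the 0.0001–0.005 / 0.0004–0.0165 mg/kg ranges typical of
multi-residue LC-MS/MS methods and below every quantified value in the
packaged summary.

Calibration to a per-variety summary table sets detection probabilities to
the target frequencies and realizes the counts exactly (detected slots
sampled without replacement), so detection counts of a generated survey
match the target cell-for-cell. The lognormal parameters of each cell are
moment-matched on the detected fraction: with n samples, n_d detections and
lower-bound mean m, the detected-values mean m_d = m·n/n_d (clamped to the
cell maximum, which absorbs rounding in published tables) pins
mu + sigma²/2 = log m_d, and the observed maximum, treated as the
(n_d − 0.5)/n_d quantile, pins mu + z·sigma = log max; the quadratic is
solved for sigma (smaller root, clamped to [0, z]). Generated means are
approximate — across replicate surveys the survey-wide chlormequat mean
lands well within 15% of the target (≈0.3% off when averaged over 60
seeds) — while counts are exact by construction.

The generator does **not** emulate between-plantation or spatial structure,
analyte co-occurrence dependence within a sample (detections are
independent across analytes), measurement error of the LC-MS/MS step, or
trace-state records (it emits only nondetect/quantified). Passing tests on
generated data therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to correlated or
mis-specified real-world data.

Simulated consumption populations draw intake then body weight per
subpopulation from configurable models; the large portion is summarized as
the empirical 97.5th percentile of intake (checked against the analytic
lognormal quantile within Monte Carlo error).

## Numerical and reporting choices

- Reported percentages and means are rounded half-up (one decimal for
  percentages, three for mg/kg means), matching published table style;
  internal computation is full precision.
- ANOVA on groups that are all constant and equal returns F = 0, p = 1
  rather than NaN.
- Problem sizes in the test suite: parameter recovery uses 12,500 samples
  (≈10,000 quantified values), closed-form Monte Carlo checks 10,000
  iterations, oracle equivalences 100 random datasets (ANOVA) and 1,000
  random vectors (percentile) — large enough for the stated tolerances
  (3 binomial SDs, 0.05 on mu/sigma, 3 MC standard errors) while keeping
  the whole suite a few seconds.
- CLI exit codes: 0 success, 1 input/validation failure, 2 configuration
  failure. Logs to stderr; machine-readable CSV to files. Every emitted
  risk value carries its scenario metadata (policy, statistic, seed).

## Known limitations

- Substitute-then-fit biases the fitted lognormal when the censored
  fraction is large (sigma inflates, as in the README example); a censored
  MLE would be the statistically efficient alternative.
- The acceptability rule is a fixed threshold on a hazard quotient; no
  cumulative or combined-toxicity assessment across PGRs is attempted.
- Processing factors (washing, soaking, cooking) and bioaccessibility are
  out of scope; quotients refer to residues in the raw commodity.
- The multi-residue co-occurrence rate depends on the detection threshold
  and cannot be cross-checked against a per-variety summary table alone;
  it is reported but has no external reference value in the tests.
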