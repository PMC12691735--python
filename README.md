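# pgrisk

Occurrence statistics and dietary-exposure risk assessment for plant growth
regulator (PGR) residues in edible mushrooms.

Residue surveys of cultivated mushrooms (chlormequat, mepiquat chloride,
thidiazuron, sodium nitrophenolate, ...) produce left-censored
concentration data: every measurement is either below the limit of
detection (LOD), between LOD and the limit of quantitation (LOQ), or
quantified. `pgrisk` is a tested pipeline for food-safety assessors that
takes such a survey from raw sample-level CSV to risk conclusions:

- **Occurrence** — detection frequencies (detection = quantified, ≥ LOQ),
  per-variety summaries under a censoring-substitution policy (0, LOD/2,
  LOD or LOQ), survey-wide means, multi-residue co-occurrence, one-way
  ANOVA across varieties with Tukey HSD grouping letters.
- **Deterministic screen** — chronic and acute hazard quotients

      %ADI  = C · F  / (bw · ADI)  · 100
      %ARfD = LP · HR / (bw · ARfD) · 100

  with C the residue level (mg/kg), F the mean daily consumption (g/day,
  converted to kg/day), bw body weight (kg), LP the large portion (97.5th
  percentile of eaters, g) and HR the highest residue in the survey. A
  quotient below 100 is an acceptable risk. Non-detects enter the chronic
  screen at zero (lower bound).
- **Probabilistic assessment** — a lognormal is fitted by maximum
  likelihood to LOD-substituted residues (the pessimistic convention) and
  propagated by Monte Carlo (default 10,000 iterations, seeded) through the
  same quotients; upper percentiles (95th/99th) are reported with a block
  Monte Carlo standard error.
- **Synthetic data** — a generator of surveys with known detection
  probabilities and truncated-lognormal concentrations, including
  calibration to a published per-variety summary table so detection counts
  are reproduced exactly, plus simulated consumption populations.

The package ships the toxicological reference panel (11 PGRs with ADI/ARfD
from JMPR / EU / GB2763 evaluations) and the per-variety occurrence summary
of a published 105-sample survey of seven mushroom varieties, both as
machine-readable CSV.

## Worked example

```python
import numpy as np
from pgrisk import (builtin_reference_tables, calibrate_to_summary,
                    generate_survey, aggregate_overall_mean, acute_risk,
                    fit_residue_distribution, simulate_exposure,
                    MonteCarloConfig, ConsumptionProfile, substitute_nondetects)
from pgrisk.occurrence import round_half_up

panel, occ = builtin_reference_tables()

# survey-wide mean from the per-variety summary (7 varieties x 15 samples)
mean = aggregate_overall_mean(occ, "chlormequat", n_varieties=7)
print(f"survey-wide chlormequat mean: {round_half_up(mean, 3)} mg/kg")

# deterministic acute screen: highest residue 3.259 mg/kg, ARfD 0.09
arfd = {p.name: p.arfd for p in panel}["chlormequat"]
print(f"acute %ARfD (general, 60 kg): {acute_risk(46.3, 3.259, 60.0, arfd):.2f}")

# probabilistic chronic assessment on a synthetic survey calibrated to the
# packaged summary: LOD-substitute, fit lognormal, simulate
ds = generate_survey(calibrate_to_summary(occ, seed=1))
mu, sigma = fit_residue_distribution(substitute_nondetects(ds, "lod")["chlormequat"])
print(f"lognormal fit: mu={mu:.3f}, sigma={sigma:.3f}")
profile = ConsumptionProfile("general", f_mean=8.0, bw=60.0, lp=46.3)
dist = simulate_exposure(MonteCarloConfig(iterations=10_000, seed=1),
                         (mu, sigma), profile, 0.04)
print(f"chronic %ADI p95={dist.percentile(95):.3f} "
      f"(MC se {dist.standard_error(95):.3f}), p99={dist.percentile(99):.3f}")
```

prints

```
survey-wide chlormequat mean: 0.352 mg/kg
acute %ARfD (general, 60 kg): 2.79
lognormal fit: mu=-4.020, sigma=2.955
chronic %ADI p95=0.722 (MC se 0.037), p99=5.617
```

Reading the output: averaged over all 105 samples (non-detects at zero)
the chlormequat level is 0.352 mg/kg. A 60-kg adult eating a 46.3-g large
portion at the highest observed residue reaches 2.79% of the acute
reference dose — far below the 100% acceptability ceiling. The Monte Carlo
tier says that even the 99th percentile of the chronic intake distribution
stays below 6% of the ADI for this illustrative consumption profile. The
large fitted sigma reflects LOD substitution: most samples sit at the LOD,
far below the quantified values.

The same stages are available from the shell:

```bash
pgrisk simulate --seed 1 --out survey.csv
pgrisk summarize --survey survey.csv --out-dir reports/
pgrisk risk --survey survey.csv --out-dir reports/
pgrisk mc --survey survey.csv --analyte chlormequat --iterations 10000 --seed 1 --out-dir reports/
pgrisk fixtures --out-dir reference/
```

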