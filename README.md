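# methrhythm

Diurnal (≈24-h) rhythm analysis of DNA methylation time series, and how
one night of total sleep deprivation alters those rhythms.

The package targets the within-subject sleep-laboratory design in which
each participant's blood methylome is profiled every 3 h for 45 h
(16 samples, starting 15:00): a baseline sleep day followed by a night
of continual wakefulness. It provides, as a tested library plus a CLI:

- **Cosinor rhythmometry** — per-probe least squares on
  `y(t) = M + A·cos(2π(t − φ)/24)` via the linearized cosine/sine
  parameterization, giving mesor `M`, amplitude `A`, and acrophase `φ`
  (the clock time of peak methylation), plus a zero-amplitude F-test.
- **Differential-rhythmicity classification** — five nested OLS models
  per probe over the two 24-h condition windows (`arrhy`, `same`,
  `loss`, `gain`, `change`), selected by AIC with Akaike-weight
  confidence `w_i = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)`; probes whose best weight
  falls below the cutoff (0.6) stay `unclassified`.
- **White-blood-cell composition handling** — counts for 13
  non-exclusive WBC classes per subject/timepoint, adjacent-timepoint
  imputation of missing draws, per-class normalization of the
  methylation matrix, and a correlation screen against relative cell
  proportions at the final timepoint with its analytic null
  expectation (`α × probes × classes`).
- **Paired differential methylation** — each sleep-deprivation sample
  compared with the baseline sample at the same clock time 24 h
  earlier, per subject, with an empirical-Bayes moderated t-test
  (probe variances shrunk toward an ensemble prior; Smyth-style
  closed-form hyperparameters), a joint moderated F across timepoint
  pairs, Benjamini–Hochberg FDR, hypo/hyper direction calls, and DMP
  counts over the threshold grid 5×10⁻⁸ … 5×10⁻².
- **Gene-set over-representation** — one-sided Fisher/hypergeometric
  tests of the top DMPs against user-supplied GMT gene sets.
- **A synthetic-data generator** — plants the five rhythm classes,
  subject random intercepts, diurnal WBC rhythms and a
  hypomethylation-dominated late-wakefulness drift on the logit (M)
  scale, so every stage is testable against known ground truth.

## Worked example

```python
import numpy as np
from methrhythm import (
    PlantedTruthConfig, generate_methylation, split_conditions,
    zscore_per_probe, classify_windows, summarize_classes,
)
from methrhythm.differential_methylation import (
    paired_moderated_tests, count_dmps,
)

cfg = PlantedTruthConfig(amplitude=1.0, noise_sd=0.2, drift_fraction=0.0)
ds = generate_methylation(truth_config=cfg, n_probes=1000, seed=11)

base, sd = split_conditions(ds.m_values, ds.sample_sheet)
base_z, _ = zscore_per_probe(base)
sd_z, _ = zscore_per_probe(sd)
result = classify_windows(base_z, sd_z)
print(summarize_classes(result["assigned_class"]).round(1))

records, _ = paired_moderated_tests(ds.m_values, ds.sample_sheet)
print(count_dmps(records)[["time_awake", "n_p_lt_0.0005"]])
```

prints

```
                          n_sites  pct_of_classifiable  pct_of_all
classification
unclassified                  164                  NaN        16.4
arrhy                         348                 41.6        34.8
same                          342                 40.9        34.2
loss                           68                  8.1         6.8
gain                           55                  6.6         5.5
change                         23                  2.8         2.3
classifiable                  836                100.0        83.6
rhythmic                      488                 58.4        48.8
rhythmic_both_conditions      365                 43.7        36.5
```

Reading the tally: of the 1000 simulated probes, 836 reached an Akaike
weight ≥ 0.6 for some model ("classifiable"); 488 of those carry a
24-h rhythm in at least one condition — 342 unchanged by sleep
deprivation (`same`), 68 losing and 55 gaining rhythm, and 23 shifting
acrophase (`change`). At this signal-to-noise (A/σ = 5) the recovered
classes track the planted mixture closely. The DMP grid lists, per
matched-clock-time pair (8 h → 29 h awake), how many probes differ at
each p-value threshold and the hypo/hyper split.

The same stages are available from the shell:

```sh
methrhythm simulate --n-probes 2000 --seed 1 --out sim/
methrhythm classify --matrix sim/beta_matrix.tsv --sheet sim/sample_sheet.csv \
    --scale beta --out classes.tsv
methrhythm run --config config.yaml --seed 1 --out results/
```

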