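# Methods

## Study design and data model

The pipeline assumes the within-subject sleep-deprivation time-series
design: `n` subjects (default 15) sampled every 3 h for 45 h starting
at 15:00, i.e. 16 samples each. The first eight samples fall on the
baseline sleep day, the last eight under total sleep deprivation;
subjects wake at 07:00 on the deprivation day, so those samples span
8–29 h of cumulative wakefulness. For rhythm analysis the series is
split into two *overlapping* nine-sample windows — sampling indices
1–9 (baseline) and 8–16 (sleep deprivation) — so that each condition
covers a complete inclusive 24-h day with equal sample counts; the
windows share indices 8 and 9 (in general the overlap is `2w − n`
samples for window length `w`). Clock times live in [0, 24) and all
phase arithmetic is modulo 24.

Methylation is carried as a probe × sample matrix with an explicit
scale tag: `beta` (proportions in [0, 1]) or `m` (logit-beta).
Statistical modelling defaults to the M scale, where additive Gaussian
structure is coherent; the beta scale is retained for I/O because that
is what array pipelines exchange. Whether a published analysis ran on
beta or M values is rarely stated, so the scale is a configuration
axis rather than a hard-coded choice.

## Cosinor estimation

A single 24-h harmonic `y = M + βc·cos ωt + βs·sin ωt`, `ω = 2π/24`,
is fitted by ordinary least squares, vectorized across probes (one
design-matrix solve per window). Amplitude and acrophase follow as
`A = √(βc² + βs²)` and `φ = atan2(βs, βc)/ω mod 24`; with this
convention `φ` is the clock time at which the fitted curve peaks,
which makes statements like "peaks between 18:00 and 23:00" directly
computable. When `A` is numerically zero (below 1e-12) the acrophase
is undefined and flagged rather than reported. Rhythm significance
uses the zero-amplitude F-test
`F = ((RSS₀ − RSS)/2)/(RSS/(n − 3))` on (2, n−3) df; exact fits
(RSS ≈ 0) get p = 0 with an `exact_fit` flag. Subjects are pooled as
replicates at each timepoint (a group-level rhythm); per-subject fits
are available by subsetting. Replicates are unweighted. Acrophases
are taken from the z-scored matrix and amplitudes from the unscaled
one, since z-scoring destroys absolute amplitude but not phase.

Z-scoring is per probe across all subject×timepoint entries of one
condition window (pooled, sample SD, ddof 1). Pooling preserves the
between-subject phase agreement the classifier relies on; per-subject
scaling would whiten exactly the signal being tested. Zero-variance
probes are set to zero and flagged. Consequently z-scoring does not
commute with subject subsetting — scaling must be recomputed after any
subsetting (asserted by a counterexample test).

## Differential-rhythmicity classification

Per probe, five nested OLS models are fitted to the pooled two-window
observations, all with condition-specific intercepts so mean shifts
never masquerade as rhythm:

| model  | rhythm terms                        | k (incl. σ²) |
|--------|-------------------------------------|--------------|
| arrhy  | none                                | 3            |
| same   | shared cos/sin                      | 5            |
| loss   | cos/sin × baseline indicator        | 5            |
| gain   | cos/sin × deprivation indicator     | 5            |
| change | condition-specific cos/sin          | 7            |

The criterion is the Gaussian AIC `n·ln(RSS/n) + 2k` (AICc optional);
Akaike weights are computed with the usual stable soft-max on
`Δᵢ = AICᵢ − min AIC`. A probe is assigned its best model's class only
if the best weight reaches the cutoff (default 0.6, applied to
whichever criterion is configured); otherwise it is `unclassified`.
RSS is floored at 1e-300 inside the log so noiseless synthetic probes
produce finite criteria. Zero-variance probes are assigned `arrhy`
with a flag.

**Overlap attribution.** Naively stacking the two windows would enter
the shared samples twice, each copy under the other condition's rhythm
regime; on synthetic data this systematically converted planted
loss/gain probes into `change`. Each physical sample therefore enters
the model-selection fit exactly once, attributed to the window whose
index centre is nearer (baseline keeps index 8, deprivation index 9).
The attribution is symmetric in the two windows, which is what makes
the label-swap property (exchanging conditions maps loss↔gain and
fixes same/change/arrhy) hold exactly. Cosinor fits still use each
full nine-sample window.

An optional FDR pre-filter (on by default) requires a probe to pass
the per-condition cosinor F-test, BH-adjusted across probes, at
α = 0.05 in at least one condition before a rhythmic class may be
assigned; failing probes with a rhythmic best model are demoted to
`unclassified`. No minimum-amplitude filter is applied: the input is
z-scored, so absolute amplitude cutoffs would be arbitrary.

Probes are classified independently, with subjects treated as
independent replicates at each timepoint (no subject random effect):
this matches the group-level design matrices of the model-selection
approach, at the cost of ignoring within-subject correlation — a known
limitation, not a bug.

## Paired differential methylation

Sampling index `i` is paired with `i + n/2` (same clock time, 24 h
apart, within subject); the default design yields eight pairs at
8–29 h awake. Differences are deprivation − baseline on the unscaled
analysis matrix — the paired contrast should reflect methylation
change, not within-window standardization.

The moderated t-test shrinks each probe's variance toward an ensemble
prior: sample variances are modelled as scaled-F draws, and the prior
df `d0` and variance `s0²` come from method-of-moments on
`log s²` (mean and excess variance over the trigamma term, with a
Newton trigamma-inverse). Then
`s̃² = (d0·s0² + d·s²)/(d0 + d)` and `t̃ = Δ̄/(s̃/√n)` on `d0 + d` df.
If the moment estimate of the excess log-variance is non-positive the
ensemble is at least as tight as pure sampling noise; `d0 = ∞`
(complete pooling) is used with a warning, and the normal reference
replaces the t. The implementation reproduces the Bioconductor limma
`eBayes` hyperparameters and statistics to ~1e-10 on a frozen fixture
(tested). `d0 = 0` recovers the ordinary paired t-test exactly.

The joint moderated F over the eight pair contrasts pools the
within-pair variances (df `8(n−1)`), shrinks once, and combines
`F = mean(t̃ⱼ²)` on `(8, d0 + d)` df; a single contrast reduces to
`F = t̃²`.

BH adjustment is the textbook step-up
(`q₍ᵢ₎ = min_{j≥i} min(1, m·p₍ⱼ₎/j)`), applied across probes within
each timepoint pair; it is order-invariant and monotone (property
tests, cross-checked against statsmodels). Direction is `hypo` iff
Δ̄ < 0. DMP counts are tabulated over the grid
5×10⁻⁸…5×10⁻², with the hypo/hyper split at the headline 5×10⁻⁴ and
the null expectation `threshold × probes tested` alongside. Top-N
selection orders by (p ascending, |Δ̄| descending, probe ID) — a
deterministic tie rule. Over-representation of the mapped genes is a
one-sided hypergeometric tail per GMT set, BH across sets, with the
universe defaulting to all genes in the supplied manifest.

## Cell composition

Thirteen non-exclusive WBC classes are tracked (total WBC,
granulocytes, lymphocytes, total T, total B, monocytes, total/memory/
naïve CD4 and CD8, NK/dendritic); composite classes are exact sums of
their members. Missing draws are imputed per subject and class as the
mean of the two adjacent sampling indices; boundary or consecutive
gaps are undefined and raise with positions listed. Normalization
divides each probe value by the matching subject/timepoint count of
one class, producing one matrix per class.

The composition screen correlates each probe's methylation at the
final sampling index with each class's *relative proportion*
(count / total-WBC count — the denominator is a design choice, as
"relative proportion" is ambiguous) across subjects, Pearson by
default (Spearman via config). It reports the number of nominal
p < α correlations, the analytic expectation `α × probes × classes`
(650 at the defaults: 0.05 × 1000 × 13), and the BH-surviving count.
Dependence among the non-exclusive classes inflates the variance of
the observed count but not its mean; the expected-count formula
deliberately ignores it.

## Synthetic data generator

Signals are built on the M scale and pushed through the logistic
function, guaranteeing beta values strictly inside (0, 1) and a
monotone signal→beta map:

`m = mesor + subject intercept + A·cos(2π(t − φ)/24)·mask + drift·ramp + ε`

- Class mixture: defaults to the classifiable-site proportions of a
  large blood-methylation rhythm screen (arrhythmic ≈ 48%, same ≈ 35%,
  loss ≈ 7%, gain ≈ 7%, change ≈ 2%); configurable.
- Rhythm regime: the mask activates the harmonic in the baseline half
  (indices 1–8), the deprivation half (9–16), both, or neither,
  according to class; `change` probes swap to a second acrophase
  shifted by 6–12 h in the deprivation half.
- Defaults (chosen once, as the package's standing study conditions):
  amplitude 0.5 and noise SD 0.25 M-units (A/σ = 2), mesor uniform in
  ±2.5, subject-intercept SD 0.3, per-probe noise SD lognormal with
  spread 0.3 (real array probes are strongly heteroscedastic; without
  this the variance ensemble is degenerate and the empirical-Bayes
  prior df is always infinite), drift magnitude 0.5 on 15% of probes,
  70% of drifted probes negative (hypomethylating).
- Late-wakefulness drift ramps linearly from onset (≥ 23 h awake) to
  full magnitude at the final sample, emulating the accelerating
  methylation change at the end of deprivation.
- WBC counts: leaf classes get sinusoidal diurnal means (granulocytes
  peaking early evening, lymphocyte subsets at night) with
  multiplicative lognormal noise, so counts stay positive and the
  composite sums hold exactly. Missing timepoints are planted only at
  interior indices and never consecutively, because the
  adjacent-mean imputation rule is undefined otherwise.

What the generator does *not* emulate: array chemistry and detection
failures, probe cross-reactivity, spatial/batch intensity artifacts,
autocorrelated within-subject noise, and genuine biological coupling
between methylation and cell composition. Passing tests therefore
demonstrate the correctness and calibration of the estimators under
the declared generative model, not their behaviour under every real
artifact.

## Numerical choices and problem sizes

- All randomness flows from `numpy.random.default_rng` seeded at one
  top-level seed; reruns are byte-identical.
- OLS solves use `lstsq`; rank deficiency in covariate residualization
  raises with the aliased covariates named.
- Beta→M conversion clips at 1e-6 to keep the logit finite.
- Test and acceptance problem sizes (500–5000 probes, 15 subjects) are
  the package's chosen desk-scale study conditions: large enough for
  stable recall/calibration estimates at binomial tolerances, small
  enough to run the whole suite in well under a minute. The published
  epigenome-wide counts (e.g. 116,119 rhythmic sites) depend on the
  real 818k-probe cohort data and are represented by
  arithmetic-consistency checks on the printed tallies instead.

## Known limitations

- No subject random effects in rhythm models (group-level fits).
- The batch/covariate stage is per-probe fixed-effects OLS
  residualization, off by default — a deliberate simplification of
  mixed-model covariate handling, which is under-specified for this
  design.
- No nonparametric rhythm tests (RAIN/JTK) and no period estimation;
  the period is fixed (default 24 h).
- No reference-based cell deconvolution from methylation itself;
  composition handling requires measured counts.
- Enrichment runs only on user-supplied gene sets; no pathway
  databases are bundled or queried.
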