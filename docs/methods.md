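# Methods

This note documents the models, conventions and design choices behind
`enosekit`, in the order data flows through the pipeline.

## Measurement model and synthetic cohorts

A breath measurement on a polymer-sensor array is simulated as a three-phase
trace per sensor, sampled at `dt_s` (default 1 s) over `duration_s`
(default 120 s):

- **baseline purge** (`t ≤ baseline_s`, default 25 s): the resting reading
  `baseline_level` (default 1.0 resistance-change units — nonzero so the
  fractional normalization `(S_i − S_0)/S_0` is well defined);
- **exposure** (`baseline_s < t ≤ baseline_s + exposure_s`, default 40 s): a
  saturating-exponential rise toward `base_amplitude · (1 + class_shift)`
  with time constant `rise_tau`;
- **purge** (after exposure): exponential decay back to baseline with
  `decay_tau`.

Gaussian noise of SD `noise_sd` and an optional linear drift are added
throughout. This is the simplest functional form with the qualitative shape
of polymer-sensor sorption curves; no adsorption/desorption chemistry is
modelled, and the humidity-sensitive channels excluded upstream are not
simulated.

The default sensor bank holds 28 heterogeneous models: amplitudes uniform in
0.5–2.0, `rise_tau` in 4–12 s (well under the 40 s exposure, so responses
saturate and the noiseless peak is within 5% of the target amplitude),
`decay_tau` in 10–30 s, and `noise_sd = 0.10 · base_amplitude` — a
realistic 10:1 signal-to-noise ratio at which clean samples always clear QC
while 20-fold-degraded ones do not. Drift defaults to 0.

The **disease effect** is a multiplicative amplitude shift (`effect_size`,
default +30%) on a subset of sensors (default the first 8 of 28):
polymer-sensor responses scale with analyte concentration, so a
concentration shift in disease-associated VOCs acts multiplicatively, and
only sensors sensitive to the affected compounds respond.

**Stale samples** — breath bags measured too late, which in practice show
low signal intensity and are removed by QC — are emulated by scaling each
trace's deviation from its baseline mean by `snr_factor` (default 0.05)
while holding the noise level fixed (compensating noise of SD
`noise_sd·√(1−snr²)` is added back, since scaling would otherwise shrink the
noise too). Degradation via amplitude collapse rather than noise inflation
matches the low-signal-intensity phenomenology.

Reproducibility: each sample draws from its own RNG stream spawned from the
master seed by sample index (`SeedSequence(seed, spawn_key=(index,))`), so
enlarging a cohort never reshuffles earlier samples, and identical
spec + seed gives bit-identical cohorts.

## Signal processing

**Effective window.** A moving-difference detector on backward differences
`d_i = |S_i − S_{i−w}|` (default `w = 5` samples) is compared against
`k · median(|d|)` over the comparisons lying inside the baseline purge
(default `k = 3`). The window starts at the first index opening a run of at
least `min_run = 5` consecutive exceedances and ends after the last
exceedance. The run requirement is essential: the median-based threshold
sits near 2 SD of the difference noise, so a single-point rule would
"detect" a signal in pure noise most of the time, while a genuine response
keeps the difference elevated throughout its rise. With these defaults the
false-detection rate on pure Gaussian noise is ~1%, and on noiseless traces
the detected start falls within one sample of the true injection time. A
trace with no qualifying run yields a "no signal" condition, never an error.

**Normalization.** `(S_i − S_0)/S_0` with `S_0` the reading at the trace's
reference index. The output is exactly 0 at the reference, invariant to
rescaling the raw trace, and used for plots and manual review only —
classification features are computed on the raw segmented signal, because
the fractional transform distorts the amplitude information the classifier
uses.

**Quality control.** Per sensor, the baseline mean and population SD
(ddof = 0) are estimated on the raw readings of the first `baseline_s`
seconds. A sample passes if any sensor's 3-point moving average stays above
`mean + 3·SD` for at least 3 consecutive samples, and is rejected
otherwise. Smoothing plus the sustained-exceedance requirement make the
rule statistically meaningful at array scale: a pointwise raw-value test
over 28 sensors × ~100 time points would pass pure noise with probability
≈ 0.97 (one in ~740 Gaussian points exceeds 3 SD by chance), whereas a real
sorption response stays above threshold for many seconds. Measured on the
default generator: 100% of clean samples pass, ≥ 95% of 20-fold-degraded
samples and ~100% of pure-noise samples are rejected. QC is evaluated
per sensor on each sample's own baseline (not pooled across the cohort).

**Smoothing.** Centered 3-sample moving average with truncated (shrinking)
windows at the edges, so output length equals input length and constant
traces are unchanged. Processing order is QC → segmentation → smoothing;
all 28 traces of a sample are cut to a common window (earliest start to
latest end over the sensors with a detected response) so the segments stay
aligned.

## Featurization: 33 descriptors per sensor

Each segmented, smoothed trace is summarised by five families
(9 + 8 + 5 + 5 + 6 = 33), concatenated over the 28 sensors in sensor-id
order into 924 features named `<sensor>__<descriptor>`. Conventions the
descriptor names alone do not pin down:

- SD and IQR are population-form (ddof = 0; linear-interpolation
  quantiles); kurtosis is Fisher excess and skewness the Fisher–Pearson
  moment coefficient, both defined as 0 for a constant trace.
- The 10%/90% thresholds for rise/fall times, time-over-90% and
  area-over-90% are fractions of the maximum of the *baseline-anchored*
  segment (signal minus its first value), so they survive a baseline
  offset. Crossings are localized by linear interpolation; rise uses the
  first upward crossings, fall the last downward ones. A threshold never
  crossed yields 0.
- "Time over X" counts strict exceedances times `dt`; "area over X"
  integrates `max(S − X, 0)` by the trapezoidal rule on the sampled,
  clipped values (areas at partial crossings are therefore trapezoidal, not
  exact piecewise-linear — the same convention the test oracle uses).
- Slopes are first differences divided by `dt`, timestamped at interval
  midpoints; ties in the extreme slopes break toward the earliest time.
- Ratios with zero denominators resolve to 0 (logged), keeping the matrix
  complete for selection.

Useful invariants, asserted in the tests: scaling a trace by `c > 0` scales
the value-dimension features by `c` and leaves time features, skewness and
kurtosis unchanged; every descriptor agrees with an independent brute-force
recomputation to 1e−9 relative tolerance.

## Selection and scaling

Fitted on training rows only, in three steps: drop columns with variance
below 1e−12; score the survivors with the one-way ANOVA F-value
(`MS_between/MS_within`; zero within-group variance with distinct means
scores +∞ and ranks first, ties break by canonical column order); keep the
top `ceil(fraction · n)` (default 3% — 870 surviving columns yield
ceil(26.1) = 27); standardize the kept columns with training means and
population SDs. The ceiling rule and tie-breaks make the selected set a
deterministic function of the training data. The fitted `SelectionState`
serializes to JSON so a trained pipeline is portable.

Inside Monte-Carlo cross-validation the whole selection state is refit on
each split's training rows. This is what keeps the no-effect null
calibration at chance: selecting 27 of 924 features on all rows first and
cross-validating afterwards would leak holdout information into the
selection and bias accuracy upward.

PCA projections (for inspection of class separation before/after selection)
fix each component's sign by making the largest-magnitude loading entry
positive, so plots are reproducible.

## Classification and evaluation

The classifier is scikit-learn's C-SVC with the RBF kernel. The default
configuration is `C = 1`, `gamma = "scale"`, `tol = 1e−3`. A reference
configuration `REFERENCE_SVC_CONFIG` (C = 66, gamma = 2.5, tol = 0.02,
degree = 10, coef0 = 66) ships for comparison runs; note that `degree` and
`coef0` are inert under the RBF kernel (they parameterize polynomial and
sigmoid kernels) and are accepted verbatim rather than silently dropped.
Also note that a fixed `gamma = 2.5` on ~27 standardized features puts
typical inter-sample distances far outside the kernel's support
(`exp(−2.5·‖x−y‖²) ≈ 0`), degenerating the decision function toward the
bias term — which is why the package default is the data-scaled gamma.

**Monte-Carlo cross-validation**: `n_iter` (default 100) independent
stratified random holdouts of `round(holdout · n)` rows (default 20%;
per-class counts by largest-remainder allocation, at least one per class —
stratification matters because the motivating cohorts are imbalanced and
unstratified 20% draws of ~40 samples can produce extreme class ratios).
Each iteration refits selection + scaling + SVC on the training portion and
records train and validation confusion counts. Aggregates are mean ± SD
over iterations (sample SD, ddof = 1 — the SD of a set of replicate
estimates). Metrics: recall TP/(TP+FN), precision TP/(TP+FP), accuracy
(TP+TN)/N, specificity TN/(TN+FP), with 0/0 resolving to 0; class 1 (sick)
is positive.

**Hyperparameter search**: a seeded random search over a bounded space
(C log-uniform 1e−2…1e3, gamma log-uniform 1e−4…1e1, tol log-uniform
1e−4…1e−1; degree and coef0 sampled for interface fidelity but inert).
Each trial is scored by MC-CV mean validation accuracy with a reduced
iteration count (default 25) for tractability; exact ties break toward the
smaller train-validation accuracy gap, then the earlier trial; an optional
baseline configuration is evaluated as trial 0 so the search never returns
something worse than its starting point. The winner should be (and, via
`BreathScreeningModel.fit(tune=True)`, is) re-scored with the full
iteration count.

**Held-out evaluation** transforms the untouched test matrix with the
training-fitted selection state and refuses any overlap between train and
test sample ids (`LeakageError`).

## What the synthetic experiments do and do not show

The generator reproduces the *statistical structure* the analysis assumes —
three-phase traces, heterogeneous sensor scales, multiplicative
class effects on a sensor subset, low-SNR degraded samples — but not real
breath data: no humidity interference, no inter-device or day-to-day
drift, no correlated physiological covariates (age, smoking, diet), and
Gaussian iid noise rather than instrument noise spectra. Passing the null
calibration (no-effect accuracy at chance) and recovery (strong-effect
held-out accuracy ≥ 0.9) therefore validates the pipeline's statistical
soundness — no leakage, no selection bias, sensitivity when separation
exists — not clinical performance on real cohorts.

Problem sizes in the test-suite and acceptance runs (50–60 samples per
class, 100 CV iterations, 60 QC replicates) were chosen as the smallest
cohorts at which the binomial noise of the measured rates is comfortably
inside the asserted bands.

## Known limitations

- The effective-window detector assumes a monotone-ish rise after
  injection; multi-peak or oscillating responses would fragment the
  exceedance runs.
- Common-window segmentation uses the union across sensors; a sensor with a
  much slower response than its neighbours can have its tail clipped.
- The QC rule is one-sided (upward responses); sensors whose resistance
  falls on exposure would need the rule mirrored.
- Feature areas use sampled-trapezoid integration of clipped signals;
  at coarse `dt` this differs from the exact piecewise-linear area near
  threshold crossings.
- The stochastic hyperparameter search is plain random sampling; an
  adaptive (model-based) search would find good regions in fewer trials
  but adds a dependency and matters little at these problem sizes.
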