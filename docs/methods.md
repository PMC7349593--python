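# Methods

This note documents the models, numerical choices and limitations
behind the package, in the order data flows through it.

## Measurement model and synthetic generator

A measurement is a six-sensor resistance time series on a uniform grid
(default 18.5 Hz) over three phases: baseline in pure air (10 s), gas
adsorption (80 s), desorption (90 s). The generator simulates the
conductance G(t) of each sensor with first-order kinetics:

- baseline: G = G₀;
- adsorption: G = G₀ (1 + A (1 − e^{−(t−t_on)/τ_ads}));
- desorption: exponential relaxation toward G₀ with τ_des, continuous
  at the phase boundary.

Kinetics are first-order in **conductance**, not resistance, because
MOX conductance is approximately proportional to the extent of the
surface reaction with the analyte. The stored signal is R = 1/G.

The response amplitude factorizes as
A = gain_s · a(type, class) · bottle · (1 + ε),
with the following sources of variation (all chosen once as realistic
for consumer-grade MOX arrays, and fixed):

| parameter | default | meaning |
|---|---|---|
| `sensor_gain_sd` | 0.10 | lognormal sd of the per-sensor-instance gain, drawn once per dataset — same-type sensor pairs share kinetics but respond distinguishably |
| `bottle_effect_sd` | 0.15 | lognormal sd of the per-bottle concentration factor, drawn once per bottle — the source of within-bottle correlation that group-aware validation exists for |
| `sample_noise_sd` | 0.05 | relative sd of per-sniff amplitude jitter |
| `kinetic_noise_sd` | 0.08 | lognormal sd of per-sniff jitter on τ_ads and τ_des (sniff-to-sniff variation in flow, temperature, surface state); without it, fitted time constants separate classes with implausible precision |
| `obs_noise_sd` | 0.005 | relative sd of per-point multiplicative noise on G |

Amplitudes below 10⁻⁶ are clipped to that floor so no curve is exactly
degenerate. The 600 s inter-measurement purge carries no data and is
not simulated.

The default cohort is 28 bottles (5 HQ, 4 AQ, 13 LQ, 6 Ea) with 10–12
sniffs each (~305 samples). Class kinetic tables are set so that HQ and
LQ are well separated in amplitude (≈5× apart, ≫ bottle noise), while
AQ and Ea amplitudes overlap within one bottle-effect sd on the log
scale and are distinguished mainly by kinetics (ethanol adsorbs and
desorbs roughly twice as fast as the wine matrix). Two purpose-built
scenarios support the reduction experiments: one where only the MQ-4
pair carries class signal, and one where classes differ only in τ_des.

What the generator does **not** emulate: sensor drift across days,
temperature/humidity covariates, heater-modulation effects, non-
exponential tails, correlated (colored) noise, or class-dependent noise
levels. Passing tests on synthetic data therefore demonstrate the
correctness and statistical behavior of the pipeline, not field
performance on real recordings.

## Normalization and segmentation

R₀ is the **median** of the baseline window (robust to spikes; the mean
would serve equally on clean data). r = R/R₀ and g = R₀/R, so r·g = 1
identically. Segments exclude the baseline window: a phase ends at the
sample at or immediately before its boundary time and the next phase
starts at the following sample, so "full" is an exact disjoint
concatenation of adsorption and desorption. Phase boundaries come from
metadata, never from change-point detection.

## The 828-feature catalogue

23 feature types per (sensor, signal, segment) cell; 6 × 2 × 3 × 23 =
828. The cell count of 23 is the load-bearing constant of the module.
Numerical choices:

- **EMA features** operate on first differences
  (y₀ = 0, y_k = (1−α) y_{k−1} + α (x_k − x_{k−1})) with
  α ∈ {0.1, 0.01, 0.001}; extrema of y are the features. α = 1
  degenerates to the raw increments.
- **Integral** is a left-Riemann sum (Σ v·Δt), which makes
  integral(full) = integral(ads) + integral(des) exact on the disjoint
  partition.
- **Smoothed derivative**: central finite differences of a 15-sample
  moving average (~0.8 s at 18.5 Hz) — wide enough to kill point noise,
  narrow enough to keep the transient peak.
- **Crossing times**: the response range is measured from the segment's
  first sample to its net extremum (max if the upward excursion
  dominates, else min); the first crossing of start + fraction·range is
  linearly interpolated between samples. A flat segment returns 0.
- **Exponential fit** y = c + A e^{−t/τ} with τ bounded to
  [Δt, 10 × duration] and deterministic initialization (c = last value,
  A = first − last, τ = duration/3). Solver failure returns the
  initialization instead of raising.
- **Moments**: sd uses n−1; skewness/kurtosis use uncorrected sample
  moments over that sd; zero-variance segments report 0 for both.

Every degenerate case falls back to a finite documented constant — one
NaN would otherwise poison every downstream model fit. Sigmoid and
polynomial fits and moving-window captures are deliberately absent; the
exponential fit represents the analytic-fit family.

## Classification and validation

Multinomial logistic regression (L2, C = 1.0, lbfgs) on z-scored
features, standardization fitted on training rows only. C and the
z-scoring flag are exposed in the config; the defaults are the common
baseline choice.

`test_fraction` counts **groups**, not samples: holding out
round(0.25 · n_groups) bottles (at least 1) is the only reading that
guarantees no bottle ever spans both sides regardless of cohort
imbalance. Each group-shuffle repeat draws from its own substream of
the master seed, so split r is identical no matter how many repeats
run. One practical consequence worth knowing: with few bottles per
class, a random fold can starve a class in training and the regularized
model may then lose that class's decision region entirely — cohorts in
the tests are sized to avoid this degenerate regime except where it is
the point.

## Feature selection

Forward selection evaluates candidates on **one** set of splits drawn
per run, shared by all candidates and steps: fair comparisons, and a
large speedup because per-fold standardization of all columns is
computed once (z-scoring is columnwise, so slicing standardized columns
equals standardizing each subset). Ties break by lexicographic feature
id; the only stochastic input is the split seed. Inner CV defaults to
25 repeats; the heavy experiment drivers rank candidates on 5 repeats
and re-score the chosen prefix at 100 repeats, which costs a per-step
ranking noise but no evaluation bias — chosen sets are always re-scored
on fresh splits where selection bias matters.

Filters: mutual information uses deterministic quantile-binned plug-in
estimation (8 bins, in bits) rather than k-NN estimators —
reproducibility over estimator efficiency. ReliefF visits every
instance (m = n, no sampling), uses Manhattan distance on min-max
scaled features, k = 10 nearest hits and per-class misses weighted by
P(c′)/(1−P(c)); classes must have more than k members.

## Experiment designs

- every nonempty sensor subset (63) cross-validated on its full column
  set, with a best-per-size summary;
- forward selection restricted per sensor, and per feature source
  (ALL, ALL-G, ALL-R and the adsorption-only ON, ON-G, ON-R);
- wrapper vs filter accuracy over a k-grid;
- PCA (on z-scored selected features) for visualization only — it is
  never used as the modeling representation.

The desorption-information check forward-selects five features within
each source restriction and re-scores on fresh splits: when classes
differ only in desorption kinetics, adsorption-only models stay at
chance (~0.25 for four balanced classes) while whole-curve models
exceed 0.9.

## Problem sizes

Defaults were chosen so every analysis runs on a single desk CPU: the
default scenario at ~305 samples; the secondary scenarios at 4 bottles
per class with 7–9 sniffs (~128 samples); candidate ranking inside
heavy selection runs at 5 shuffle repeats with 100-repeat re-scoring;
sensor-subset sweeps at 25 repeats. `--full-scale` in the report
driver restores 100 repeats everywhere.

## Known limitations

- The greedy wrapper has no optimality guarantee; an exhaustive-search
  oracle dominates it by construction (asserted on small tables).
- Synthetic accuracies run higher than typical field results because
  the generator's noise structure is benign; qualitative orderings
  (wrapper ≥ filters at small k, LOGO ≥ shuffle mean with larger
  spread, near-parity of the best single sensor) are the meaningful
  outputs, not absolute percentages.
- Backward elimination, genetic-algorithm search and multivariate
  filters (Wilks' Λ, Mahalanobis) are out of scope, as are SVM/MLP/
  tree/k-NN comparisons.
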