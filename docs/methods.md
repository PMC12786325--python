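# Methods

This note documents the models behind each module, the parameter choices that
matter, and what the synthetic generators do and do not emulate.

## Liquid-level control

**Plant.** The culture chamber is an open dish at the air-liquid interface.
The level obeys a mass balance

    d(level)/dt = (net_flow − evaporation) / dish_area

with `net_flow` in µL/min, area in mm², level in mm. The actuator saturates
symmetrically at `max_flow`; the laser distance sensor quantizes the level to
`sensor_quantum` (round-to-nearest). The level clips at zero (dry dish, logged).

**Controller.** Positional discrete PID with rectangular integration and a
backward-difference derivative:

    e(t)  = setpoint − measured(t)
    I(t)  = I(t−1) + e(t)·Ts
    u(t)  = Kp·e(t) + Ki·I(t) + Kd·(e(t) − e(t−1))/Ts

The velocity form and trapezoidal integration would be equally defensible;
the positional/rectangular form is the textbook default for a "standard
discrete PID" and is what the tests pin down. Anti-windup is conditional
integration: the accumulator freezes while the actuator is saturated. It is
unexercised at the reference tuning (Ki = 0) but required for the loop to be
usable as a full PID.

**Control interval.** Ts = 0.1 s. The bench hardware's sensor/control rate is
not specified anywhere we could anchor it; 0.1 s is fast relative to the 3-s
convergence requirement and slow enough that a laser distance sensor easily
sustains it.

**Reference plant.** `REFERENCE_PLANT` models a 6-mm-diameter chamber
(28.27 mm² surface — consistent with the ~150 µL of medium such a chamber
holds at a ~5 mm level), pump gain 10 mL/min per unit command, saturation at
2 mL/min, evaporation 20 µL/min, sensor quantum 0.1 mm. These values make the
printed behaviour physical: a +2 mm step (57 µL of excess volume) is pumped
out in ~1.7 s of saturated outflow plus a sub-second proportional tail. A
larger dish is not compatible with the 3-s figure — on a 60-mm dish (2827 mm²)
even full saturated flow moves the level only 0.012 mm/s, so no tuning of the
printed gains could recover a 2-mm disturbance within 3 s; the closed-loop
time constant of the proportional loop, k = Kp·pump_gain/(60·area), makes
this explicit. After convergence the level holds a ~0.05 mm limit cycle:
evaporation drifts it down until the quantized measurement steps, at which
point one proportional correction pumps it back. That limit cycle, not the
transient, is the steady-state holding tolerance reported by the acceptance
run (~0.05 mm, inside the ±0.2 mm specification).

**Disturbance model.** An instantaneous step added to the true level. A bolus
injection or a probe dip are both well approximated by this at the 0.1-s
timescale.

**Stability guard.** A run aborts when the level departs from the setpoint by
more than 10× the applied excitation (disturbance step or initial offset) —
a cheap divergence detector for misconfigured gains.

## Synthetic MEA recordings

Each electrode carries three additive components, all seeded through a single
`numpy` Generator per recording:

1. **Coloured background.** Spectral amplitude ∝ sqrt(1/f^α + 1/f_knee^α)
   with α = 1 (canonical LFP slope), saturated below 1 Hz and joining a white
   floor at f_knee = 100 Hz. The low-frequency saturation keeps single
   fragments stationary (without it the deepest 1/f bins dominate the
   variance and fragment power wanders); the white floor represents
   instrument/thermal noise and carries most of the total power. The shape is
   calibrated analytically so that with unit band gains the time-domain SD
   equals `noise_sd` (default 10 µV) in expectation; band gains are applied
   after calibration so a gain g multiplies band power by exactly g².
   The background is synthesized independently per 10-s fragment. Fragments
   are the unit of every downstream analysis and align exactly with these
   blocks, so no analysis window ever straddles a synthesis boundary; content
   below the 0.1-Hz fragment resolution is not modelled.
2. **Band signatures.** Condition profiles multiply the background amplitude
   in named bands: the EV profile dampens 80–600 Hz (HFO) by 0.6 and halves
   the firing rate relative to control; the GW profile boosts 13–30 Hz (beta)
   by 1.3. The directions (EV suppresses firing and HFO power; GW is
   electrically near control) reflect the platform's findings; the magnitudes
   are generator defaults chosen once to make the three-class problem
   learnable but not degenerate, and they are configuration-exposed.
3. **Spikes.** Poisson-placed biphasic templates (0.6-ms negative lobe, 0.9-ms
   positive rebound at 40% amplitude — generic extracellular morphology) on
   `n_active` of the electrodes (default 30 of 60), peak amplitude in units of
   the background SD (default 8, comfortably above the 5.5-SD detection
   threshold). Overlapping templates are allowed; at the default rates
   collisions are negligible.

Composite conditions are mixed at the **fragment** level: each 10-s fragment
draws its profile independently with the mixture weights (default
0.32/0.57/0.11 over CTL/GW/EV), and the ground-truth fragment labels are kept
on the recording for recovery tests. Mixing whole recordings instead would
make the mixture trivially separable at the recording level and would not
produce a split class repartition.

What the generator does **not** emulate: inter-donor and inter-slice
variability, non-stationary drift, stimulation artifacts, correlated noise
across electrodes, spike waveform diversity, or any pharmacology. Passing
tests therefore demonstrate the correctness and calibration of the analysis
chain, not classifier performance on real tissue recordings.

## Spike detection

Per electrode the SD is estimated on the full trace (not per window): the
full-trace estimate is stable, makes the Gaussian false-positive oracle exact,
and the 10-ms "rolling window" is interpreted as the merge/refractory scope —
candidate samples with |v| above 5.5·SD within 10 ms of an accepted event are
merged into it, and the event time is the first threshold crossing. Detection
is two-sided (|v|): extracellular spikes are predominantly negative, but
two-sided thresholding is the conservative reading and the detector's counts
are invariant to sign flips by construction. Both choices are arguments
(`window_ms`, `threshold_sd`), and per-window SD could be layered on without
changing the interface. A zero-variance trace yields zero spikes with a
warning rather than an error.

At 5.5 SD the two-sided Gaussian tail gives ≈ 2·Φ̄(5.5)·N expected false
positives — about 0.05 per 2-minute electrode at 10 kHz — which the test suite
checks against the Poisson 99% interval over 100 seeded traces.

## Spectral analysis

Fragments are non-overlapping, consecutive 10-s windows; incomplete tails are
discarded. Per fragment the mean is removed and a rectangular-window
periodogram is computed, one-sided, normalized by fs·N so that the density
integrates to the fragment variance (Parseval holds to rounding, asserted at
1%). The native resolution of a 10-s fragment is exactly 0.1 Hz, so the
0.2–300 Hz / 0.1 Hz output grid maps 1:1 onto FFT bins (2999 of them) with no
interpolation; a requested grid that does not match the native one is
rejected rather than resampled. No taper is applied — at 0.1-Hz resolution
with band-level summaries, leakage is immaterial, and the untapered
periodogram keeps the Parseval calibration exact.

Band power averages the density over half-open bands [lo, hi). The standard
spectrogram is capped at 300 Hz; the HFO band extends to 600 Hz, so HFO
summaries computed from a `Recording` trigger a second spectral pass up to
the highest band edge internally.

## Classification

Features: per selected electrode, fragment power densities mean-pooled into
1-Hz bins over 0.2–300 Hz (300 bins; the first pools the eight 0.2–0.9 Hz
bins, the 300-Hz edge folds into the last bin), columns electrode-major. With
20 electrodes that is 6000 features — 1-Hz pooling keeps the forest tractable
and denoises the chi-square-distributed periodogram bins; the raw 0.1-Hz
resolution remains available (`bin_hz=0.1`). Electrode selection ranks
electrodes by full-trace SD; the pipeline averages the per-recording SDs over
all recordings so every fragment shares one feature space, with ties broken
by the lower electrode id.

The split is stratified at the fragment level, 70/30, seeded. This is the
literal protocol; it does allow fragments of one recording on both sides of
the split, so `group_by_recording=True` is provided as the stricter
alternative (on the synthetic generator the distinction is immaterial because
fragments are exchangeable within a condition by construction, but real
recordings should consider it). The forest uses 500 trees, unlimited depth,
√p features per split, a fixed seed, and one worker; five-fold stratified
cross-validation runs on the training portion as an overfitting check. All
seeds and hyperparameters are recorded in the report.

CUP (confidence upon prediction) is defined here as the mean predicted
probability of the winning class over test fragments — the natural reading of
the term; a uniformly uncertain classifier has CUP = 1/k exactly. Class
repartition is the fraction of a condition's fragments assigned to each
trained class, and the chi-square goodness-of-fit test compares assignment
*counts* (the test requires counts, not percentages) to the uniform
random-assignment expectation of total/k per class (33.3% per class with
three trained classes, 50% with two), dof = k−1.

The composite GW+EV condition is never a training class: the forest is
trained on the three pure signatures and the composite fragments are pushed
through `predict_repartition`, so the recovered repartition estimates the
mixing weights.

## Proteomics

The pipeline mirrors label-free MS practice for samples whose loading cannot
be equalized:

- **Presence filter**: keep a protein iff some condition detects it in
  strictly more than `min_frac` (default 0.75) of its samples. Detection
  means a genuinely measured value — imputed entries are recorded in a mask
  and do not count, so filtering commutes with imputation on the survivor set.
- **Imputation**: undetected values are set to the sample's own 2.5% lower
  quantile of detected abundances (linear-interpolation quantile, per sample
  — a global constant would ignore loading differences).
- **TMM factors**: the published trimmed-mean-of-M-values procedure —
  upper-quartile-closest-to-mean reference, M/A computed on total-sum-scaled
  abundances, double trim (30% of M, 5% of A), precision-weighted mean of the
  surviving M. The returned factor is the *effective* size factor (total
  abundance × trimmed fold, geometric mean 1), so a sample loaded at 4× its
  twin gets a 4× factor; a test cross-checks the factors against Bioconductor
  edgeR's `calcNormFactors` on the same matrix to within 2%.
- **Ranks**: per sample, rank 1 = most abundant, ties averaged; undetected
  proteins share the worst tied rank (m+1 … n averaged) so that rank means
  are comparable across samples with different detection depths. Ranks are
  computed after imputation in the pipeline, but the rank of an imputed value
  lands in the same tied tail either way. The entire rank pipeline is
  invariant to any per-sample monotone transform — the reason ranks are the
  comparison currency for non-normalizable samples.
- **Differential test**: per protein, two-sided Mann-Whitney on the
  per-sample ranks between two conditions, BH-adjusted. The asymptotic
  tie-corrected statistic is used *without* continuity correction: ranks are
  integers (ties across samples are routine, ruling out the exact method),
  and at ~10 samples per group the corrected test rejects at ~3.3% instead of
  5% while the uncorrected one is calibrated at the nominal level (verified
  on null tables). Note the power constraint: with 5 samples per group the
  smallest achievable rank-sum p-value (~0.01) cannot survive BH adjustment
  across ~1000 proteins, so BH-significant calls require roughly 8+ samples
  per group; the generator default is 10 per condition. This rank-sum + BH
  combination deliberately replaces a count-model GLM (negative-binomial
  dispersion estimation is meaningless for non-count MS abundances); TMM
  factors are still computed and reported for loading diagnostics.
- **Overlap**: |A∩B| / |A∪B| as a percentage truncated to whole percent
  (95/117 → 81%, 77/129 → 59%, 30/165 → 18%).
- Ranked lists and differential tables are written in plain formats (RNK-style
  two-column files, TSV) consumable by downstream ontology-enrichment tools;
  enrichment itself is out of scope.

## Protein-table generator

Log2 abundances are protein-level N(20, 2) plus within-sample N(0, 0.6),
i.e. log-normal intensities spanning ~6 orders of magnitude as in label-free
MS. `loading_factors` multiply whole samples; `enriched_set` proteins are
multiplied by `effect` in one condition (`effect=1` is a null table); per
sample, the lowest `missing_rate` fraction of values is censored — missing
not at random, at the detection limit, which is why low-quantile imputation
is the matching strategy. Ground truth (enriched ids, loading, effect, seed)
rides along on the table.

## Reproducibility

All randomness flows from one top-level seed. Stages derive sub-seeds as
SHA-256(seed:stage) mod 2³¹ (`aliflow.io.derive_seed`), so any stage can be
re-run in isolation and the full report is bit-reproducible for a fixed seed.
Reports are JSON/CSV with seeds and hyperparameters embedded; the pipeline
writes a resolved copy of its configuration next to its outputs.

## Problem sizes

The full-scale experiment (the acceptance script and the end-to-end tests)
uses 300 ten-second fragments per class — 25 two-minute recordings per
condition at 60 electrodes / 10 kHz — plus 504 composite fragments, about
7·10⁹ synthesized samples in total; signal synthesis dominates the run time
(a few minutes on one CPU). Unit and property tests run reduced geometries
(2–12 electrodes, 1–2 kHz) chosen so every code path is exercised with the
same fragment/grid structure.

## Known limitations

- The plant is a single lumped volume: no tubing delays, pump pulsation, or
  sensor noise beyond quantization; the PID derivative term acts on the
  quantized measurement and would amplify sensor noise if any were modelled.
- The classifier's >90% accuracy on synthetic data validates the pipeline,
  not biological discriminability; effect magnitudes are generator defaults.
- The rank-sum differential test ignores abundance magnitudes by design;
  proteins with large fold changes deep in the abundance tail can rank-move
  less than the same fold change near the middle.
- HDF5/CSV are the only recording formats; proprietary MEA formats, spike
  sorting, and artifact removal are out of scope.
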