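# Methods

This note documents the models, numerical choices and limitations of
`pulseaf`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Atrial fibrillation (AF) manifests in photoplethysmography (PPG) as
irregularly irregular inter-beat intervals (IBIs) and beat-to-beat
amplitude variability, against the quasi-regular, serially correlated
intervals of normal sinus rhythm (NSR). The package classifies 2-minute,
125 Hz single-channel PPG segments as AF or NSR.

## Synthetic PPG generator

The generator is phenomenological: it reproduces the interval and
amplitude statistics a rhythm classifier keys on, not hemodynamics.

* **Intervals.** An AR(1) Gaussian process scaled to a stated mean and
  coefficient of variation (CV), truncated below at 0.3 s (a 200 bpm
  ceiling). Presets: NSR mean IBI 0.8 s, CV 0.04, lag-1 correlation 0.6
  (respiratory sinus arrhythmia); AF mean IBI 0.65 s, CV 0.20, lag-1
  correlation 0 ("irregularly irregular"). The 5× CV ratio and the
  absence of serial correlation in AF are standard AF phenomenology; the
  AF mean IBI is shorter because AF typically runs faster than NSR.
* **Pulse morphology.** Each beat is a systolic Gaussian lobe (σ =
  0.06·IBI) plus a dicrotic lobe at +0.25·IBI with 30% amplitude
  (σ = 0.09·IBI). Per-beat amplitudes are Normal(1, amp_cv), floored at
  0.1; presets use amp CV 0.05 (NSR) and 0.20 (AF).
* **Artifacts.** Baseline wander: 0.1 Hz sinusoid at 10% of pulse
  amplitude with a random phase. Measurement noise: white Gaussian at 2%
  of pulse amplitude. The first beat lands at t = 0 so records begin at a
  systolic peak.
* **Determinism.** All randomness flows through one `numpy` generator
  seeded per record; dataset-level per-record seeds derive from a master
  seed.

What the generator does **not** emulate: motion artifacts, sensor
saturation, ectopic beats, comorbid arrhythmias, inter-subject morphology
differences, and ICU-grade signal-quality variation. Passing tests
therefore demonstrate that the pipeline recovers the interval/amplitude
statistics it is designed around — not clinical performance on real
recordings, which is known to be a harder problem.

## Preprocessing

Systolic peaks are local maxima with minimum spacing 0.3 s and prominence
≥ 10% of the signal range; expressing prominence as a range fraction makes
detection invariant to positive affine rescaling, and the spacing floor
rejects dicrotic lobes at plausible heart rates. Segments start exactly at
the first detected peak and span 15,000 samples (half-open, 0-based);
segmentation is pure slicing. Normalization happens after segmentation
(the natural order for a streaming front end); default min–max to [0, 1],
z-score (n−1 denominator) as an option.

## Decomposition

* **Sifting.** Cubic-spline envelopes through maxima/minima with a mirror
  extension of two extrema at each boundary; fewer than four spline knots
  falls back to linear interpolation; the candidate mode is the signal
  minus the envelope mean. Stop per Huang's Cauchy criterion
  Σ(h_{k−1}−h_k)²/Σh_{k−1}² < 0.2, capped at 100 iterations.
* **Termination.** Extraction stops when the residual has fewer than 3
  extrema (monotonic trend) or 12 IMFs have been extracted. A signal with
  too few extrema is returned as pure residual.
* **Exactness.** Because sifting only subtracts, Σ IMF + residual equals
  the input to machine precision, always — this identity is the backbone
  of several tests.
* **Ensembles.** Noise SD is 0.2× the signal SD (standard EEMD practice).
  CEEMD decomposes signal ± noise_i for i = 1..N (2N EMD calls; default
  N = 20, and N = 8 in the end-to-end benchmark); EEMD uses positive noise
  only (default N = 200). Realizations with differing IMF counts are
  zero-padded to the deepest decomposition before averaging — truncation
  was rejected because it breaks the reconstruction identity. In CEEMD the
  paired ±noise cancels exactly in the average, so its reconstruction
  error is at machine precision while EEMD's decays only as 1/√N; the
  2N-vs-N call counts are recorded on the result object.
* **Selection.** Pearson coherence of each IMF with the original signal;
  threshold 0.1; zero-variance IMFs get coherence 0; if nothing passes,
  the single most coherent IMF is kept (logged) so the feature chain never
  receives an empty set.

No reference EMD implementation is bundled or required; the test suite
validates the decomposition against closed-form oracles (the analytic
components of a two-tone signal) and an algorithmically independent
zero-phase Butterworth band-split.

## Feature extraction

* **Periodogram.** 4 s frames, 2 s hop (59 frames per 2-minute segment —
  at least 3 beats per frame at plausible heart rates), Hann window,
  one-sided squared-magnitude FFT scaled so the bin sum equals the
  windowed frame energy (discrete Parseval). The textbook limit definition
  of a power spectrum is not a computable estimator; the windowed
  periodogram is the standard realization.
* **Filterbank.** 32 order-4 Gammatone filters, centers log-spaced on
  0.1–20 Hz (the band containing PPG fundamentals and their relevant
  harmonics), phase 0. Bandwidth is constant-Q, w = f₀/4, floored at
  0.05 Hz. Each filter is realized as the magnitude FFT of its impulse
  response sampled at the frame's bin frequencies and peak-normalized to
  1; band energy is the inner product of the frame spectrum with those
  weights.
* **Combination across IMFs.** Per-IMF power spectra are summed before
  filtering (cross-term-free total power); a stacked per-IMF mode exists
  behind `FeatureConfig.combine="stack"`.
* **Normalization and compression.** Division by the global mean band
  power of the record (simplest reading of "average power"; a per-band
  variant would change only the relative band weighting), making the whole
  chain scale-invariant and the normalized entries average exactly 1;
  then U^ϑ with ϑ = 1/15, the classic power-law exponent for
  power-normalized cepstral features. A final DCT along bands is off by
  default — the compressed matrices themselves are the features — and
  available behind a flag.
* **Time-domain features.** Mean IBI, IBI SD, RMSSD, fraction of
  successive IBI changes > 50 ms, Shannon entropy (bits) of an 8-bin IBI
  histogram, and peak-amplitude CV, computed from detected peaks (≥ 4
  required) and appended per record; at the network input they are
  broadcast across frames. Per-record (rather than per-frame) attachment
  was chosen because 4 s frames contain too few beats for stable interval
  statistics.

## Classifier

Input standardization uses training-set means/SDs per feature, followed by
ReLU (the input activation); one BiLSTM layer with 64 units per direction;
the concatenated final forward/backward hidden states feed a 32-unit ReLU
layer and a 2-unit SoftMax (NSR = 0, AF = 1; exact probability ties
resolve to NSR). Widths, batch size 16 and the 10-epoch decay period are
the package's own choices, sized for CPU training on a few hundred
records. Weights are Glorot-uniform with forget-gate bias 1; Adam with
β = (0.9, 0.999), ε = 1e−8; initial learning rate 0.01525, decay factor
0.5, at most 100 epochs. Gradients are exact BPTT, checked against finite
differences to ~1e−8 relative error in the suite. Everything is
deterministic given the config seed.

The learning-rate range test takes one Adam step per batch along a
geometric lr grid, retaining each batch's pre-step loss. The loss-vs-lr
relation is used only through its empirical minimum: the suggested initial
lr minimizes the 5-point moving average of the curve, restricted to the
finite prefix if the loss diverges; a flat curve suggests the grid start.
On a convex quadratic this rule provably lands inside the stable step-size
interval, which is the property the suite asserts.

## Evaluation

Recall, precision and F-measure are percentages carried at full precision;
report tables round half-up to 2 decimals. The ET-score multiplies the
harmonic-mean term (β²+1)·F_AF·F_NSR/(β²·(F_AF+F_NSR)) (β = 1 throughout)
by a speed-rank time factor applied as a fraction: rank 1 → 1.00, each
further rank −0.02, floored at 0.02. The fractional reading is the only
one consistent with the published worked examples the suite reproduces.
Measured wall times may feed the ranking but are never asserted in tests
(hardware-dependent); ranks can also be supplied directly.

## Problem sizes

The end-to-end benchmark trains on 100 synthetic records and evaluates on
50 (75 AF / 75 NSR split 2:1), 2-minute segments at 125 Hz, CEEMD with
N = 8, 64 hidden units — a configuration chosen to exercise the full
method at realistic segment length while remaining a desk-scale,
single-CPU computation. Unit and property tests use shorter segments
(typically 60–70 s) and smaller ensembles.

## Known limitations

* Synthetic-only validation; see the generator caveats above.
* EMD boundary handling (two-extrema mirror) can still leak edge artifacts
  into the last IMFs of short signals; selection usually discards them.
* The classifier supports exactly one BiLSTM layer and binary labels.
* The WFDB format is not read; records enter as plain CSV.
* No ROC/AUC or confidence intervals; the evaluation surface mirrors the
  confusion-matrix/F-measure/ET-score system it implements.
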