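# Methods

This note documents the models and procedures implemented in `slocad`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical decisions taken where the design
was genuinely open.

## Slow wave event detection

Detection operates on the *negative envelope* of the band-passed
multichannel EEG rather than on single channels: per sample, the four
most negative channel values are selected, the most negative of those is
dropped (robustness to single-channel artifacts), and the remaining
three are averaged. The envelope is centered by removing its mean over
the whole recording (global, not per-epoch centering — per-epoch
centering would make event amplitudes depend on epoch boundaries).

* **Band-pass**: zero-phase 4th-order Butterworth, 0.5–4 Hz
  (`scipy.signal.sosfiltfilt`); forward–backward filtering doubles the
  effective order and removes phase delay, which matters because event
  *timing* feeds the fMRI design.
* **Half-waves**: a candidate spans a positive-to-negative zero crossing
  to the next negative-to-positive crossing. Crossings are localized on
  the sample grid without sub-sample interpolation (≤ 5 ms error at the
  200 Hz working rate); the onset is the last non-negative sample before
  the negative run. Runs touching the recording edges have no flanking
  crossing and are discarded.
* **Criteria**: duration within [0.25 s, 1.0 s] (bounds inclusive) and
  trough ≤ −5 μV (inclusive). Lowering the amplitude threshold (more
  negative) always yields a subset of detections — a tested invariant.
* **Slopes** are magnitudes, |trough| / limb duration. Signed slopes
  would cancel in the mean-slope formula below, which would make the
  synchronization score meaningless.
* **Involvement** is computed on the per-channel 0.5–4 Hz signal (the
  same band the envelope is built from), as the percentage of channels
  whose average over a 40 ms window centered on the trough is strictly
  below −5 μV. Windows that would extend past the recording are
  truncated with a warning.
* **Synchronization score**:
  `SyncS = involvement × (neg_slope + pos_slope)/2 / 1000`, with
  involvement on the 0–100 percent scale, so typical scores land in the
  1–100 range. The score is invariant to time shifts of the event and
  homogeneous of degree one in the slopes.

## Spindle detection

A single channel (conventionally Cz; any channel name or index can be
configured) is band-passed to 10–16 Hz with a zero-phase Hamming-window
FIR filter of ~1 s length. The published workflow names a b-spline
wavelet filter whose exact family is toolbox-internal; the FIR dialect
used here has equivalent pass/stop behavior at these bandwidths and is
documented as a divergence.

Power is the squared filtered signal smoothed with a centered 100 ms
moving average. Per 30-s epoch, the high and low thresholds are
`median + 4·MAD` and `median + 2·MAD` of the epoch's power, with MAD
taken raw (no 1.4826 normal-consistency factor — the detection rule is
defined on the raw MAD). Candidates are maximal runs of power strictly
above the high threshold, extended outward while power exceeds the low
threshold *of the epoch containing the exceedance onset*; extension may
cross epoch boundaries and is clipped only at the recording edges.
Overlapping extended spans are merged. Events must last 0.3–3 s.

The specificity filter compares the mean rectangular-window periodogram
power per frequency bin in 10–16 Hz against the pooled flanking bands
8–10 and 16–18 Hz on the raw event segment (zero-padded to at least
0.5 s); events with a ratio > 3 are retained. A flat (broadband)
spectrum scores ≈ 1 and is rejected; a sigma-band sinusoid scores in the
hundreds. `peak_power_time`, the argmax of smoothed power within the
event, serves as the "spindle peak" for coupling.

**Known limitation.** Because boundaries are defined by low-threshold
crossings of *smoothed* power, any burst is measured ≥ ~0.1 s longer
than its generating waveform, and on near-silent backgrounds the low
threshold sits just above the noise floor so measured durations inflate
further. Very strong sub-0.3 s bursts on a silent background can
therefore pass the minimum-duration criterion. Against ongoing
sigma-band activity — the regime the adaptive median+MAD thresholds are
designed for — boundaries hug the burst and short bursts are rejected
as intended; the test suite poses the burst scenarios in that regime.

## Slow wave–spindle coupling

An SWE is coupled when some spindle's power peak lies within a centered
4-s window (±2 s, boundary inclusive — ties must be deterministic and
inclusivity matches "within") of the SWE trough. One spindle may couple
several SWEs; no exclusivity is imposed.

## Design matrices

* **HRF**: difference of two gamma densities, peak delay 6 s, undershoot
  delay 16 s, dispersions 1 s, undershoot ratio 1:6, 32-s kernel — the
  de-facto canonical parameterization. The kernel is peak-normalized
  (max = 1) so a unit-height regressor peaks at the coefficient's value.
  No temporal/dispersion derivatives and no FIR basis are provided.
* **Event regressors**: duration boxcars (height 1) on a 16× oversampled
  grid, convolved and sampled at the frame times; frame times reference
  the frame midpoint, `(i + 0.5)·TR`. Zero-duration events become
  one-sample impulses. Spindle regressors use duration boxcars too
  (symmetry with SWEs); the spindle column is omitted when no spindles
  were detected, since an all-zero column would be rank deficient.
* **Parametric modulators**: per-event values are mean-centered before
  convolution so the unmodulated event column keeps the mean response
  (standard identifiability), then serially orthogonalized —
  Gram–Schmidt in the declared order, each column residualized against
  all earlier ones, earlier columns untouched. In `coupling_syncs` the
  binary coupling modulator is entered before the synchronization
  scores, giving coupling explanatory priority. In `stage_syncs` each
  stage's modulator is centered within its stage and residualized
  against its own event column, so the interaction model collapses to
  the stage model when scores are constant within a stage.
* **Nuisance**: 24 motion regressors ([R, ΔR, R², ΔR²], backward
  differences with first row zero), 5 aCompCor components (PCA of the
  linearly detrended, per-voxel standardized CSF matrix; unit variance,
  mutually orthogonal; fewer with a warning when rank-deficient) and a
  constant. Optional cosine or Legendre polynomial drift columns are off
  by default; the synthetic pipeline enables a Legendre term matching
  the drift order it simulates.

## GLM estimation and thresholding

Fitting is ordinary least squares per masked voxel (no prewhitening —
an explicit divergence from AR(1) modeling; the synthetic noise is
white, and OLS keeps estimates unbiased under correlated noise at some
efficiency cost). `df = frames − rank(X)`; a rank-deficient design is an
error naming the dependent columns. T-contrasts report one-sided
(activation) p-values by default. Residual sums of squares below
1e−12 of the total sum of squares are treated as exactly zero, and such
voxels receive an infinite-T sentinel (excluded from BH ranking by
p = 0 for positive effects) with a warning.

Subject maps are thresholded by Benjamini–Hochberg FDR over the analysis
mask at q = 0.05 first, then a cluster-extent filter removes connected
components below k = 10 voxels (26-neighbor connectivity by default;
6/18/26 configurable). FDR-then-extent matches the order in which the
thresholds are conventionally quoted. The analysis mask defaults to the
full grid for synthetic runs; a gray-matter probability mask
(p > 0.20) is the intended mask for real data and can be supplied.

## Reference maps and SloCAD

The probability map is the voxelwise mean of binarized subject maps
(values are multiples of 1/N). The reference mask is `probability ≥
threshold` with threshold 0.20; inclusion at exactly 20 % is inclusive
(a `strict` flag switches to `>`). Overlap statistics report the shared
voxel count and the percentage of each mask, rounded half-up to one
decimal.

The deviation of a subject map I from a reference R is reported as three
complementary scalars rather than a single number: `missing_fraction`
(canonical territory the subject fails to recruit — the clinically
salient direction), `extra_fraction` (atypical recruitment), and the
symmetric `dice_deviation = 1 − Dice(I, R)` as the headline scalar.
Subtraction operates on the binarized thresholded maps, matching the
binarization used to build the reference; mean-T summaries within the
missing/extra sets and a per-atlas-label weighting hook are available
but off by default (weights default to uniform).

## Synthetic data

The generators exist to give every stage a ground-truthed test surface.

* **EEG**: per-channel 1/f ("pink") background noise (white optional);
  SWEs as one negative half-period of a sinusoid (duration = truth
  duration, trough at the midpoint) on an involved-channel subset —
  matching the half-wave detector's target morphology without
  privileging exact slopes; spindles as Gaussian-windowed sinusoids
  (σ = duration/6), by default on all channels so any detection channel
  sees them. Overlapping truth events on a channel sum linearly with a
  warning. Default test conditions: 8 channels, 200 Hz, −40 μV / 0.6 s
  SWEs on 2 μV noise — chosen for testability; the source recordings'
  amplitude statistics are not published, so no realism claim is made.
* **Hypnogram**: contiguous stage blocks rendered on the 30-s epoch
  grid; each epoch takes the stage of the block containing its start.
* **BOLD**: baseline 100 + per-voxel Legendre polynomial drift +
  β × (HRF-convolved event boxcar) in active ROIs (+ slope × convolved
  centered-modulator sticks) + optional leakage of the simulated
  motion/CSF signals + white Gaussian noise. TR defaults to 2 s
  (configurable; the source does not state one). The generator uses the
  package's own HRF/regressor code, so noiseless identifiability is
  exact by construction — GLM tests therefore exercise estimation, not
  convolution-dialect mismatch.
* **Confounds**: motion as slow random walks; CSF voxels as shared
  low-frequency sinusoid mixtures plus noise — enough structure to
  exercise the motion-24/aCompCor plumbing.
* **Atlas**: seeded Voronoi partition into contiguous labels.

Not emulated: head geometry, scanner artifacts, REM/wake
microstructure, physiological noise spectra, spatial autocorrelation of
BOLD noise, or registration error. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
noise model, not performance on real recordings.

## Problem sizes and determinism

The end-to-end demonstrations use a 24×24×16 voxel grid, 180 volumes at
TR 2 s (6 min runs), 5-subject cohorts and 10 deviation replicates —
sizes at which the full pipeline runs in seconds while leaving the
statistical behavior (FDR calibration, cluster filtering, probability
thresholding) non-trivial. Every stochastic stage takes an explicit
seed; `run_pipeline` derives per-subject seeds from the global seed and
records them, with SHA-256 hashes of all artifacts in the manifest, so
identical configurations are byte-reproducible.
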