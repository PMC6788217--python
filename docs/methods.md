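# Methods

`eegfmri` implements an end-to-end analysis linking band-limited
electrophysiological power to hemodynamic signals in a resting-state
network, together with a synthetic data generator whose ground truth the
analysis can be validated against. This note documents the model, the
numerical choices, and what the synthetic validation does and does not
show.

## The coupling model

The analysis assumes the standard neurovascular coupling used throughout
simultaneous EEG–fMRI work: the BOLD signal at a voxel follows the
band-limited power of the neural oscillation at that location, convolved
with a canonical hemodynamic response function (HRF),

    BOLD_v(t) = Σ_k  m_{vk} · (h ⊗ P_k)(t) + drift + noise,

where `m_{vk}` is the spatial loading of network `k` at voxel `v`, `P_k`
is the network's power time-course at one sample per second, and `h` is
the double-gamma canonical HRF (response delay 6 s, undershoot delay
16 s, unit dispersions, peak:undershoot ratio 6, length 32 s; with those
parameters the kernel peaks at (6−1)·1 = 5 s). The pipeline estimates
`P_k` from EEG and tests the coupling voxel by voxel.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions.

* **Head model.** Voxels fill a rectangular box (default 8×8×6 at 6 mm);
  the gray-matter mask is the inscribed ellipsoid. Sensors (default 32)
  sit on an upper-hemisphere shell. The leadfield is the closed-form
  current-dipole potential in an infinite homogeneous conductor
  (σ = 0.33 S/m), then average-referenced. This is a deliberate stand-in
  for a finite-element forward model: it is exactly linear and lets the
  inverse solution be tested against analytic ground truth, but carries
  no tissue geometry, so absolute localization accuracy on real heads is
  outside what these tests show.
* **Sources.** Each network is a smooth Gaussian blob (σ = 1 voxel
  spacing, floored at 0.1) inside the gray matter. Its voxels carry a
  band-limited carrier (default alpha, 8–13 Hz) amplitude-modulated by a
  slow envelope: rectified low-pass Gaussian noise with 0.1 Hz cutoff,
  the timescale of resting-state fluctuations. Both envelope and carrier
  are synthesized spectrally (hard frequency-domain truncation) rather
  than with recursive filters: a 0.1 Hz Butterworth at EEG sampling
  rates is numerically fragile and its edge transients can dominate a
  whole run, and carrier skirts at shared band edges would leak
  envelope-modulated power into adjacent analysis bands. The carrier
  keeps a 0.5 Hz margin inside its nominal band, emulating a rhythm that
  does not sit exactly on the analysis-band boundaries. Every voxel also
  receives 1/f-power background noise (default amplitude 0.5 relative to
  the unit-variance carrier), giving each analysis band a noise floor as
  in real EEG. Dipole orientations are fixed random unit vectors.
* **Ground-truth envelope.** The stored 1 Hz envelope of each network is
  its realized per-second band power (modulator² × carrier instantaneous
  power). This is the quantity a perfect band-power analysis of the
  neural signal would see, and therefore the quantity the BOLD coupling
  acts on; its slow structure comes from the sub-0.1 Hz modulator.
* **Artifacts.** Four families at amplitudes expressed as multiples of
  the clean sensor RMS: gradient artifact (50×, exactly periodic at the
  slice rate, onsets in `tr_markers`), ballistocardiogram (5×,
  locked to `cardiac_markers` with per-beat lag jitter and slow
  amplitude drift), blink transients on frontal sensors (3×), and
  30–80 Hz myogenic bursts on rim sensors (2×). Zero amplitude disables
  a family; negative amplitudes are rejected.
* **BOLD.** HRF-convolved, variance-standardized network envelopes
  weighted by the maps and sampled at the TR (default 2 s), plus
  second-order Legendre drift with Laplace-distributed per-voxel
  coefficients (default scale 0.3) and white noise (default 0.5). The
  heavy-tailed drift reflects the spatial structure of scanner drift;
  exactly Gaussian spatial patterns would also be unidentifiable for a
  spatial ICA, which would make the fMRI network extraction fail for
  reasons unrelated to the method under test.

With all noise switched off, the correlation between a network's
HRF-convolved envelope and any in-network BOLD voxel is 1 by
construction — the end-to-end analysis must recover this, and the test
suite asserts it.

## EEG cleaning

Cleaning follows the usual order for MR-environment EEG. Gradient
artifact: epoch on TR markers, subtract the average of the
`n_avg_epochs` nearest neighboring epochs (the current epoch excluded),
then fit and remove the leading principal components of the residual
epoch matrix per epoch (optimal basis set, default 3 components).
Ballistocardiogram: epoch −0.2 s to +0.6 s around each R peak and remove
the per-epoch least-squares fit of the top singular vectors of the raw
epoch matrix — the first vector absorbs the mean pulse shape, the next
ones its amplitude and lag variation; zero components is an exact
no-op. R peaks, when not provided, come from peak detection on the
band-passed (5–20 Hz), squared ECG with a 0.5 s refractory period.

Bad channels are those whose 1–80 Hz mean correlation with the other
channels or whose noise-band variance (200–250 Hz; 0.4–0.5 of Nyquist
with a warning when the sampling rate is too low) falls outside
median ± 3·1.4826·MAD of the cross-channel distribution — a robust,
parameter-free outlier rule. Bad channels are replaced by
inverse-distance-weighted averages of their four nearest good
neighbors. Filtering is a zero-phase 4th-order Butterworth band-pass
(1–80 Hz).

Biological artifacts are removed by ICA. A component is artifactual if
|r| with the EOG reference > 0.3, |r| with the EMG reference > 0.3,
excess kurtosis > 10, or the similarity of its log spectrum to a fitted
1/f^β line over 2–40 Hz falls below 0.5 (the similarity is the absolute
log-log correlation). All thresholds are configurable. The pipeline
builds its reference traces from role channels of the synthetic montage
band-limited to the artifact-characteristic ranges (frontal mean,
1–8 Hz, for EOG; rim mean, 30 Hz–0.45·fs, for EMG); without the band
limit, broadband neural activity shared with those channels masquerades
as artifact and the classifier removes the very signal under study.
Cleaning concludes with average re-referencing.

## ICA engine

One engine serves sensor-space artifact ICA, temporal ICA of band power,
and spatial ICA of BOLD: PCA whitening to the requested order, then
deflationary FastICA with tanh contrast (a = 1), tolerance 1e−4, up to
1000 iterations per component and 10 restarts; restart attempts use a
damped (averaged) update that suppresses the two-cycle oscillation the
plain iteration can fall into on nearly Gaussian directions. Component
signs follow the positive-skewness-of-loadings convention.

Model order is the Wax–Kailath MDL minimum. On short series, where the
dimension is comparable to the number of observations, the MDL
asymptotics saturate at full order, so the automatic order used by the
network decompositions is the minimum of MDL and the count of
correlation eigenvalues above the Marchenko–Pastur upper edge
(1 + √(p/n))², additionally capped by configuration. The desk-scale
preset caps at 3: with ~100 voxels and ~160 frames, a larger order
splits a network's power process into a slow component and its own
frame-to-frame power noise, two pieces with the same topography of
which only one couples to BOLD.

## Source power

The inverse is eLORETA: per-voxel 3×3 weights iterated to the fixed
point where each weight block is the symmetric square root of
`K_vᵀ M K_v`, with `M` the regularized pseudoinverse of the weighted
gain Gram matrix. Regularization is 0.05 of the mean sensor-space
eigenvalue (configurable), applied on the average-reference subspace;
the noise covariance is the identity (this design has no empty-room
recordings). Convergence is declared when the largest relative Frobenius
change of any block falls below 1e−6; the solver errors with its
iteration trace otherwise. The defining property — zero localization
error for noise-free point sources — is asserted in the tests at 50/50
random dipoles.

Band power uses a short-time Fourier transform with a 2 s Hamming window
and 50% overlap (one frame per second, frame `t` centered at `t+1` s); a
band's power is the mean periodogram power over the bins whose center
lies in `[lo, hi)` — shared printed edges belong to the higher band, and
80 Hz closes gamma and full inclusively. Orientation powers are summed.
Because the STFT is linear in the signal, the pipeline computes source
band power by applying the inverse operator to the sensor STFT
coefficients, which equals the explicit source-time-series route exactly
(asserted in a test) without materialising hundreds of megabytes of
source signals.

## Network detection and template matching

Temporal ICA decomposes the gray-matter voxels × frames power matrix per
band; each component's spatial map is the Fisher-z-transformed
correlation of its time-course with every voxel's power series (zero,
with a warning, for constant series). Spatial ICA decomposes the BOLD
volumes × voxels matrix so the sources are spatially independent maps,
each z-scored across voxels; the mixing columns are the associated
time-courses.

The network of interest is the component whose map correlates best with
a template within the gray-matter mask (ties go to the lower index).
Because ICA leaves a per-component sign ambiguity that loading skewness
cannot reliably resolve on ~100-voxel grids, each component is first
oriented so that its mean map value over the template core (template
above half its maximum) is nonnegative. For the EEG route the template
is the ground-truth map smeared through the inverse's orientation-
averaged power point-spread — the analogue of matching EEG-derived maps
against a template obtained with the same modality — while the fMRI
route uses the full-resolution map.

## Hemodynamic correlation and group inference

The selected component's time-course (or the occipital-sensor alpha
power, for the sensor-level variant) is convolved with the canonical
HRF, and correlated voxel by voxel with the BOLD series after linear
upsampling to 1 Hz; the first 32 s are excluded as convolution burn-in.
Correlations are clipped at |r| ≤ 1−1e−12 and Fisher-z transformed.

Group inference stacks subject z-maps and applies one-sample one-sided
t-tests per voxel (both directions run through the same machinery on
negated maps). Voxels with zero sample variance take the degenerate
limits p ∈ {0, ½, 1}. Multiple comparisons use the Benjamini–Yekutieli
step-up procedure, valid under arbitrary dependence; sensor-level maps
are corrected over voxels per band, network-level maps jointly over
voxels × bands, and the fMRI map over voxels. Spatial correspondence
between the EEG-derived and fMRI-derived network maps is quantified by
Pearson correlation of the unthresholded group t-maps within the
gray-matter mask (CC) and the Dice coefficient of the BY-significant
positive masks (DC; a z > 1.96 binarization is selectable). The report
is a two-row table (CC, DC) over the six bands.

## Problem sizes and what the validation shows

The desk-scale preset used by the validation suite runs 24 sensors, a
6×6×5 grid (~100 gray-matter voxels), 160 s at 200 Hz, and 80 BOLD
volumes per subject, with groups of 10 subjects; a full study of ten
such groups completes in a few minutes on one CPU. The package defaults
(32 sensors, ~200 gray-matter voxels, 300 s at 250 Hz) and all larger
scales are configuration away.

Passing the end-to-end test — the alpha column of the CC/DC report
strictly exceeding the delta, theta, beta, and gamma columns in at least
8 of 10 independent studies — shows that the chain of cleaning, inverse
solution, power estimation, ICA selection, HRF correlation and
BY-corrected group inference recovers a planted alpha-band coupling and
rejects bands that carry none. It does not show performance under
realistic head geometry, inter-subject anatomical variability,
vigilance-state changes, or physiological noise beyond drift and white
noise, none of which the generator models.

## Known limitations

* The forward model is a homogeneous-conductor stand-in; no claims about
  real-head localization accuracy follow from it.
* The non-adaptive AAS+OBS cleaning assumes reliable markers; drifting
  slice timing beyond the sliding-average window is not handled.
* MDL model orders at desk scale are not meaningful (the suite treats
  them as logged values, not assertions) — only at paper-scale
  dimensions does the criterion produce orders in the tens.
* BY-FDR at desk scale is conservative: with ~600 jointly corrected
  tests and 10 subjects, Dice values of 0 occur in a minority of runs
  purely from the correction's strictness, which is why the end-to-end
  criterion is a majority-of-studies statement rather than a per-run
  guarantee.
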