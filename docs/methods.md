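# Methods

This note documents the models, conventions and numerical choices
behind `erpcompare`, and what the synthetic-data tests do and do not
establish about real recordings.

## The measurement model

The pipeline targets a three-group visual paradigm: abstract objects
presented on a desktop monitor (PC), in immersive VR, or as physical
objects (RL); 33 subjects per group, 80 trials, two consecutive
presentations per object, 128-channel EEG at 512 Hz, epochs −500 to
+1500 ms around stimulus onset.  t = 0 is defined as the onset of the
door-opening event that reveals the object; the ~150 ms door travel is
not added to latencies, so all latencies are relative to that single
reference.

### ERP quantification

1. Trials are averaged within subject, then subjects within
   condition × presentation (grand average), so subjects weigh equally.
2. An RMS time course over all electrodes and conditions localises the
   three components without favouring any condition.
3. Per subject, the ROI-mean waveform (default occipito-parietal ROI:
   O1, Oz, O2, PO3, POz, PO4, P3, Pz, P4; overridable) is searched for
   the signed extremum within each component window — defaults P1
   70–170 ms, N1 110–230 ms, P2 200–330 ms, chosen to bracket the
   group-mean latencies the generator uses (120–137, 155–188,
   259–274 ms) with margin for between-subject spread.  Ties resolve to
   the earliest sample; latency is reported at sample resolution
   (1/512 s ≈ 1.95 ms), with no sub-sample interpolation.
4. Amplitude is the mean over the subject's own peak ± 15 ms (closed
   window, exact sample inclusion), so between-condition latency
   differences cannot masquerade as amplitude differences.
5. Peak-to-peak correction: P1 is baseline-referenced as measured;
   N1 is reported as N1 − P1 and P2 as P2 − N1, removing carry-over of
   the preceding component's absolute level.

### Preprocessing

Deviant-channel detection uses the SD of each channel over
trials × samples as the deviance statistic — the criterion is a
channel lying more than k = 2 SDs (over channels) from the channel
mean.  Whether such a rule should operate on SDs, variances or mean
amplitudes is a genuine free choice; SD is used and tested against a
brute-force reimplementation.  Interpolation replaces a bad channel by
the mean of its good nearest neighbours (adjacency from template
montage positions, k = 4); a spherical-spline alternative would be
smoother but needs nothing the analysis downstream is sensitive to.
The average reference, a zero-phase FIR band-pass (0.25–30 Hz, 257-tap
Hamming design applied forward–backward, ~6.6 Hz transition width;
passband ripple < 2% at 10 Hz, > 97% attenuation at 60 Hz) and linear
detrending, and a −500…−300 ms baseline complete the chain.  Zero-phase
application matters: a causal filter would shift peak latencies, the
quantity under study.  Artifact-subspace reconstruction and ICA-based
artifact removal operate on continuous raw data with external
toolchains and are represented by an identity hook (`clean_hook`)
accepting already-cleaned epochs.

### Induced time–frequency analysis

Morlet kernels are Gaussian-windowed complex exponentials with 12
cycles: envelope SD σ_t = n_cycles/(2πf), support truncated at
± n_cycles/(2f), exact zero-mean correction, and amplitude calibration
such that a unit sinusoid at the kernel frequency reads out as
amplitude 1 — the transform therefore reports microvolts.  The default
grid 1–100 Hz in 0.5 Hz steps yields 199 kernels.

The induced (non-phase-locked) response is isolated by subtracting each
channel's trial average from every trial, convolving per trial,
taking magnitudes per trial, and averaging the magnitudes.  The order
is the defining contract: phase-locked activity is removed by the
subtraction, while activity with trial-varying phase survives the
magnitude-then-average path (it would cancel in any average taken
before the magnitude).

The iABR scalar is the mean baseline-subtracted amplitude over
9.5–12 Hz × 410–970 ms × a posterior cluster (Pz, POz, Oz, O1, O2,
P1–P10 plus a 14-electrode ring; configurable).  Baseline
normalisation is subtractive per frequency and channel over
−500…−300 ms; a post-stimulus desynchronization therefore yields
negative values, matching the sign convention of reported iABR
effects.  Only sign and ordering of the iABR are treated as
meaningful; absolute magnitudes depend on this normalisation choice.

Edge handling: a sample is flagged unreliable when the epoch edge lies
within two envelope SDs of the kernel centre (more than ~2% of kernel
mass outside the data).  Under this criterion the 410–970 ms window is
clear of edge effects for all frequencies ≥ 9.5 Hz in a −500…+1500 ms
epoch; note that the *truncated support* (±0.63 s at 9.5 Hz) does
overhang the right epoch edge for the last samples of the window, but
the overhanging Gaussian tail beyond 2σ is energetically negligible.

### Inference chain

* Mixed split-plot ANOVA (between: condition; within: component,
  presentation) with univariate sums of squares; each within effect is
  tested against its own subject-interaction error term.  Mauchly's
  test runs on the pooled within-group covariance of the effect's
  orthonormal contrasts; when it rejects at .05, Greenhouse–Geisser ε
  (trace formula, clipped to [1/(k−1), 1]) shrinks the degrees of
  freedom.  Effect size is classical η² = SS_effect/SS_total (not
  partial η²).  Designs too small to estimate the contrast covariance
  fall back to uncorrected p-values.
* Post-hoc families are the three pairwise comparisons of the groups,
  Bonferroni-corrected at α = 0.05/3 ≈ 0.017.  With raw samples,
  Levene's test (mean-centred, the classical form) gates Welch versus
  Student per pair; with summary statistics Levene is not computable
  and the choice is an explicit flag.
* The JZS Bayes factor integrates the noncentral-t likelihood over a
  Cauchy(0, √2/2) prior on the standardized effect size δ (the common
  default), via adaptive quadrature at absolute tolerance ≪ 1e-6.
  BF₁₀ is computed from the Student t with pooled df even when the
  frequentist test was Welch: with equal group sizes the two t values
  coincide, and the default Bayesian two-sample test is Student-based.
* Summary-statistics mode and raw-sample mode agree to < 1e-10 by
  construction (both reduce to (mean, SD, n)).

## The synthetic-data generator

Each trial is the sum of three parts projected to the scalp through a
smooth occipito-parietal gain profile (Gaussian in chordal distance
from the ROI centroid on the template 10-05 montage sphere; no forward
model):

* **Components.** Gaussian-windowed monophasic deflections.  `width`
  is the FWHM; defaults P1 24 ms, N1 32 ms, P2 48 ms.  These were
  chosen so that adjacent components overlap mildly: with the closest
  configured latency separation (~35 ms between P1 and N1 in the VR
  condition) wider kernels would bias measured peak latencies by
  several milliseconds through tail overlap, which would defeat
  parameter-recovery testing.  Condition-specific latency means/SDs
  are the group values the analysis is meant to recover; amplitudes
  (P1: 5.2/4.6/3.8 µV for PC/VR/RL; N1: −7.2/−5.6/−5.9; P2:
  4.6/8.0/5.0, SDs 1.8–2.2 µV) reproduce the qualitative
  between-condition amplitude orderings (P1 largest for PC, corrected
  N1 most negative for PC, corrected P2 largest for VR).
* **Between-subject structure.** One standard-normal factor per
  subject shifts all three component latencies, scaled by each
  component's SD — individual differences in processing speed move the
  whole complex together.  Independent draws would invert the P1–N1
  order for a noticeable fraction of subjects at the configured SDs,
  which real ERPs do not show; the shared factor preserves each
  component's marginal SD and leaves between-group tests untouched.
  Amplitudes are drawn independently per component from a normal
  truncated at 20% of the mean magnitude on the zero side
  (sign-preserving; an untruncated draw occasionally flips a
  component's polarity and degenerates peak picking).
* **Within-subject jitter.** Per-trial, per-component latency jitter
  (default SD 5 ms) makes the ±15 ms amplitude window non-trivial.  No
  per-trial jitter magnitude is established for this paradigm; the
  value is a documented free parameter.
* **Alpha.** A 10 Hz sinusoid with uniformly random phase per trial
  (hence induced, not evoked), amplitude 3 µV, multiplied by an
  envelope that dips by a condition-specific fraction (PC 0.50,
  VR 0.55, RL 0.30) over 350–1050 ms with 100 ms raised-cosine ramps.
  The depth ordering encodes the qualitative target: least
  desynchronization for real objects.
* **Noise.** 1/f pink noise (spectral exponent 1), per-channel SD
  normalised to 2 µV, independent across channels.

Seeding: one master seed; per-subject streams derive from
(seed, condition index, subject index) through a `SeedSequence`, so any
subject regenerates independently and bit-identically.

**What the generator does not emulate:** volume-conducted channel
correlations (noise is channel-independent), ocular/muscle/cardiac
artifacts, non-stationary drift, realistic head geometry, latency-
amplitude coupling, behavioural responses.  Passing recovery tests
therefore shows the *analysis* is correct and well-calibrated under
the assumed signal structure — not that it is robust to every artifact
class of real EEG (the artifact-removal stages are out of scope here).

## Problem sizes in the test-suite and script

The statistics of interest live at the subject level, so recovery
sweeps keep the full statistical structure (3 × 33 subjects, 80
trials, 2 presentations, configured means/SDs) but run on a 9-channel
montage holding exactly the measurement ROI — spatial dimension beyond
the ROI does not enter ROI-mean statistics.  The 50-replicate recovery
sweep checks that (a) grand-mean recovered latencies sit within ±3 ms
of the configured means and (b) ≥90% of the 300 post-hoc
significance decisions (6 pairs × 50 replicates) match the target
pattern; at the configured effect sizes some single comparisons (e.g.
P1 RL–VR, d ≈ 0.74, power ≈ 0.7 at α = .017) are *expected* to flip in
a minority of replicates, so the match criterion is an aggregate over
decisions, not all-pairs-per-replicate.  ANOVA type-I calibration uses
2000 null replicates (binomial SE ≈ 0.005 at the nominal 0.05).  The
directional iABR check uses 6 subjects per condition and the alpha-band
wavelet grid; it is a sign/ordering property, not a magnitude claim.

## Known limitations

* Neighbour-average interpolation is cruder than spherical splines.
* The Mauchly/GG machinery assumes balanced, complete designs (the
  paradigm is balanced); unbalanced input raises rather than
  reweighting.
* η² is classical; partial η² users must rescale.
* The iABR baseline scheme (subtractive, pre-stimulus) is one of
  several defensible conventions; comparisons across packages should
  check the normalisation first.
* Latencies are sample-resolution; at 512 Hz the quantisation is
  ~2 ms, commensurate with the ±3 ms recovery tolerance.
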