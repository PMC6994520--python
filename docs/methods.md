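# Methods

This note describes the models and procedures implemented in `ebg`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Scientific setting

The electrobulbogram (EBG) is a non-invasive measure of human
olfactory-bulb (OB) activity: four EEG electrodes in a curved row across
the nasal bridge, referenced to the mastoid average, pick up an odor
event-related synchronization (OERS) — a gamma-band (~55–65 Hz) power
increase roughly 100–150 ms after a sniff-triggered odor onset.  The
package implements the complete analysis chain needed to measure, localize
and validate that signal, exercised entirely on synthetic recordings with
known ground truth.

## Volume conductor and lead fields (`ebg.headmodel`)

The head is four concentric spheres (inner to outer: white matter, gray
matter, skull, scalp) with conductivities 0.14, 0.33, 0.01 and 0.43 S/m.
Shell radii are not part of the method's published description; we use
(78, 80, 86, 92) mm, a standard adult geometry, configurable.

The potential of a current dipole is computed by a Legendre-series
expansion.  The free-medium dipole potential is expanded in spherical
harmonics about the sphere center; for each degree *n* the radial
two-point boundary-value problem across the four shells (continuity of
potential and radial current density at each interface, zero radial
current at the scalp) is solved as a 7×7 linear system whose basis
functions are rescaled per shell so conditioning is independent of *n*.
The series is truncated when the relative increment falls below 1e-8
(default cap 200 terms; the largest source eccentricity used, 0.85 of the
inner radius, converges by *n* ≈ 140).  In the equal-conductivity limit
the transfer factor reduces analytically to (2n+1)/n, and the summed
series matches the closed-form homogeneous-sphere potential (generating-
function summation) to better than 1e-6 relative — both are regression
tests.

Coordinates are RAS millimetres with the sphere center at the origin.
Standard 10-20 scalp positions come from the MNE template montage and are
projected radially onto the model scalp sphere; the OB seeds
(±6, 30, −32) are used directly in that frame.  "Radially outward" dipole
orientation means the unit vector from the sphere center through the
source.  Electrode co-registration is a six-parameter rigid fit (Kabsch
SVD, reflections excluded) to ≥3 non-collinear fiducials.

A forward simulation of bilateral radial OB dipoles on a dense scalp
sampling concentrates power at the inferior-frontal scalp around the
nasal bridge, which is the rationale for the EBG electrode placement.

## Synthetic recordings (`ebg.simulate`)

`generate_recording` builds a continuous multichannel session at 512 Hz:

- **OB burst** (Odor trials): 60 Hz cosine, Hann envelope from 100 to
  150 ms post onset, multiplied by the olfactometer concentration ramp
  1 − 0.1^(t/0.2) (90% of maximum at 200 ms).  Phase is locked up to a
  ±0.5 rad jitter.  Default peak moment 40 nA·m per bulb, chosen so that
  a 20-trial session yields Odor > Air OERS in ≳95% of seeded runs
  (mean sensor contrast ≈ 1.6–2 dB) — the study's intended operating
  point; the method itself prescribes no sensor SNR, so this is a free
  calibration of the generator, exposed as `ob_amplitude`.
- **Sniff-locked component** (both conditions): 40 Hz, Hann envelope
  −100..+100 ms around onset, 6 nA·m, projected from the same OB seeds.
- **Background**: 24 random intracranial dipoles with 1/f^α source
  spectra (α = 1.0 by default; the fitted sensor-spectrum exponent over
  2–80 Hz stays within ±0.2 of α) scaled to 15 µV RMS per channel, plus
  0.8 µV white sensor noise, plus 50 Hz line noise (4 µV, coherent with
  smooth per-channel gains).
- **Artifacts** (optional): blinks are 0.35-s raised-cosine transients
  with a frontal spatial profile decaying over 40 mm from the nasion
  (350 µV construction amplitude); muscle events are 0.4-s 55–100 Hz
  noise bursts with a 50-mm lateralized profile (40 µV).  Both exceed the
  detection thresholds by construction.
- Recordings are mastoid-referenced at generation, as acquired.

The congenital-anosmia scenario sets the OB moment to zero and changes
nothing else.  Habituation sessions scale the OB burst by
1 + slope·trial and a midline parietal N1–P2/3 source (60 nA·m initial,
trough at 380 ms, peak at 620 ms) by (1 − decay)^trial; intensity ratings
track the cortical amplitude plus noise on a 0–10 scale.  Retest tables
draw subject effects once (SD 0.25 dB) and session noise independently
(SD 0.433 dB), giving a true average-measures ICC(2,3) of 0.5 around a
mean power of 0.75 dB.

What the generator does **not** emulate: realistic skull anisotropy or
anatomy (spherical shells only), respiration dynamics beyond the fixed
sniff window, eye movements other than blinks, electrode impedance drift,
or inter-subject anatomical variability.  Passing tests therefore
demonstrate correctness of the algorithms and their calibration under the
stated statistical conditions, not field performance on real recordings.

## Preprocessing (`ebg.preproc`)

Epochs span −500..+1500 ms (1025 samples; ≥ 2 s, covering 100 line
cycles).  The chain is epoch → mastoid re-reference → 1–100 Hz zero-phase
Butterworth (order 4, forward–backward) → line removal by least-squares
sine/cosine fit over the whole epoch (exact for integer-cycle epochs;
orthogonal to other integer-cycle content).  Bad channels are flagged
before the notch by z-scoring per-channel 50 Hz power across channels
(z > 3.5) and replaced by the inverse-distance-weighted mean of neighbors
within 50 mm; more than 25% bad aborts.

Artifact trials are flagged from the Hilbert amplitude of band-passed
data, z-scored against the pooled trial/time distribution per channel,
with a trial flagged when any sample on any in-scope channel exceeds the
threshold: muscle = order-8 Butterworth 60–95 Hz, z > 6, all channels;
blink = order-4 Butterworth 2–12 Hz, z > 4, EBG/frontal channels only.
The amplitude envelope is boxcar-smoothed over roughly the band-passed
artifact's effective duration (0.2 s muscle; 0.6 s blink, covering the
transient plus filter ringing) before z-scoring — the standard
z-value detector construction — which suppresses sub-100-ms noise
excursions that would otherwise dominate the false-alarm rate of the
"any sample" rule; epochs are detrended and odd-reflection padded so the
zero-phase filters are free of edge transients.  The detection bands,
smoothing lengths and the pooled z reference are implementation choices
(the thresholds 6 and 4 are fixed by the method); at the defaults the
combined false-flag rate on clean sessions is below 2% with 100%
sensitivity at construction amplitudes.  A caveat: because the artifacts
themselves inflate the pooled variance, z-scores saturate when a large
fraction of trials is contaminated; sensitivity is calibrated at 5
blinks + 5 muscle events per 40-trial session.

Rejection only ever sets a mask with a reason code; retained data are
never modified.

## Time-frequency analysis (`ebg.timefreq`)

Power between 30 and 100 Hz is estimated with a sliding-window multitaper
transform: at each frequency the window spans three cycles (3/f) and
carries two DPSS tapers (time-half-bandwidth (K+1)/2 = 1.5), applied as
complex wavelets by FFT convolution.  Windows that would extend past the
epoch are dropped (NaN), never padded.  The default frequency step is
0.5 Hz (0.1 Hz available; it is pure oversampling given the 3-cycle
smoothing) and the time axis is decimated by 4 (~7.8 ms).

Normalization is matched-amplitude: a unit sinusoid at the bin frequency
reads power 1/2 (its variance) at every frequency.  Note that the
two-taper bank's spectral response is broad (±25 Hz half-bandwidth at
60 Hz) and peaks ~18% below the bin frequency, so a pure tone's argmax
across bins sits below the tone; this is a property of the estimator's
stated parameters, not of the implementation (a single-taper call
localizes exactly).  The broadband gamma target makes this acceptable.
White-noise band power matches the analytic taper response within 10%.

dB maps normalize each trial, channel and frequency by its whole-epoch
mean power (per-trial before averaging; configurable).  The OERS value is
the mean dB over 55–65 Hz × 100–125 ms × the four EBG electrodes ×
retained trials (the wider 100–150 ms window is available).  Inter-trial
phase coherence is the modulus of the trial-mean unit phasor of the
taper-averaged complex coefficients.

## Source localization (`ebg.sourceloc`)

The cross-spectral density (CSD) is estimated on common-average-
referenced data at 60 Hz ± 5 Hz over 100–250 ms post stimulus by tapered
DFT at the exact frequency; the taper count follows the time-half-
bandwidth rule K = max(1, ⌊2TW − 1⌋) (one taper at the default window).

The source space is a regular ≥10-mm grid over a gray-matter probability
volume thresholded at 40%.  A procedural spherical phantom (probability
0.9 inside 70 mm, 5-mm linear edge) stands in for an MRI segmentation; a
NIfTI map can be supplied instead.  The lattice is anchored so the first
anchor point is a node; the two OB seeds are 12 mm apart, which no 10-mm
lattice can contain jointly, so remaining anchors are inserted as extra
nodes.

DICS computes one unit-gain spatial filter per voxel from the pooled
(Odor+Air) CSD — the balanced common filter, so condition contrasts are
not biased by filter differences — with ridge loading of 10% of the mean
CSD diagonal (the "10%" has no stated reference in the method; the mean
diagonal is ours).  Free orientation is handled by reducing the 3×3
projected CSD to its dominant eigenvalue of the real part.  The contrast
is (P_odor − P_air)/P_air.

Two regimes are distinguished.  (a) For sustained in-band sources the
trial-level CSD is well posed and the relative contrast localizes a
right-OB source to the correct node (≤ one grid spacing in ≥95% of runs
at band SNR ≈ 2).  (b) The 50-ms OERS burst contributes too little energy
to the 150-ms trial-level CSD to survive its sampling fluctuations at
desk-scale trial counts, so the pipeline localizes the burst from the
evoked (trial-averaged) CSD; there the Air power is a near-zero residual
and the relative contrast is ill-conditioned, so the peak is taken on the
power difference divided by each filter's white-noise gain (the
neural-activity-index construction, which removes the unit-gain
beamformer's depth bias).

The guided dipole comparison fits the dominant topography (leading
eigenvector of the real CSD) with the forward models of symmetric
bilateral pairs at the OB, anterior piriform (±22, 2, −14), medial OFC
(±6, 42, −16) and primary auditory cortex (±48, −22, 8) — alternative
coordinates are literature-standard defaults, configurable — radially
oriented by default, and reports the captured fraction per site.
Optionally the fit is prewhitened by a noise CSD (the Air condition),
standard practice that stops spatially correlated background from
inflating smooth-but-wrong source models.  A geometric limitation of the
spherical conductor should be noted: the OB and medial-OFC pair patterns
are nearly collinear (subspace overlap 0.93 raw, 0.62 whitened), so this
comparison separates the OB cleanly from piriform and auditory sources
(whitened overlaps ≈ 0.05) but can exceed the medial OFC by at most
~1.6×; distinguishing those two sites requires realistic head geometry.

## Statistics (`ebg.reliability`, `ebg.habituation`)

The Odor-vs-Air contrast uses a Monte-Carlo permutation test (default
1000 permutations): per-subject condition labels are randomly exchanged
(sign flips of the paired difference; an unpaired trial-label variant is
provided for single-subject contrasts) and the two-tailed t statistic
recomputed.  The p-value is the add-one estimator
(1 + #{|t*| ≥ |t|})/(B + 1), which is valid where the raw exceedance
fraction can be zero.  No multiple-testing correction is applied across
time-frequency maps; replication across independent sessions is the
intended guard.

Reliability across sessions: ICC(2,k) — two-way random effects, absolute
agreement, average measures — from the ANOVA decomposition, with the
between-subject test F = MS_rows/MS_error on (n−1, (n−1)(k−1)) df
(the convention of McGraw & Wong and of pingouin, against which the
implementation is cross-checked); pairwise Pearson correlations;
per-session Cohen's d with noncentral-t 95% CIs; fixed-effect
(inverse-variance) pooled d with var(d) = 1/n + d²/2n; dispersion
Q = Σ w_i (d_i − d̄)², distributed as χ²(k−1) under homogeneity (its mean
calibrates to k−1 = 2 within ±0.3 over 1000 simulations); and the
standard error of the session-mean power across sessions.

Habituation: a linear mixed model (trial fixed slope, subject random
intercepts, ML; degenerate random-effect fits fall back to pooled OLS
with a warning) tests the per-trial OERS trend and the N1–P2/3
peak-to-peak trend; an early/late split-half permutation test (extra
trial to the early half) complements it.  ERP peaks are the most negative
sample in 250–500 ms (N1) and most positive in 450–900 ms (P2/3) of the
1–7 Hz band-passed Pz signal — windows and band are conventional choices,
configurable.  The validation property is the dissociation: with a flat
OB and a decaying cortical source, the OERS trend CI covers zero while
the ERP trend CI is negative, jointly in ≥80% of seeded runs.

## Problem sizes of the validation studies

Chosen so the full suite runs comfortably on a single CPU: source
recovery 10 runs × 80 trials × 68 channels × ~1800 voxels; permutation
calibration 1000 null simulations × 1000 permutations at n = 8; ICC
recovery 500 tables × n = 50 per target; Q calibration 1000 replicates ×
n = 18 × 3 sessions; habituation dissociation 50 runs × 3 subjects × 24
trials (32+4 channels); anosmia null 50 single-subject runs × 40 trials;
dipole comparison 50 runs × 3 pooled subjects × 40 trials (64+4
channels); detector rates over 150 artifact injections (15 sessions ×
5 blinks + 5 muscle events) and 600 clean trials.  The reproduction script uses the same scenarios (30 runs for
the three long studies).

## Known limitations

- Spherical geometry: no skull holes (cribriform plate), no realistic
  OB-to-electrode proximity; OB-vs-mOFC source discrimination is
  geometrically capped (above).
- The two-taper, three-cycle transform trades frequency localization for
  temporal resolution by design; single-frequency effects are smeared
  over ±25 Hz in the gamma band.
- Trial-level DICS of brief low-energy bursts is fluctuation-dominated;
  the evoked route assumes partial phase locking (which the generator,
  and the reported OERS phase-locking, exhibit).
- The artifact detectors' pooled z-scores saturate at high contamination
  fractions; heavily contaminated sessions need iterative or robust
  variance estimation, which is out of scope.
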