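# Methods

`preyscope` reconstructs, as tested library code, the analysis chain of a
tethered-larval-zebrafish virtual hunting experiment: binocular eye
tracking during presentation of a factorial moving-spot panel, two-photon
calcium imaging of the optic tectum at 1.8 Hz, and the statistics that
link stimulus features to hunting initiation and to tectal population
activity.  Because no such dataset ships with the package, a synthetic
experiment generator with full ground truth stands in for the rig; every
analysis stage is validated by recovery of what the generator planted.

## Stimulus model

Sixteen moving spots form a 2×2×2×2 factorial over direction
(left-to-right = 1), speed (fast 30°/s = 1, slow 15°/s), size (large
13.2° = 1, small 3.5°) and contrast polarity (dark on bright = 1).  Spots
appear 100° lateral and sweep 200° at constant speed (13.33 s slow, 6.67 s
fast).  Two whole-field flashes (dim, bright; 3 s) complete the 18-stimulus
panel.  One stimulus is shown per 32 s epoch; per focal plane each stimulus
repeats 5–8 times in a seeded pseudo-random order.  Dark-spot epochs raise
the background luminance from 2 s before spot onset to 2 s after offset.
The spot appears 4 s into the epoch, leaving a ≥2 s imaging baseline even
after the background step.  Geometry is collapsed to one azimuth dimension
(elevation fixed); Weber contrast is carried as metadata only.

## Oculomotor simulator

Eye positions are sampled at 60 Hz, nasal-positive per eye, so the
vergence angle is the sum of the channels.  Per spot epoch, at most one
evoked convergent saccade is drawn Bernoulli with probability
`logit⁻¹(−6.51 + 1.33·size + 1.87·polarity + 0.90·speed·size·polarity)`,
timed to the moment the spot crosses an azimuth drawn from a truncated
normal centred at −5.6° (SD 30°, limits ±90°).  Spontaneous convergences
are Poisson at 1.89 events/hr, placed outside stimulus windows.

Each saccade is a sigmoidal nasal rotation in both eyes with a short
amplitude-dependent duration (20 ms + 1.5 ms/deg, emulating the saccadic
main sequence), onset asynchrony uniform in [0, 80] ms, a 1 s vergence
plateau and an exponential release (τ = 0.8 s).  The vergence increment is
drawn from a normal with mean 19.03° and SD 9.3°, truncated **two-sided and
symmetrically** to mean ± 10°: the symmetric truncation preserves the mean
exactly while excluding unphysical near-zero or negative "convergences"
that no detector should be asked to find.  For evoked events the eye
contralateral to the spot receives an additive 3° amplitude bias (split
±1.5° about the even division).  Fixation/measurement noise is white with
SD 0.15°, typical of infrared video-oculography at this rate.

## Saccade detection and kinematics

Candidate onsets are raw first-difference velocity crossings (>60°/s
nasal); at 60 Hz a saccade spans 1–3 samples, so smoothing before the
velocity gate would hide small events.  A convergent saccade requires
suprathreshold candidates in both eyes within 150 ms, a confirmed nasal
displacement of ≥3° per eye (post- minus pre-window means, 200 ms each),
and a 1 s refractory interval; the onset is the earlier eye's crossing.
The 3° displacement gate sits just below the smallest amplitude the
simulator produces (~3.5°/eye for the least asymmetric floor event), so
the amplitude distribution is not censored, while remaining ≈20 noise SDs
above a 200 ms window mean at the default tracker noise.  Peak nasal
velocity is the maximum derivative of a 50 ms-smoothed trace within 400 ms
of onset.  On traces up to 10⁴ samples the detector is pinned to an
exhaustive brute-force implementation of the same rules.

## Behavioral response model

Response rate per stimulus is the fraction of its epochs containing an
evoked saccade.  The logistic model of per-trial response on the four
binary features is fitted by maximum likelihood (binomial GLM on
per-stimulus counts — the identical likelihood, orders of magnitude
faster), with Wald 95% CIs and odds ratios `exp(β)`.  Forward stepwise
selection over the 15 main effects and interactions up to fourth order is
scored by a cross-validated R²: trials are halved (stratified by
stimulus), the model fitted on one half, and its predicted per-stimulus
rates scored against the held-out half's observed rates; the term whose
addition improves mean cvR² by >0.01 is accepted.  A caveat documented in
the test suite: rate-space R² is insensitive to coefficient structure that
moves only near-zero rates, so predictively equivalent term sets (e.g.
`{polarity, size:polarity, speed:size:polarity}`) can be selected in place
of the generating `{size, polarity, speed:size:polarity}`; tests therefore
assert predictive equivalence, not term identity.

Angular prey geometry uses `2·atan(size/2d)` for subtended size and the
small-angle rate `speed/d` for angular speed (a 135 μm object 0.5 mm away
subtends ≈15°).

## Imaging front end

Frames per epoch = ⌊32 s × 1.8 Hz⌋ = 57; the residual 0.6 frame is dead
time.  Registration is rigid per-frame translation against a running-mean
template (phase cross-correlation, shifts clipped at 20 px).  Segmentation
thresholds the temporal-activity map (per-pixel SD over time), labels
connected components, and splits oversized blobs by watershed on the
distance transform; masks are kept within soma-scale area bounds.  ΔF/F
baselines each epoch on the mean of its first 3 frames (all stimuli start
≥2 s into the epoch); a rolling-percentile baseline is selectable.  A cell
is *visually responsive* when, for at least one of the 18 stimuli, the
per-trial window-peak vs baseline paired t-test gives p < 0.05 **and** the
peak rep-averaged response exceeds 3 baseline SDs.  No multiple-testing
correction is applied across stimuli, mirroring the "at least one
stimulus" criterion; the resulting false-positive rate on pure noise
(empirically ~0.2 at 3 reps) is quantified in the tests and is why
population-level claims rest on the planted ground truth, not on the raw
responsive count.

## Visual response vectors and clustering

A VRV concatenates the rep-averaged ΔF/F of the first 38 frames of each of
the 18 stimuli (684 points), normalized by its SD.  Clustering is greedy
seeded-centroid: the cell with the most neighbours at r ≥ 0.75 seeds a
candidate; membership (correlation-to-centroid ≥ 0.75) and centroid are
iterated to a fixed point; candidates survive only with ≥6 cells from ≥6
fish; members of accepted clusters are removed and the search repeats.
The r ≥ 0.75 member contract is asserted exactly.  Selectivity indices use
`SI = (R_pref − R_flip)/(R_pref + R_flip)` on rectified peak responses,
where `R_pref` is the panel maximum and `R_flip` the response to the
stimulus with the queried feature bit inverted, signed so positive means
preference for bit value 1.  Rectification avoids division pathologies for
suppressed responses.

## Non-linear mixed selectivity

Six binary regressors over the 16-spot panel — all selective for large,
dark spots, with/without speed and direction selectivity (nDS-nSp, nDS-Sp,
R2L-nSp, R2L-Sp, L2R-nSp, L2R-Sp) — are correlated against each ROI's
peak-response 16-vector; ROIs join the best regressor when r ≥ 0.75.  Two
5-parameter least-squares models of per-trial peak response are compared
by cross-validation over random halvings of the reps (20 splits): a linear
model on the four features, and a non-linear model on
`{size·pol, speed·size·pol, dir·size·pol, dir·speed·size·pol}`.  The
third interaction is the one reconstruction choice: it completes parameter
parity while carrying speed-independent direction selectivity.
`SI_nlin = (cvR²_nlin − cvR²_lin)/(|cvR²_nlin| + |cvR²_lin|)` (0 when the
denominator vanishes).  Receptive-field centres are circular means of the
spot azimuth one frame before each responsive stimulus's response peak,
corrected by the mean gaze azimuth of the eye contralateral to the ROI's
hemisphere (the retinotectal projection is fully crossed; nasal-positive
angles convert to screen azimuth with opposite signs for the two eyes).

## Premotor assemblies

For each convergence the pre-conv window is the 3 frames (≈1.65 s) ending
one frame before the saccade frame; the peri-conv window the 5 frames
(≈2.75 s) centred on it.  The saccade frame is the imaging frame containing
the saccade onset (floor division of the eye clock onto the frame grid).
For evoked events, a cell's response-trial window mean is tested against
the window means of non-response trials of the same stimulus with a
one-sided prediction-interval t statistic
(`t = (x̄_resp − x̄_null)/(s_null·√(1+1/n))`): with exactly one response
trial per event, pooling frames would let the within-window variance of a
partial-window burst mask arbitrarily large responses, while the
prediction-interval form stays calibrated (null false-positive rate ≈ α in
simulation).  SNR is the peak windowed signal in units of the pooled
non-response frame SD; modulation requires p < 0.05 and SNR > 3.
Spontaneous convergences are tested within-epoch against the remainder of
the 32 s epoch.

Assemblies are detected per hemisphere among modulated SPV cells: a 2-SD
covariance ellipse is fitted to the centroids; while area/n exceeds
533 μm²/cell the most Mahalanobis-distant cell is dropped and the ellipse
refitted; an assembly requires ≥6 cells at compliant density (boundary
values accepted; collinear sets get a 1 μm semi-axis floor).  The
population lead time max-normalizes each member's epoch trace, averages,
thresholds at baseline mean + 2 SD, and reports the onset of the
contiguous suprathreshold run ending at the saccade frame — identical to
the earliest-crossing rule on clean data but immune to isolated baseline
noise crossings.  Intra-assembly correlation is the median leave-one-out
Pearson r of each member against the mean of the rest.  The false
discovery rate circularly shifts every ROI's full trace by one common
seeded offset (≥2 epochs) per permutation — preserving inter-cell
correlations while destroying event alignment — re-runs the identical
detection, and reports mean shuffled count / original count over 5
permutations.  Oculomotor laterality uses paired t-tests of the eye
ipsilateral vs contralateral to each assembly (post-saccadic position,
position change, peak velocity); anterior-posterior trends are independent
OLS fits of an eye parameter against the assembly centre's distance from
the posterior-commissure landmark, per tectum.

## Synthetic population

ROIs are planted in a 2-D region map (left/right tectal SPV and neuropil
bands, habenulae, midline torus longitudinalis; shapely polygons;
non-overlap asserted).  Archetypes: luminance-ON cells (41% placed in the
TL), dimming detectors, luminance-inhibited cells, mirror pairs of
direction-selective large-bright-spot clusters whose response latency
follows the retinotopic sweep, the six NLMS classes with frontal receptive
fields, premotor assembly cells, and non-responsive cells.  Latent drives
are built on the frame grid — sustained boxcars, or Gaussian bumps
(σ = 0.7 s) at the moment the spot crosses the cell's RF azimuth — and
convolved with a peak-normalized difference-of-exponentials indicator
kernel (rise 0.1 s, decay 1.5 s, sampled at frame centres so an onset
frame is non-zero), with white noise (SD 0.08) added.  Convolution is
per-epoch by default (no cross-epoch carryover), which makes rep averages
and pre-stimulus baselines exact for recovery tests; full-session
convolution is available.

Assembly cells burst from `lead` frames (1–3) before their designated
saccade frame through `lead`+4 frames, in the response trial only; each
assembly is paired with a convergence whose contralateral eye lies on the
assembly's side, emulating the ipsilateral bias of tectal premotor output.
Members additionally carry weak (0.5×) visual tuning to one random
small/bright spot each, with individual RF azimuths: this keeps them
visually responsive without giving the group coherent visual
co-activation, which would both contaminate lead times in trigger trials
and inflate the permutation FDR.

What the generator does **not** emulate: photon/shot noise, bleaching,
neuropil contamination, non-rigid motion, correlated network background,
tail/locomotor behaviour, 3-D screen optics.  Passing recovery tests
therefore demonstrates correctness of the analysis logic under the stated
noise model, not robustness to every artifact of real recordings.

## Problem sizes and numerical choices

The bundled analysis scripts use 6 focal planes × 5 reps (540 epochs) and
~400 ROIs; the test fixture uses one plane × 8 reps with behavioral
response probabilities raised to ~40–50% for large/dark stimuli so a
144-epoch session contains enough evoked convergences for event-triggered
statistics (at the naturalistic 5–10% best-stimulus rate, thousands of
epochs would be needed per test).  Coefficient-recovery checks run at
20,000 trials per stimulus, where the polarity coefficient's standard
error is ≈0.05; the acceptance test averages five replicate refits to test
unbiasedness at that tolerance.  Ties in regressor assignment break in the
fixed key order; zero-variance vectors are unassignable; all random
operations take explicit integer seeds and identical seeds reproduce
byte-identical outputs.

## Known limitations

Segmentation and the visually-responsive criterion are stated stand-ins
for unpublished originals; the exact SI and clustering formulas are
likewise reconstructions, parameterized so alternatives can be swapped in.
The stepwise selector can return predictively equivalent rather than
literally identical term sets (above).  Real-data entry points (TIFF
stacks, CSV eye traces, HDF5/NPZ trace stores) are format-complete but
have only been exercised on synthetic data.
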