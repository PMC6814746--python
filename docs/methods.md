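# Methods

`caspike` quantifies single nuclear Ca²⁺ transients ("spikes") in per-cell
fluorescence time series from plant root tips, classifies the compartment
of signal origin from paired nuclear/cytosolic recordings of a
dual-localised sensor, and aggregates per-plant and per-genotype
statistics. A seeded simulator with exact ground truth provides the
validation substrate. This note records the model, the numerical choices,
and what the tests do and do not establish.

## Signal model and pipeline

A raw trace is a non-negative fluorescence series F(t) sampled every 2–3 s
for roughly 1–1.5 h. The pipeline:

1. **Normalization.** ΔF/F = (F − F₀)/F₀ with F₀ the mean of the first
   `n_baseline` = 20 frames. By construction the baseline window of the
   normalized series has zero mean, and ΔF/F is invariant under
   multiplicative rescaling of the raw intensities.
2. **Detrending.** An ordinary-least-squares polynomial in time (default
   cubic, configurable 0–5) is subtracted. A cubic absorbs slow drift
   (photobleaching, focus creep) over a 1.5 h recording without absorbing
   ~40 s transients. Because polynomial fitting commutes with the affine
   map F ↦ (F − F₀)/F₀, detrending the raw fluorescence and then dividing
   by F₀ is algebraically identical to detrending ΔF/F; both orders are
   offered (`detrend_target`), and the default operates on ΔF/F so that
   thresholds are dimensionless.
3. **Gradient.** Central differences (one-sided at the edges) divided by
   the frame interval, in ΔF/F · s⁻¹.
4. **Peak.** The maximum of the detrended signal; ties break to the
   earliest frame.
5. **Pulse boundaries.** Scanning outward from the peak, the onset
   (offset) is the first frame before (after) the peak at which the
   detrended signal and the magnitude of its gradient are both at or below
   their thresholds. A scan that reaches the trace edge flags that
   boundary as *censored*; censored calls are reported but excluded from
   cohort shape statistics.
6. **Shape.** rise = peak − onset, fall = offset − peak, duration is
   *defined* as rise + fall (the identity holds bit-exactly), amplitude is
   the detrended value at the peak.

Thresholds are multiples of a per-trace robust noise scale, the
normal-consistent median absolute deviation (1.4826 × MAD), so one set of
multipliers serves traces of any brightness. Per-trace (rather than
global) scaling is the default because illumination and expression level
vary between cells.

## Detection and boundary refinement

`detect_spikes` smooths the detrended series with a short Savitzky–Golay
filter (window 9 frames, polynomial order 2) before candidate gating and
boundary scanning. The smoothing is essential at realistic noise: the
maximum of ~2700 frames of white noise reaches ≈4σ, while a transient five
noise scales high only reaches ≈5σ at a single frame, so an unsmoothed
amplitude gate cannot separate the two reliably; after smoothing the
transient (which spans many frames) retains most of its height while the
noise scale drops by half. Candidate peaks are processed highest-first:
each candidate above `amp_mult` = 5 noise scales is scanned for
boundaries, the spanned interval is masked, and the process repeats, which
generalises to multiple well-separated pulses even though one spike per
responding cell is the expected biology.

The raw threshold scan localises boundaries coarsely: it stops where the
signal crosses the threshold partway up the limb (a bias proportional to
limb duration) or, on steep limbs, overshoots into baseline because the
gradient criterion fails until past the corner. Each call is therefore
refined:

- a line is fitted to the central 10–90% band of each limb of the smoothed
  transient and extrapolated to baseline — exact for a piecewise-linear
  transient — with the extrapolation distance shrunk by the second-order
  ratio-correction 1/(1 + (σ_m/m)²) for the noisy fitted slope m;
- the refined boundary may pass the scan bound by at most 25% of the limb
  span, and only when the signal at the scan bound is still above half the
  signal threshold (evidence that the scan stopped on the limb rather than
  in baseline);
- the peak time is moved a damped (0.7), capped (6 s) step toward the
  intersection of the two limb lines, correcting the drift of a noisy
  argmax toward the shallower limb.

An optional plug-in debiasing step (`debias=True`) evaluates the full
scan-plus-refinement estimator on a noiseless tent with the call's
estimated shape and thresholds and subtracts the resulting deterministic
error. It removes the residual deterministic bias on long shallow limbs
(≈0.8 s at a 24 s fall) but the correction reacts to the noisy shape
estimates and inflates boundary error variance; it is off by default
because the default configuration prioritises mean absolute boundary
error.

Default multipliers — signal threshold 1.0σ̂, gradient threshold 1.5σ̂_g,
amplitude gate 5.0σ̂ — and the refinement constants were fixed by
simulation-based calibration against tent transients with known onsets
(rise/fall 10–30 s, peak amplitude five noise scales, 2 s frames, cubic
drift). Under those conditions the detector misses no spikes, produces no
false positives away from trace edges, and recovers rise and fall times
with mean absolute error ≈3.3–3.8 s (under two frame intervals). The
residual mean bias is ≈ +0.7 s on a 15 s rise and ≈ −0.7 s on a 24 s fall;
threshold-crossing estimators at this sampling density and noise level
could not be pushed below roughly ±0.7 s in any configuration explored,
which should be kept in mind when comparing sub-second kinetic differences
between conditions.

Degenerate inputs: a peak already below threshold yields a zero-width
pulse, rejected by the minimum-duration rule (default two frame
intervals); traces whose detrended residual is at machine-noise level
(robust scale below 10⁻¹² of the signal range) yield no calls; boundary
scans that exhaust the trace yield censored calls, and calls censored at
both ends are discarded.

## Origin classification

Whether a transient originates in the nucleus or arrives from the cytosol
is decided by onset order: lag = t_on(cytosolic) − t_on(nuclear), with
lags within one frame interval reported as indistinguishable and cells
with a call in only one channel as unpaired. Onset order (not peak order)
is used because diffusion and buffering reshape the rising limb more than
they shift initiation. Within a cell, nuclear and cytosolic calls are
paired greedily by nearest peak time, which is deterministic and adequate
for the single-spike regime. With noiseless channels a programmed
two-frame nuclear lead is classified nuclear-first without error; at peak
signal-to-noise 5, independent onset jitter of ~3 s per channel against a
4 s lag limits single-cell classification accuracy to roughly 60–70%, so
noisy per-cell origin calls should be aggregated before interpretation.
Cross-correlation lag estimation, which would do better, is deliberately
out of scope.

## Cohort statistics

Per plant: responder status (≥1 accepted nuclear call), the count of
accepted nuclear calls from cells within a reference span of the root tip
(default 200 µm, implemented as a counting window; a rate-rescaling mode
is available), and the spike rate per hour. Per cohort: the responder
percentage, the meristem/elongation partition of calls (a cell exactly on
the boundary counts as meristematic), arithmetic means ± SD of rise, fall
and duration over uncensored nuclear calls, and the OLS line of
primary-root growth rate (cm/day between days 3 and 5) against spike
rate, fitted on all matched plants with no outlier handling. Hypothesis
tests are out of scope; the module emits the tables such tests would
consume.

## Synthetic data

The generator emulates the recording statistics of root-tip confocal
time-lapse experiments: F(t) = f₀·(1 + drift(t) + Σ kernels) + noise, with
a gentle cubic drift (≈5% over the recording), additive Gaussian noise
(an optional Poisson shot-noise mode exists), and at most one transient
per responding cell. Defaults encode the study conditions: 2 s frames over
5400 s; wild-type kinetics Gaussian around 15.4 s rise and 24.1 s fall
(dispersions 4 and 6 s — plausible biological spreads, not measured
values — truncated at two frames); peak amplitude 0.5 ΔF/F with noise
0.1 ΔF/F (signal-to-noise 5); the cytosolic channel lagging the nucleus by
two frames at 80% of the nuclear amplitude; responder probability 0.6;
Poisson(5 × hours) spiking cells per responder plant; 80% of cells within
the 200 µm meristem boundary. The tent kernel (piecewise linear) is the
default because its onset/peak/end are analytically exact ground truth; a
double-exponential kernel is provided for realism, with ground-truth
boundaries defined as the 5%-of-amplitude crossings. Mutant presets
(`low_frequency`, `slow_kinetics`) encode direction of effect only —
frequency reduced, kinetics slowed by invented multipliers — and are not
quantitative models of any genotype.

All randomness derives from `numpy` `SeedSequence` spawning, so a fixed
seed reproduces every trace, table and TIFF byte-for-byte.

What the simulator does **not** emulate: motion and registration error,
focus drift beyond a smooth polynomial, photon-noise heteroscedasticity
coupled to signal level (unless the Poisson mode is chosen), overlapping
or bursting transients, cell-to-cell amplitude variability, and spatial
crosstalk between the two sensor channels. Passing recovery tests on
synthetic cohorts therefore demonstrates correctness of the estimators
under the stated noise model, not performance on raw microscope output.

## Imaging front end

The in-scope portion of image preprocessing: plain multi-page grayscale
TIFF stacks (one per channel, frame order = time order), background
subtraction (constant level, or per-frame percentile to track slow
illumination changes), and per-frame mean intensity over circular ROIs (a
pixel belongs to an ROI when its centre is within the radius). Extraction
is linear and commutes with exact background subtraction away from the
zero-clip floor. The stack simulator renders each nucleus as a Gaussian
blob whose brightness follows a simulated trace, closing the loop from
pixels to spike calls in tests. Registration, segmentation and tracking
are out of scope.

## Problem sizes used in validation

The test suite and the reproduction script use 200 single-spike traces for
boundary-recovery benchmarks, 50-plant cohorts (20 cells per plant, both
channels) for end-to-end statistics, 1000 series for peak-oracle
equivalence and 100 for boundary-oracle equivalence — sizes at which the
binomial and standard-error bounds quoted in the tests are meaningful
while the whole suite completes in a few minutes on one core.
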