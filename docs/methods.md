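# Methods

This note documents the models implemented in `neuromove`, the
parameter choices that matter, what the synthetic data do and do not
emulate, and the numerical decisions taken where the design was open.

## Study design assumed by the pipeline

Each session cell is a block design: 20 s of task alternating with 20 s
of rest. Reaching blocks contain five movements paced by 4 s vocal
prompts ("go" 2 s, "stop" 2 s); steering is continuous circular cursor
motion inside a 2 cm tunnel around a circle of 33-inch circumference
(R₀ = 838.2/2π ≈ 133.4 mm). Cells are crossed over task (reach, steer),
hand (dominant/non-paretic vs non-dominant/paretic — the paretic hand
occupies the non-dominant slot) and, for reaching, condition
(spontaneous arm use, SAU, vs maximal arm use with the trunk
restrained, MAU). Default block count is three per cell. Recordings
include a 20 s rest lead-in before the first block so that pre-onset
baselines and filter settling exist for every block; schedules start at
t = 0 with the first task interval.

## Kinematics

Joint positions arrive at 30 Hz in a right-handed frame (+y up, +z
anterior). Trunk flexion is the angle of the spine-base→shoulder-centre
vector from vertical, projected into the sagittal plane (atan2 of the
anterior over the vertical component, so 0° is upright and leaning
toward the target is positive). The elbow angle is the interior angle
at the elbow between the vectors to the acromion (side of interest) and
to the wrist; 180° is full extension. Both operators are pure per-frame
geometry, invariant to translation (and, for the elbow, any rigid
transform).

Before metric extraction, joint trajectories are low-passed with a
zero-phase 4th-order Butterworth at **2 Hz**. The paced movement cycle
is 0.25 Hz and essentially all movement energy lies below ~1.5 Hz, while
range statistics (max − min within a 2 s segment) are extreme-value
statistics whose bias grows directly with per-frame angular noise;
smoothing at 2 Hz keeps marker noise of a few millimetres from
inflating ranges by more than ~1°. Gaps of up to 3 consecutive missing
frames are linearly interpolated; longer gaps leave NaNs that exclude
the affected frames.

Per outward segment (cue → cue + 2 s, clipped to its task interval):
trunk and elbow ranges are max − min of the angle series (the "range
of" reading; percentile ranges were deliberately not used), hand mean
velocity is the mean frame-to-frame speed of the hand joint, and arm
use is

AU (%) = 100 · (hand forward displacement − acromion forward
displacement) / hand forward displacement,

with displacements taken as max − min of the anterior coordinate within
the segment. PANU = AU(MAU) − AU(SAU), computed per hand; segments with
non-positive hand forward displacement are excluded from AU, and a
negative PANU (less arm use when forced) is allowed and flagged rather
than clamped. This AU construction operationalizes "trunk share of the
forward reach"; it is isolated in one operation so an alternative
definition can be swapped without touching anything else.

Steering metrics come from the radius r(t) and unwrapped polar angle
θ(t) about the circle centre: R = mean r, σ = SD r (ddof = 1),
We = √(2πe)·σ, laps = |Δθ|/2π (fractional laps allowed — 20 s trials
rarely end on a lap boundary), speed = laps/duration, MT =
duration/laps, IDe = 2πR/We, IPe = IDe/MT, bias = We/W, and the error
rate is the fraction of samples more than W/2 from R₀. **MT is the
time per lap**, not the total trial time: IPe is a rate in bits/s and
the reported speed variable is time per lap, which makes IPe
independent of trial duration. Degenerate inputs follow an explicit
contract: σ below 1 nm is treated as exactly zero (We = 0, IDe/IPe
reported as NaN, never infinity); zero laps leaves MT undefined.
Per-block metrics are averaged across a cell's blocks.

## fNIRS

The modified Beer–Lambert law is solved per channel and sample:
ΔOD(λ) = ε(λ)·Δc·d·DPF with d = 30 mm source–detector distance and
DPF = 6.0 for both wavelengths (760/850 nm). Extinction coefficients
(µM⁻¹·cm⁻¹) are embedded as a named constant table
(Gratzer/Cope values) and are config-overridable; the 2×2 system is
checked for invertibility. The inversion is linear and exactly inverts
the synthetic forward model.

Channel quality control rejects channels whose intensity proxy
(10^(−ΔOD)) has a coefficient of variation above 15% at either
wavelength. Optional motion correction (median-absolute-deviation spike
detection with cubic-spline replacement) defaults off for synthetic
data and on for imported recordings.

Event-related filtering targets the 0.01–0.1 Hz band. The low-pass side
is a zero-phase 3rd-order Butterworth at 0.1 Hz. The high-pass side is
**linear detrending rather than a recursive 0.01 Hz high-pass**: at
10 Hz sampling a 0.01 Hz pole rings with a ~100 s time constant, so on
120–160 s records its edge transient contaminates most of the signal
(a 1.1 Hz probe sine still shows 4–9% residual mid-record), whereas
components below 0.01 Hz complete less than one cycle on such records
and are captured by a linear trend plus the per-epoch baseline
correction. The ~3 s settling of the 0.1 Hz corner is absorbed by the
20 s rest lead-in.

Epochs span −2…+20 s around each task onset, are baseline-corrected by
the mean of −2…0 s, averaged across the cell's blocks (truncated epochs
are excluded with a warning), and summarized by the maximum ΔHbO₂ in
0…20 s — the peak is reported as-is, so a strictly negative epoch
yields its negative maximum. Channel peaks are averaged within
hemisphere, and hemispheres are labelled by role: opposite the moving
hand = contralateral; for stroke subjects the lesioned hemisphere is
additionally ipsilesional (equal to contralateral when the paretic hand
moves and the lesion is contralateral to it).

## EEG

Preprocessing is a zero-phase 4th-order 1–40 Hz band-pass with optional
common-average re-referencing (default on). Epochs whose absolute
amplitude exceeds 100 µV (synthetic scale) are rejected; more than 50%
rejected epochs raises an error naming the session.

The ERSP uses a sliding 1 s Hann window with 90% overlap. The baseline
is the mean rest power per frequency and channel, using only STFT
frames fully inside "clean rest" (rest intervals excluding the first
5 s after task offset, where the post-movement rebound lives, plus the
lead-in). Epochs span −5…+24 s around block onsets and are **averaged
in the power domain before conversion to dB**: the log of a noisy power
estimate is biased low (≈ −0.76 dB for 3 epochs, −0.11 dB for 20), so
dB-averaging per epoch would systematically deepen every estimate,
while power-averaging leaves the map unbiased.

Band summaries (alpha 8–13 Hz, beta 14–29 Hz) average
baseline-normalized power ratios over a time–frequency window and take
one log. Two support rules avoid mixing regimes: time frames must lie
fully (window support) inside the target interval, and frequency rows
must lie one Hann main-lobe width (1/window length = 1 Hz) inside the
band — otherwise leakage from the neighbouring rhythm (the alpha peak
bleeding into the 14 Hz bin) dilutes the beta mean by several tenths of
a dB at deep ERD levels.

ERD is the mean dB over the movement windows (reaching: 0–2 s after
each cue; steering: the whole block), ERS over the post-movement
windows (reaching: 2–4 s after each cue; steering: 0–4 s after block
offset). The ERS is therefore anchored to a **post-movement latency**,
not to the between-block rest; both windows are configurable and the
choice is recorded in the output metadata (`ers_origin`). Signs are
never clamped.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the acquisition design (rates 30/10/500 Hz,
block structure, montages: 4 fNIRS channels and 4 EEG electrodes per
sensorimotor hemisphere) with controllable ground truth per session:

- **Skeleton**: rigid segments (trunk 500 mm, upper arm 300 mm, forearm
  260 mm, hand 80 mm, half shoulder width 180 mm — adult-scale
  constants recorded in the profile), driven by smooth sin² activation
  profiles per cue; trunk amplitude ≈ 0 in MAU profiles. Gaussian joint
  jitter (default 3 mm) models marker noise. Amplitudes implying elbow
  angles beyond 180° or trunk flexion beyond 90° are rejected as
  non-physical.
- **Cursor**: radius R₀ + white Gaussian radial noise, angle advancing
  clockwise at 2π·lap_rate rad/s, sampled at 60 Hz.
- **fNIRS**: a canonical double-gamma HRF (gamma densities with shape
  7 and 17: peak 6 s, undershoot 16 s, 1:6 ratio) convolved with the
  task boxcar, normalized to unit peak and scaled to the target
  amplitude (ΔHbR = −0.3 × ΔHbO₂), plus sinusoidal cardiac (0.4 µM,
  1.1 Hz), respiration (0.3 µM, 0.3 Hz) and Mayer waves (0.1 µM,
  0.095 Hz — just inside the analysis band, deliberately the hardest
  component), linear drift (±0.5 µM per record) and white noise
  (0.15 µM); everything is pushed through the same extinction matrix
  the analysis inverts, so the no-noise round trip is exact.
- **EEG**: 1/f-power background (3 µV, flattened below 1 Hz) plus
  band-limited Gaussian oscillators (10 µV per band) whose amplitude is
  multiplied by 10^(ERD/20) in movement windows and 10^(ERS/20) in
  post-movement windows, with 100 ms ramps. Prominent idle rhythms
  (oscillator ≫ in-band background) are assumed; with the default
  scaling the background floor biases a −6 dB ERD by ≈ +0.3 dB, within
  the ±0.5 dB recovery target.

Cohorts draw per-subject parameters around healthy baselines;
stroke-like subjects add configured mean shifts on the paretic
(non-dominant) side — more trunk flexion, less elbow use, slower laps,
noisier radius, larger ΔHbO₂ peak, attenuated beta ERD, larger alpha
ERS — scaled by a latent severity factor that also generates the
clinical covariates (FM-UE, WMFT, BBT ratio, BI), so brain–movement and
brain–clinical correlations exist by construction. Contralateral
responses exceed ipsilateral ones (fNIRS ratio 0.65, EEG dB scale 0.7).
Effect magnitudes are configuration, not empirical claims; setting
every shift to zero makes the groups exchangeable, which is how type-I
calibration is tested. Defaults assume complete data (no exclusions).

Not emulated: muscle dynamics or biomechanically realistic motor
variability, EEG volume conduction and channel correlation, lesion
anatomy, motion artifacts in fNIRS (the generator produces none, which
is why motion correction defaults off), and non-stationary noise. A
passing recovery suite therefore shows the pipeline is correct and
calibrated under the stated noise model — not that it is robust to
every artifact of real recordings.

## Statistics

The mixed ANOVA implements the classical univariate decomposition for
one between-subject factor and any number of two-level within-subject
factors on balanced, complete data (incomplete subjects are dropped
listwise per dependent variable). Effects are computed by recursive
mean-centring over factor subsets; each within effect is tested against
its own subject-interaction mean square, between effects against the
subject-within-group mean square. The decomposition satisfies the
total-sum-of-squares identity to 1e-9 (tested), and matches pingouin's
mixed ANOVA exactly on the one-within design. With two-level within
factors sphericity is moot; a guard raises for factors with more
levels. η²p = SS_effect/(SS_effect + SS_error); a constant dependent
variable yields F = 0, p = 1, η²p = 0 rather than 0/0.

BH adjustment is the step-up rule (monotone, capped at 1). Spearman
correlations use average ranks; the partial variant residualizes the
ranks of x and y on the ranks of the covariates plus an intercept and
Pearson-correlates the residuals, with a t-approximate p-value on
n − 2 − k degrees of freedom. The covariate set defaults to empty and
the output always states which variant ran. Zero-variance inputs return
an explicitly undefined (flagged) result. The r² > 0.25 reporting
filter marks at-least-moderate associations.

Repeated-cohort studies (type-I calibration over 200 null cohorts,
power of the Group × Hand trunk-flexion interaction and the Group IPe
effect at n = 21/group) run on **metric-level cohorts**: per-subject
parameters are drawn from the same distributions the session generator
uses and mapped through the steering-law formulas plus small
measurement noise. Signal synthesis and extraction are validated
separately against ground truth (50 full sessions), so repeating them
hundreds of times inside the statistical simulations would only re-test
what is already covered while inflating runtime by orders of magnitude.
Problem sizes used by the default suite and the acceptance script —
3 blocks per session, 50 recovery sessions, 200 cohorts, one full
42-subject run — were chosen as the smallest sizes at which the
binomial/Monte-Carlo error of each check is well below its tolerance.

## Pipeline and formats

The CSV session directory is the canonical interchange format
(schedule.json, skeleton.csv, cursor.csv + geometry.json, od.csv long
format, eeg.csv long format, ground_truth.json for synthetic sessions);
XDF import is not provided. Runs are deterministic under a fixed seed;
every output CSV carries the configuration hash in its header line and
the manifest records window/filter provenance and all warnings
(dropped segments, truncated epochs, rejected channels). A failing
subject is isolated: its error is logged and the rest of the cohort
proceeds.

## Known limitations

- The mixed ANOVA requires balanced two-level within factors; it does
  not provide Type-III handling for unbalanced cell counts or
  sphericity corrections for multi-level factors.
- The AU/PANU construction is one operationalization of trunk-vs-arm
  share; instrumented force or EMG-based definitions would differ.
- Hemisphere summaries assume all four channels of a hemisphere are
  comparable; no channel weighting or short-separation regression is
  applied.
- The ERS window choice (post-movement latency vs between-block rest)
  changes absolute ERS values; compare only within one convention.
- Zero-phase filtering needs the rest lead-in to absorb edge
  transients; trimming recordings to exactly the first task onset will
  bias the first block.
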