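# Methods

This note documents the models, numerical choices and limitations behind
`gaitcoord`. It covers what each stage assumes, which defaults matter and
why, what the synthetic cohort does and does not emulate, and where the
design was genuinely open.

## Signal chain

### Units, filtering

IMU streams are SI internally (m/s², rad/s, µT); the CSV reader converts
from native units (g, deg/s, Gauss) when a `# units: native` header line
is present. All channels pass through a low-pass Butterworth filter,
default 4th order with a 6 Hz design cutoff, applied forward–backward
(`sosfiltfilt`). Zero-phase filtering was chosen deliberately: a causal
pass would delay the hip and knee waveforms by an angle-dependent phase
and corrupt the relative-phase analysis downstream. The cost is a
steeper net response — the squared magnitude of the design — so the 6 Hz
design cutoff is the −6 dB point of the net filter rather than −3 dB.
Whether the filtering should be zero-phase is configurable in principle
(the filter function can be applied once to raw arrays by callers who
need causal behaviour), but every pipeline path uses zero-phase.

### Orientation estimation

Quaternions are Hamilton, scalar-first, sensor-to-world. The world frame
is X anterior, Y vertical (up), Z medio-lateral, chosen so that sagittal
rotations are rotations about Z and fall out of an intrinsic Z–Y–X Euler
decomposition as the first angle. The complementary filter integrates
the gyroscope with a trapezoidal body-rate step and, each sample, moves a
fraction `gain` (default 0.02, i.e. a 0.98 gyroscope weight) along the
geodesic toward the TRIAD attitude built from the accelerometer
(gravity/up reference) and magnetometer (heading reference).
`gain = 0` is pure dead-reckoning. The first sample is initialised from
accelerometer + magnetometer alone. Zero-norm accelerometer samples
contribute no correction and are logged.

Assumptions: quasi-static accelerometer (specific force ≈ gravity) — the
default emission model makes this exact; a homogeneous magnetic field;
uniform sampling. Gimbal proximity (|Y| within 1° of 90°) is logged and
values retained; walking kinematics stay far from it, though the
constant-vertical-rotation regime used in one test does not.

Sensor-to-segment calibration is an open point in this pipeline's
setting: an optional quiet-standing window (`calibration.window_s`)
subtracts the mean angle over the initial window from each joint. It is
off by default because the synthetic cohort emits walking from the first
sample; with real recordings that begin with quiet standing it should be
enabled (0.5 s is a reasonable window).

### Gait events and cycles

Initial contacts are the first negative-going zero-crossing of the
(filtered) sagittal shank angular velocity after each mid-swing peak;
peaks are `scipy.signal.find_peaks` local maxima above a prominence of
0.5 rad/s (well below the ≈5 rad/s mid-swing peak, well above sensor
noise). A `positive_swing` flag flips the convention for mirrored
mountings. Where the original workflow relied on visual inspection and
occasional manual correction, this pipeline substitutes (a) a
physiological duration gate — cycles shorter than 0.4 s or longer than
2.5 s are discarded and logged — and (b) an events-override CSV that
replaces detected initial contacts for named passes.

Cycles are resampled onto 101 nodes (0–100% of the gait cycle, both
endpoints included) by linear interpolation — exact for piecewise-linear
signals, and with ≈200 samples per cycle the interpolation error for
smooth kinematics is far below any tolerance used here. Excursion is
max − min of the *unnormalised* samples of each cycle.

### Continuous relative phase

Each joint's waveform is centred by subtracting (max + min)/2 over the
analysis span — without centring, the analytic-signal phase of an offset
oscillation is meaningless. The analytic signal is built on a padded
series and the pad discarded afterwards, mimicking the practice of
retaining extraneous recording around the span of interest. The default
pad is one median cycle length per side, continued **periodically**
(wrap-around). Mirror (odd-reflection) padding is available but not the
default: reflecting about an endpoint reverses the direction of phase
progression and, when the endpoint sits near an extremum, the
continuation error `2·x(t₀)(1 − cos ωτ)` grows to several times the
amplitude; in testing this corrupted mid-signal CRP by tens of degrees,
while the periodic continuation of a quasi-periodic gait signal is exact
up to stride-to-stride variation.

CRP is computed on the continuous pass first and only then segmented
into cycles — the order matters because unwrapping across cycle
boundaries avoids endpoint phase artifacts in every cycle. The folded
difference `d = |φ_hip − φ_knee| mod 360; CRP = min(d, 360 − d)` lives on
[0°, 180°]. MARP is the mean over the 101 nodes of the across-cycle mean
curve; DP is the mean of the across-cycle sample SD (n − 1 denominator —
the cycles are a sample of the participant's stride population). DP for
a single cycle is undefined and reported as NaN.

## Group statistics

Outlier exclusion uses Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR; linear
interpolation quartiles) computed per group on the preferred-speed
condition, by default on MARP and DP (the metric list is configurable; a
participant outside any fence is removed from all conditions). Strict
inequality means an all-equal sample excludes nobody.

The factorial models pool the participant × speed observations with no
random participant effect — the same degrees-of-freedom structure the
original analysis used. This ignores within-participant correlation
across speeds, so p-values are anti-conservative for repeated-measures
inference; a mixed model would be the statistically stricter choice and
is deliberately out of scope. ANOVA/ANCOVA use type-II sums of squares
via OLS (`statsmodels`), partial η² = SS_effect/(SS_effect + SS_resid).
The ANCOVA interaction is evaluated first; pairwise simple-effect post
hocs are produced only when it is significant. Bonferroni adjustment
multiplies pairwise p-values by the number of comparisons.

SPM uses the pooled-variance two-sample t at each of the 101 nodes and a
permutation max-|t| null: the critical threshold t* is the
⌈(1 − α)(n_perm + 1)⌉-th order statistic of the maxima over `n_perm`
random label permutations plus the observed labelling, which controls
the family-wise error at α exactly under exchangeability (for
n_perm = 200, α = 0.05 the realised level is 10/201 ≈ 0.0498).
Zero-variance nodes get a pooled-variance floor of 1e−24 so the t
statistic stays finite. Clusters are maximal runs of nodes with
|t| > t*. Random-field-theory thresholds are not implemented; the
permutation route makes no smoothness assumptions and is exact at these
sample sizes.

## Synthetic cohort

The generator produces the statistical structure the analysis consumes,
not a musculoskeletal simulation. Hip and knee are sinusoids at the
stride frequency: `hip = (A_h − 10°) + A_h sin(2πu)`,
`knee = (A_k + 2°) + A_k sin(2πu − λ)`, with u the cycle fraction and
per-participant × speed excursions 2A and walking speeds drawn from the
group parameter sets. The lag λ is redrawn **per cycle** from
Normal(lag mean, lag SD) and cross-faded with a cosine ramp over the
first 5% of each cycle so the waveform stays smooth for the Hilbert
transform. This makes CRP analytically predictable: CRP ≈ λ_k over
cycle k, so MARP estimates the lag mean and DP the lag SD — the
generator's lag SD is the generative analogue of DP.

Defaults (`configs/hoa.yaml`, `configs/pd.yaml`): group sizes 19 HOA /
24 pwPD; per-speed walking speeds (HOA 0.67/1.07/1.45, pwPD
0.65/0.97/1.19 m/s, with their SDs) and hip/knee excursions (e.g. HOA
preferred hip 40.5° ± 7.6°, knee 65.2° ± 8.6°) follow published
descriptive statistics for these populations at slow/preferred/fast
instructed speeds; strides per pass (5 slow, 3 preferred/fast) follow
the observed step counts on a short walkway. Cadence is not part of
those statistics; stride times of 1.40/1.10/0.95 s (86/109/126
steps/min) were chosen as typical for older adults and fixed. The lag
parameters (HOA 60° ± 10°, pwPD 55° ± 12°) are not tabulated anywhere;
they were set once to magnitudes consistent with hip–knee CRP reported
in the coordination literature, with the pwPD set expressing the
trend-level pattern of slightly tighter mean coupling and higher
variability. Sensor noise SDs (0.05 m/s², 0.005 rad/s, 0.5 µT) are
typical MEMS figures.

The shank angular-velocity signature is one Gaussian bump per cycle
(peak 5 rad/s at 80% of the cycle, SD 5% of the cycle) on a baseline
chosen so the signal crosses zero exactly at each interior cycle
boundary — the true initial contacts, which sit on whole samples because
the stride period is rounded to the 200 Hz grid. The pass-initial
boundary has no preceding swing, so detection recovers n of the n + 1
truth boundaries. Raw IMU emission places the world frame on the pelvis,
rotates thigh by the hip angle and shank by hip + knee about the
medio-lateral axis, and emits gravity, segment angular rate and the
reference field in each sensor frame, with optional noise and
hardware-range clipping (±16 g, ±2000 °/s, ±1.9 Gauss).

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: soft-tissue artifact, magnetic
disturbance, non-sinusoidal joint trajectories (real knees have a
stance flexion wave), asymmetry, freezing or festination, turning, and —
importantly — between-participant variability in the *mean* coordination
strategy. Participants within a group differ only through finite-cycle
sampling noise, so group contrasts on MARP/DP are easier to detect here
than in real cohorts; the SPM and ANCOVA machinery is exercised, not
calibrated to field effect sizes. Per-cycle excursion equals the drawn
value exactly when the lag SD is zero; with stochastic lags the
cross-fade can shift a cycle's extremum by up to ≈0.5° at the default
lag SD (sub-degree in all recovery tests).

## Determinism and problem sizes

Every stochastic step draws from `numpy.random.Generator`s spawned from
the single run seed; identical configurations reproduce all numeric
outputs bit-for-bit (CSV floats are written at 10 significant digits).
The shipped test suite and the acceptance script run the cohort at its
default size (43 participants × 3 speeds × 5 passes, ≈1500 gait cycles)
and the permutation analyses at 200–1000 permutations with 500-replicate
null simulations — sizes chosen so the full analysis completes in well
under a minute on one CPU while keeping Monte-Carlo error comfortably
inside the asserted tolerances.

## Known limitations

- Pooled (non-repeated-measures) factorial models, as discussed above.
- The complementary filter assumes a clean magnetic field; there is no
  disturbance rejection.
- The walking-speed covariate is taken as given (from the manifest or
  generator truth); the pipeline does not estimate speed from the IMUs.
- Only right-side sagittal kinematics are modelled; frontal/transverse
  angles appear only as by-products of the Euler decomposition.
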