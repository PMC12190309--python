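# gaitcoord

Wearable-sensor analysis of hip–knee inter-joint coordination during
walking, for gait researchers comparing people with Parkinson's disease
(pwPD) against healthy older adults (HOA) across instructed walking
speeds.

The package implements the full chain from raw inertial measurement unit
(IMU) streams to group statistics:

1. **IMU I/O** — plain-CSV accelerometer/gyroscope/magnetometer streams
   (200 Hz; pelvis, right thigh, right shank), native-unit conversion, and
   zero-phase 4th-order Butterworth low-pass filtering at 6 Hz.
2. **Orientation** — complementary-filter fusion (gyroscope integration
   pulled toward accelerometer + magnetometer attitude, 0.98 gyro weight)
   to Hamilton sensor-to-world quaternions; joint orientation
   `q_joint = q_prox* ⊗ q_dist`; intrinsic Z–Y–X Euler decomposition with
   the medio-lateral Z angle as the sagittal hip/knee angle.
3. **Gait cycles** — initial contacts from the first negative-going
   zero-crossing after the mid-swing peak of sagittal shank angular
   velocity; segmentation into cycles time-normalised to 101 points;
   per-cycle joint excursion (max − min).
4. **Coordination** — continuous relative phase (CRP): Hilbert-transform
   phase angles of the centred hip and knee waveforms,
   `CRP = |φ_hip − φ_knee|` folded onto [0°, 180°] (0 in-phase, 180
   anti-phase), computed over the whole pass and then segmented.
   Summaries per participant × speed: **MARP** (mean of the ensemble-mean
   CRP curve — average coordination strategy) and **DP** (mean of the
   pointwise across-cycle SD — coordination variability).
5. **Group statistics** — participant-level 1.5×IQR (Tukey fence) outlier
   exclusion; two-way ANOVA (group × speed) on walking speed with
   Bonferroni post hocs; two-way ANCOVAs on MARP, DP and excursions with
   actual walking speed as covariate (partial η² effect sizes,
   interaction-gated simple effects); and 1-D statistical parametric
   mapping (SPM) of the CRP waveforms via a label-permutation max-|t|
   critical threshold t*.
6. **Synthetic cohort generator** — participant data of this kind are not
   publicly sharable, so the package ships a calibrated generator:
   sinusoidal hip/knee kinematics at realistic cadences whose excursions,
   walking speeds and hip–knee phase lags are drawn from group-specific
   parameter sets (`gaitcoord/configs/*.yaml`), with per-cycle lag
   redraws (the generative analogue of DP), matching shank
   angular-velocity signatures, and optional raw IMU emission — plus a
   ground-truth object for every draw.

## Worked example

```python
import numpy as np
from gaitcoord import analyze_pass, marp_dp
from gaitcoord.cycles import GaitEvents
from gaitcoord.synthetic import ConditionSpec, generate_pass

cond = ConditionSpec(
    speed_mean=1.0, speed_sd=0.0, hip_exc_mean=40.0, hip_exc_sd=0.0,
    knee_exc_mean=60.0, knee_exc_sd=0.0, lag_mean_deg=60.0, lag_sd_deg=10.0,
    cadence_spm=109.0, strides_per_pass=3,
)
angles, truth = generate_pass(cond, 200.0, np.random.default_rng(0), n_cycles=200)
cycles = analyze_pass(angles, GaitEvents(truth.ic_indices, []))
marp, dp = marp_dp(cycles)
print(f"MARP {marp:.2f} deg, DP {dp:.2f} deg")
```

prints

```
MARP 60.02 deg, DP 9.41 deg
```

the per-cycle hip–knee phase lag was drawn from Normal(60°, 10°), and the
CRP summaries recover both moments: MARP ≈ the mean lag (average coupling
strategy) and DP ≈ the lag SD (cycle-to-cycle coordination variability).

The `examples/` directory holds one short script per capability
(synthetic cohort + event detection, CRP basics, sensor-fusion round
trip, full pipeline); each prints its numbers with a note on what they
mean. A thin CLI wraps the pipeline stages:

```bash
gaitcoord all --seed 1 --out run_out            # full synthetic run
gaitcoord simulate --seed 1 --out data_dir      # write raw IMU CSVs + manifest
gaitcoord angles --data data_dir --out work     # then: events, crp, stats
```

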