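"""Generate a synthetic gait cohort and check event detection against truth.

Draws two healthy-older-adult participants with the shipped defaults,
emits each pass's shank angular-velocity signature, detects initial
contacts, and compares them to the generator's ground truth.
"""

import numpy as np

from gaitcoord import detect_initial_contacts
from gaitcoord.synthetic import default_cohort_spec, generate_cohort, generate_shank_gyro

spec = default_cohort_spec("HOA", n_participants=2, passes_per_speed=1, seed=42)
cohort = generate_cohort(spec)

for cp in cohort[:3]:
    tr = cp.truth
    noise_free = generate_shank_gyro(tr)
    ev = detect_initial_contacts(noise_free, spec.fs)
    errors = [int(np.min(np.abs(tr.ic_indices - ic))) for ic in ev.ic_indices]
    print(
        f"{tr.participant} {tr.speed_condition:9s} "
        f"speed {tr.walking_speed_mps:.2f} m/s  "
        f"hip excursion {tr.hip_excursion_deg:.1f} deg  "
        f"ICs detected {len(ev.ic_indices)}/{len(tr.ic_indices)}  "
        f"max |error| {max(errors)} samples"
    )

print(
    "\nEach line is one walking pass: the drawn walking speed and hip range of\n"
    "motion, how many initial contacts the zero-crossing detector recovered\n"
    "(the pass-initial boundary has no preceding swing, so n of n+1), and the\n"
    "worst sample offset versus the generator's ground truth (0 = exact)."
)
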