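"""Continuous relative phase on analytic signals and a stochastic cohort pass.

First the textbook limits: identical sinusoids are perfectly in-phase
(CRP 0), sign-flipped ones anti-phase (CRP 180), a 90-degree lag gives
CRP 90.  Then MARP/DP recovery: a pass whose per-cycle hip-knee lag is
drawn from Normal(60, 10) degrees should summarise to MARP ~60, DP ~10.
"""

import numpy as np

from gaitcoord import analyze_pass, crp, hilbert_phase, marp_dp
from gaitcoord.cycles import GaitEvents
from gaitcoord.series import JointAngleSeries
from gaitcoord.synthetic import ConditionSpec, generate_pass

fs = 200.0
t = np.arange(0, 10, 1 / fs)
hip = np.sin(2 * np.pi * t)

for name, other in [
    ("identical", hip.copy()),
    ("sign-flipped", -hip),
    ("90-deg lag", np.sin(2 * np.pi * t - np.pi / 2)),
]:
    c = crp(hilbert_phase(hip, pad=200), hilbert_phase(other, pad=200))
    mid = c[len(c) // 4 : -len(c) // 4]
    print(f"{name:13s} CRP mid-signal mean {mid.mean():7.2f} deg (SD {mid.std():.3f})")

cond = ConditionSpec(1.0, 0.0, 40.0, 0.0, 60.0, 0.0, 60.0, 10.0, 109.0, 3)
angles, truth = generate_pass(cond, fs, np.random.default_rng(0), n_cycles=200)
cycles = analyze_pass(angles, GaitEvents(truth.ic_indices, []))
marp, dp = marp_dp(cycles)
print(f"\n200-cycle pass, lag ~ N(60, 10): MARP {marp:.2f} deg, DP {dp:.2f} deg")
print(
    "\nCRP quantifies hip-knee coupling (0 = in-phase, 180 = anti-phase).\n"
    "MARP is the mean coordination strategy, DP the cycle-to-cycle\n"
    "variability; both recover the generative lag mean and SD."
)
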