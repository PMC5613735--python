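"""Recover per-slice rigid misalignments from matched landmarks.

Each synthetic slice carries analytic landmark coordinates in both the
canonical (aligned) frame and its own misaligned frame; the closed-form
Procrustes/Kabsch fit should recover the inverse of the applied transform
to floating-point precision.
"""

import math

from histovol import LandmarkPairSet, StackSpec, estimate_rigid, generate_stack

spec = StackSpec(n_slices=8, damaged_slices=(), seed=3)
_, truth = generate_stack(spec)

print("slice  applied_theta_deg  recovered_theta_deg  rms_residual")
worst = 0.0
for k, (applied, lm) in enumerate(zip(truth.applied_transforms, truth.landmark_sets)):
    fit, rms = estimate_rigid(LandmarkPairSet(lm["misaligned"], lm["canonical"]))
    inv = applied.inverse()
    worst = max(worst, abs(fit.theta - inv.theta))
    print(
        f"{k:5d}  {math.degrees(applied.theta):17.4f}"
        f"  {math.degrees(-fit.theta):19.4f}  {rms:.2e}"
    )
print(f"worst angular recovery error: {worst:.2e} rad")
# With exact landmarks the residuals are ~1e-14: the fit is exact up to
# floating point, so registration error downstream comes only from the
# nearest-neighbour resampling of pixels.
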