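"""Generate a synthetic serial-section stack and inspect its ground truth.

The generator renders an ellipsoid-like organ sectioned into misaligned 2D
slices: negative tissue bright in green/blue, red-bright positive cell
clusters, extra-organ speckle, and one slice with near-zero tissue contrast.
"""

from pathlib import Path

from histovol import StackSpec, generate_stack, write_fixture

spec = StackSpec()  # 256 x 256 px, 24 sections, seed 42
sections, truth = generate_stack(spec)

print(f"slices: {len(sections)}, frame: {sections[0].shape}")
print(f"true positive fraction (positive / tissue voxels): {truth.positive_fraction:.4f}")
print(f"damaged slices: {list(spec.damaged_slices)}")
t = truth.applied_transforms[0]
print(f"slice 0 misalignment: theta={t.theta:+.4f} rad, t=({t.tx:+.1f}, {t.ty:+.1f}) px")

out = Path("scratch/example_stack")
manifest = write_fixture(sections, truth, out)
print(f"fixture written, manifest: {manifest}")
# The positive fraction is what the full pipeline must recover; the applied
# transforms are what registration must invert.
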