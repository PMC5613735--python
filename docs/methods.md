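# Methods

## Problem and pipeline

The package reconstructs the 3D distribution of a red-fluorescent cell
population from an ordered stack of 2D section images. Serial cryosections
are imaged independently, so each lands on its slide with an arbitrary
in-plane rotation and shift; some sections image with tissue contrast too
weak to classify ("damaged" slices); and the field of view contains
non-tissue debris and imaging speckle. The pipeline runs, per
configuration, in a fixed order:

1. **Auto-contrast** — per-image linear stretch. The low/high clip bounds
   are the pixel values at rank `floor(saturation·n)` from each end of the
   sorted pooled values of all three channels, mapped to 0/255 with
   clipping. One transfer function per image (channels jointly), so the
   red/green ratio that later drives marking is preserved. Constant images
   pass through unchanged. Default saturation 0.0035 per tail.
2. **Marking + grayscale** — grayscale is the rounded Rec. 601 luma
   (0.299 R + 0.587 G + 0.114 B). Every pixel whose **red channel ≥
   red_threshold** (default 25, per-slice overrides supported; the
   comparison is inclusive so boundary pixels stay positive) gets
   **+mark_boost** (default 100), clipped at 255. The boost moves positive
   pixels above the negative-tissue intensity band so one scalar threshold
   separates the classes later. Marking a slice twice is an error, not a
   no-op: the `marked` flag exists to surface pipeline-wiring bugs.
3. **Gaussian smooth + decimation** (optional, default off) — normalised
   Gaussian kernel, reflective boundaries, then every `factor`-th pixel
   starting at index 0 (output dims `ceil(dim/factor)`). Marking precedes
   smoothing so the boosted plateau survives blurring.
4. **Rigid registration** — closed-form 2D Procrustes/Kabsch fit from
   matched landmarks (see below), nearest-neighbour resampling into the
   reference slice's frame. Default reference is the middle slice
   (`⌊n/2⌋`); default mode is *chain* (each slice fitted to its nearest
   registered neighbour toward the reference, transforms composed), the
   practice for serial sections where landmarks are only reliable between
   adjacent slices; *direct* mode fits every slice straight to the
   reference. A damaged slice without landmarks passes through with the
   identity.
5. **Classification** — intensity > `positive_above` (default 80) →
   POSITIVE; `background_below` ≤ I ≤ `positive_above` (default 3..80) →
   NEGATIVE; below → BACKGROUND. The strictness (>, closed middle band, <)
   is the unique assignment in which the three stated class descriptions
   are simultaneously consistent and every voxel gets exactly one label.
6. **Damaged-slice repair** — on each configured damaged slice, every
   BACKGROUND/NEGATIVE voxel takes the label at the same (x, y) of the
   nearest non-damaged slice (ties toward lower z); POSITIVE voxels are
   kept, because the positive signal remains distinguishable even when
   tissue contrast is lost. Label copying is the nearest-neighbour
   analogue appropriate after classification; interpolating intensities
   would manufacture values on a slice defined by not having usable ones.
7. **Region growing** — breadth-first growth from a seed through tissue
   voxels (NEGATIVE or POSITIVE); unreached voxels become BACKGROUND.
   Connectivity 6 by default (face neighbours) — conservative against
   diagonal leakage across the strongly anisotropic z spacing; 26
   available. `seed: auto` picks the tissue voxel nearest the tissue
   centroid, which lands inside any convex-ish organ; an explicit (x, y, z)
   seed is validated to be tissue.
8. **XY majority down-sampling** (z never reduced: one voxel per section) —
   each `factor×factor×1` block takes its majority label; ties break
   POSITIVE > NEGATIVE > BACKGROUND so signal is never silently erased.
   Edge blocks are partial and vote with their real voxels only.
9. **VTK output** — legacy ASCII structured points, scalars
   `unsigned_char`, x varying fastest then y then z, one image row per
   line. Default label→scalar map 0/100/200 (the ~100-step class
   separation used throughout). ASCII was chosen over binary so output is
   diffable and byte-stable; the package's reader consumes exactly this
   dialect and is the writer's round-trip oracle.

Coordinates: images are (row, col), 0-based, row 0 at the top; volume
x = col, y = row, z = slice; origin defaults to (0, 0, 0).

## The rigid fit

With centred landmark pairs, the optimal rotation is the polar angle of
the 2×2 cross-covariance — `theta = atan2(Σ m̃×f̃, Σ m̃·f̃)` — and the
translation maps the moving centroid onto the fixed one. This is the
global least-squares optimum over proper rotations; reflections cannot
occur by construction, matching the physical constraint that sections are
not flipped. Degenerate input (fewer than two pairs, or all points
coincident) is rejected. With exact landmarks the fit recovers applied
transforms to ~1e-16 rad, so downstream geometric error is entirely the
±half-pixel jitter of nearest-neighbour resampling.

## Voxel spacing and units

The default spacing (5.8, 8.9, 2.5) with unit tag "as published (mm)" is
carried verbatim from the source dataset's stated resolutions. Those
numbers are mutually inconsistent with the stated 10 µm section thickness
and a centimetre-scale organ — µm was almost certainly meant — but the
package treats spacing as metadata only: it is never used in computation,
and silently "fixing" published numbers would be worse than carrying them
with a visible tag. Override both in the config if you know your geometry.

## The synthetic generator

`StackSpec` defaults define the test-bench conditions: a 256×256 px ×
24-section stack (a desk-scale stand-in for a real ~560×870×48
acquisition), an elliptical organ silhouette whose semi-axes shrink
toward the stack ends as `sqrt(1 − 0.6·u²)` (u ∈ [−1,1]) with a slight
centre drift — the simplest shape guaranteeing the single connected 3D
component region growing assumes; negative tissue rendered dim in red
(mean 8) and bright in green/blue (mean 70, luma ≈ 52, inside the 3..80
band); 25 red-bright clusters per slice (radius 3–7 px, red 180–240);
12 extra-organ tissue-coloured speckle blobs per slice; per-slice rigid
misalignment up to 5° and 10 px, drawn about the image centre (a corner-
anchored 5° rotation would sweep the organ out of frame, which misaligned
sections do not do); slice 11 damaged (tissue channels ×0.04, clusters
kept) — near mid-stack, where section area changes slowly between
neighbours, mirroring where repair is meaningful. Landmarks are a fixed
ring of 8 analytic points shared by all slices and mapped through each
slice's transform — they stand in for human-clicked correspondences and
are exact by construction, so registration accuracy is measured separately
from landmark-picking error.

Ground truth (applied transforms, full-resolution label grid in the
aligned frame, landmark sets in both frames, positive fraction) is emitted
alongside the pixels. Identical specs produce byte-identical stacks.

What the generator does **not** emulate: stitching seams, uneven
illumination, out-of-plane deformation, anatomically realistic organ
shape, or landmark-picking noise. Passing tests therefore demonstrate the
correctness of the pipeline's operations and bookkeeping, not robustness
to every artefact of real slides — on real data the registration quality
is bounded by the user's landmarks, and threshold defaults may need
per-stack tuning.

## Accuracy on the default synthetic stack

End-to-end, the recovered positive fraction sits ~3.5–4% (relative) above
truth across seeds. The bias is almost entirely the damaged-slice repair:
label copying merges the neighbour's positive clusters with the damaged
slice's own preserved ones, roughly doubling that one slice's positive
share; nearest-neighbour double resampling contributes only zero-mean
boundary jitter. Repaired damaged-slice tissue counts land within ~1% of
truth because adjacent section areas differ little near mid-stack. These
are properties of the stated repair rule, not tunables.

## Numerical choices

- All 8-bit quantities are computed in float64 and rounded half-up
  (`floor(x + 0.5)`) before clipping to [0, 255], for platform-stable
  results.
- The auto-contrast rank rule (`floor(saturation·n)` from each end) is a
  plain order-statistic, deliberately simpler than histogram-bin
  heuristics of interactive tools; the joint-channel choice is documented
  rather than assumed.
- Gaussian kernels are truncated at 4σ (radius `int(4σ + 0.5)`).
- VTK header floats are written as the shortest decimal that parses back
  to the identical double, making the writer byte-stable and the
  round trip exact.
- Region growing is implemented via connected-component labelling of the
  tissue mask with the 6- or 26-neighbour structuring element, keeping the
  seed's component; tests verify equivalence against an independent
  hand-written breadth-first search.

## Known limitations

- Rigid alignment only: no affine or elastic deformation model, so tissue
  stretch between sections remains in the volume.
- Landmarks must be provided per slice (files of x y pairs, matched by row
  order); there is no automatic landmark detection.
- Global class thresholds with per-slice red-threshold overrides; no
  histogram-adaptive thresholding.
- The VTK reader supports exactly the writer's dialect (legacy ASCII
  structured points, one unsigned_char scalar array) — it is an I/O
  round-trip tool, not a general VTK parser.
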