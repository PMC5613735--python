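# histovol

Reconstruct a 3D labelled voxel volume from serial 2D fluorescence
histology sections.

Mapping where a fluorescently tagged cell population sits inside a whole
organ is commonly done by cryosectioning the organ, imaging every section,
and stacking the 2D images back into a 3D volume. `histovol` implements
that reconstruction for red-fluorescent-reporter stacks (e.g. tdTomato⁺
cardiomyocytes in a mouse heart): each section image is contrast-stretched,
converted to grayscale with red-positive pixels *marked* by a +100
intensity boost, rigidly realigned from user-supplied landmarks, classified
voxel-wise into positive / negative / non-tissue background, cleaned of
extra-organ noise by seeded 3D region growing, and written as a legacy VTK
structured-points file that opens directly in ParaView.

It is aimed at labs doing anatomical mapping from slide scanners or
moving-stage fluorescence microscopes who want a scripted, reproducible
alternative to a manual ImageJ/TrakEM2/MATLAB tool chain — plus a synthetic
stack generator with exact ground truth, so every stage of the pipeline can
be validated without any microscope data.

## The method

For slice $k$ with matched landmark pairs $(m_i, f_i)$ the rigid alignment
is the closed-form 2D Procrustes/Kabsch fit: with centred points
$\tilde m_i, \tilde f_i$,

$$\hat\theta = \operatorname{atan2}\Big(\sum_i \tilde m_i \times \tilde f_i,\; \sum_i \tilde m_i \cdot \tilde f_i\Big), \qquad \hat t = \bar f - R(\hat\theta)\,\bar m,$$

which minimises $\sum_i \lVert R m_i + t - f_i \rVert^2$ over rotations and
translations (no scaling, no reflection — sections are never flipped).
Slices are resampled with nearest-neighbour interpolation so discrete
intensity classes are never blended.

Voxel classification uses two global intensity thresholds on the marked
grayscale: intensity $> 80$ → positively stained, $3 \le I \le 80$ →
negatively stained tissue, $< 3$ → non-tissue background. Slices whose
tissue signal was too weak to classify are repaired by copying labels from
the nearest intact slice (positive voxels are preserved), and a seeded
region grow through tissue voxels (6- or 26-connectivity) removes
everything not connected to the organ.

## Worked example

```sh
python examples/03_full_reconstruction.py
```

generates the default synthetic stack (256×256 px, 24 sections, one
damaged slice, per-slice misalignment up to 5° / 10 px), runs the full
pipeline on it, and prints:

```
final dims (nx, ny, nz): (256, 256, 24)
voxel spacing: (5.8, 8.9, 2.5) (as published (mm))
removed extra-organ voxels: 3488
recovered positive fraction: 0.1153
true positive fraction:      0.1112
relative error: 3.71%
VTK volume for ParaView: scratch/example_run/out/volume.vtk
```

The *positive fraction* is the share of tissue voxels classified as
positively stained; the pipeline recovers the generator's ground truth to
within a few percent, with the residual dominated by the damaged-slice
repair (label copying merges the neighbour's positive pattern with the
slice's own preserved signal). The removed voxels are the extra-organ
speckle that region growing deleted.

The same run from a shell:

```sh
histovol synth --out stack/                 # synthetic stack + ground truth
histovol run --config pipeline.yaml         # full reconstruction
```

with per-stage subcommands (`preprocess`, `register`, `classify`,
`reconstruct`) available for inspecting intermediate results. A minimal
`pipeline.yaml`:

```yaml
manifest: stack/manifest.tsv
landmarks_dir: stack/landmarks
output: {vtk: out/volume.vtk, report: out/report.json}
```

Every other parameter (red marking threshold 25, mark boost 100, class
thresholds 3/80, connectivity 6, voxel spacing 5.8/8.9/2.5, ...) has a
documented default and can be overridden in the YAML; unknown keys are
rejected.

## Layout

- `src/histovol/` — library modules: `synthetic`, `stack_io`, `preprocess`,
  `registration`, `segmentation`, `vtk_io`, `config`, `pipeline`, `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, parameters, numerical choices, limitations
- `tests/` — pytest suite with independent oracles
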