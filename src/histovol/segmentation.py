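"""Voxel classification, damaged-slice repair and noise cleanup.

After alignment each voxel carries one 8-bit intensity: marked positive
pixels sit ~100 above negative tissue, negative tissue sits well above the
near-zero non-tissue background.  Classification is therefore a pair of
global intensity thresholds; slices whose tissue signal was too weak to
classify are repaired by copying labels from the nearest intact slice; and
everything not connected to the organ is removed by seeded 3D region
growing, which deletes extra-organ speckle while preserving the single
connected organ component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SegmentationError
from .preprocess import GraySlice
from .volume import Label, LabelVolume, VolumeMeta

__all__ = [
    "ClassThresholds",
    "classify_volume",
    "interpolate_damaged_slices",
    "region_grow_cleanup",
    "volume_downsample",
]


@dataclass(frozen=True)
class ClassThresholds:
    """Intensity bounds of the three-class rule.

    With the defaults: intensity > 80 is positively stained, 3..80
    (inclusive) is negatively stained tissue, and < 3 is non-tissue
    background.  This strictness (> above, closed middle band, < below) is
    the only reading consistent with all three stated class descriptions.
    """

    positive_above: int = 80
    background_below: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.background_below <= self.positive_above <= 255):
            raise SegmentationError(
                "thresholds must satisfy 0 <= background_below <= positive_above <= 255, "
                f"got background_below={self.background_below}, positive_above={self.positive_above}"
            )


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),   # face neighbours
    26: ndimage.generate_binary_structure(3, 3),  # face+edge+corner
}


def classify_volume(
    stack: list[GraySlice],
    thresholds: ClassThresholds = ClassThresholds(),
    meta: VolumeMeta | None = None,
) -> LabelVolume:
    """Stack aligned grayscale slices and classify every voxel.

    Slices must share one frame (be aligned).  Each voxel receives exactly
    one label, so the three class counts always partition the voxel total.
    """
    if not stack:
        raise SegmentationError("empty slice stack")
    shapes = {s.pixels.shape for s in stack}
    if len(shapes) > 1:
        raise SegmentationError(f"slices are not on a uniform frame: {sorted(shapes)}")
    intensity = np.stack([s.pixels for s in stack], axis=2)  # (ny, nx, nz)
    labels = np.full(intensity.shape, int(Label.NEGATIVE), dtype=np.uint8)
    labels[intensity > thresholds.positive_above] = int(Label.POSITIVE)
    labels[intensity < thresholds.background_below] = int(Label.BACKGROUND)
    ny, nx, nz = labels.shape
    if meta is not None and meta.dims != (nx, ny, nz):
        raise SegmentationError(
            f"meta.dims {meta.dims} disagree with stack dims ({nx},{ny},{nz})"
        )
    return LabelVolume(labels, meta)


def interpolate_damaged_slices(
    volume: LabelVolume, damaged: list[int]
) -> LabelVolume:
    """Repair damaged slices by nearest-slice label copying.

    On each damaged slice, every BACKGROUND or NEGATIVE voxel takes the
    label of the same (x, y) position on the nearest non-damaged slice
    (ties broken toward lower z).  POSITIVE voxels are preserved: the
    positive signal remained distinguishable even on slices whose tissue
    background was too weak to classify.
    """
    nz = volume.labels.shape[2]
    damaged = sorted(set(int(d) for d in damaged))
    for d in damaged:
        if not (0 <= d < nz):
            raise SegmentationError(f"damaged slice index {d} out of range [0, {nz})")
    if not damaged:
        return volume.copy()
    intact = [z for z in range(nz) if z not in set(damaged)]
    if not intact:
        raise SegmentationError("all slices are damaged; nothing to interpolate from")
    out = volume.labels.copy()
    intact_arr = np.asarray(intact)
    for d in damaged:
        dist = np.abs(intact_arr - d)
        # argmin takes the first minimum; intact_arr is ascending so the
        # lower-z neighbour wins ties
        src = int(intact_arr[np.argmin(dist)])
        replaceable = volume.labels[:, :, d] != Label.POSITIVE
        slice_out = out[:, :, d]
        slice_out[replaceable] = volume.labels[:, :, src][replaceable]
    return LabelVolume(out, volume.meta)


def _auto_seed(tissue: np.ndarray) -> tuple[int, int, int]:
    """Tissue voxel nearest (in voxel index space) to the tissue centroid."""
    coords = np.argwhere(tissue)  # (n, 3) in (y, x, z)
    centroid = coords.mean(axis=0)
    nearest = coords[np.argmin(np.sum((coords - centroid) ** 2, axis=1))]
    y, x, z = (int(v) for v in nearest)
    return (x, y, z)


def region_grow_cleanup(
    volume: LabelVolume,
    connectivity: int = 6,
    seed: tuple[int, int, int] | str = "auto",
) -> tuple[LabelVolume, int]:
    """Remove tissue not connected to the seed (extra-organ noise).

    Grows from the seed through tissue voxels (NEGATIVE or POSITIVE) under
    6- or 26-connectivity; voxels not reached are relabelled BACKGROUND,
    reached voxels keep their labels.  ``seed="auto"`` picks the tissue
    voxel nearest the tissue centroid.  Seeds are (x, y, z) voxel indices.

    Returns the cleaned volume and the number of removed tissue voxels.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise SegmentationError(
            f"connectivity must be 6 or 26, got {connectivity}"
        )
    tissue = volume.tissue_mask()
    if not tissue.any():
        raise SegmentationError("volume contains no tissue voxels to grow from")
    if isinstance(seed, str):
        if seed != "auto":
            raise SegmentationError(f"seed must be (x, y, z) or 'auto', got {seed!r}")
        seed_xyz = _auto_seed(tissue)
    else:
        seed_xyz = tuple(int(v) for v in seed)  # type: ignore[assignment]
    x, y, z = seed_xyz
    ny, nx, nz = volume.labels.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise SegmentationError(f"seed {seed_xyz} outside volume dims {(nx, ny, nz)}")
    if not tissue[y, x, z]:
        raise SegmentationError(
            f"seed {seed_xyz} lies on a BACKGROUND voxel; choose a tissue voxel"
        )
    components, _ = ndimage.label(tissue, structure=_CONNECTIVITY_STRUCTS[connectivity])
    keep = components == components[y, x, z]
    out = volume.labels.copy()
    removed = int(np.count_nonzero(tissue & ~keep))
    out[tissue & ~keep] = int(Label.BACKGROUND)
    return LabelVolume(out, volume.meta), removed


#: Tie-break precedence for majority down-sampling: never silently erase
#: signal, so POSITIVE beats NEGATIVE beats BACKGROUND on equal counts.
_PRECEDENCE = (Label.POSITIVE, Label.NEGATIVE, Label.BACKGROUND)


def volume_downsample(volume: LabelVolume, factor: int) -> LabelVolume:
    """Majority-label down-sampling in X and Y (Z kept: one voxel per section).

    Each output voxel takes the majority label of its factor x factor x 1
    block (edge blocks may be partial); ties break by the signal-favouring
    precedence POSITIVE > NEGATIVE > BACKGROUND.  Spacing in x and y is
    multiplied by the factor; dims become ceil(dim / factor).
    """
    factor = int(factor)
    if factor < 1:
        raise SegmentationError(f"downsample factor must be >= 1, got {factor}")
    ny, nx, nz = volume.labels.shape
    if factor > nx or factor > ny:
        raise SegmentationError(
            f"downsample factor {factor} exceeds XY extent ({nx}x{ny})"
        )
    if factor == 1:
        return volume.copy()
    out_ny = -(-ny // factor)
    out_nx = -(-nx // factor)
    # pad with a sentinel that counts for no label, so partial edge blocks
    # take the majority of their real voxels only
    padded = np.full((out_ny * factor, out_nx * factor, nz), 255, dtype=np.uint8)
    padded[:ny, :nx, :] = volume.labels
    blocks = padded.reshape(out_ny, factor, out_nx, factor, nz)
    counts = np.stack(
        [(blocks == int(lab)).sum(axis=(1, 3)) for lab in _PRECEDENCE], axis=0
    )
    # argmax returns the first maximum -> precedence order decides ties
    winner = np.argmax(counts, axis=0)
    lut = np.array([int(lab) for lab in _PRECEDENCE], dtype=np.uint8)
    out_labels = lut[winner]
    dx, dy, dz = volume.meta.spacing
    meta = VolumeMeta(
        dims=(out_nx, out_ny, nz),
        spacing=(dx * factor, dy * factor, dz),
        origin=volume.meta.origin,
        unit_label=volume.meta.unit_label,
    )
    return LabelVolume(out_labels, meta)
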