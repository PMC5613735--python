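"""Labelled voxel volumes and their metadata.

A :class:`LabelVolume` is the central 3D container of the pipeline: a regular
axis-aligned grid in which every voxel carries exactly one of three classes —
non-tissue background, negatively stained tissue, or positively stained
tissue (the red-fluorescent cell population the reconstruction maps).

Array convention
----------------
Label grids are numpy arrays of shape ``(height, width, n_slices)`` indexed
``[row, col, slice]``.  The volume axes map onto that as ``x = col``,
``y = row``, ``z = slice`` with row 0 at the image top, so
``meta.dims == (width, height, n_slices)``.  This convention is what fixes
the x-fastest scalar ordering of the VTK writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = ["Label", "VolumeMeta", "LabelVolume", "DEFAULT_SPACING"]

#: Voxel spacing carried verbatim from the source dataset's stated
#: resolutions (x, y, z).  The unit tag is metadata only and is never used
#: in computation; see the methods note on the published unit ambiguity.
DEFAULT_SPACING = (5.8, 8.9, 2.5)
DEFAULT_UNIT_LABEL = "as published (mm)"


class Label(IntEnum):
    """Voxel classes, ordered so that higher value = stronger signal."""

    BACKGROUND = 0
    NEGATIVE = 1
    POSITIVE = 2


@dataclass(frozen=True)
class VolumeMeta:
    """Geometry metadata of a voxel grid.

    Parameters
    ----------
    dims
        ``(nx, ny, nz)`` voxel counts.
    spacing
        ``(dx, dy, dz)`` physical units per voxel, all > 0.
    origin
        ``(x0, y0, z0)`` position of voxel (0, 0, 0).
    unit_label
        Free-text unit tag propagated into reports; purely descriptive.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit_label: str = DEFAULT_UNIT_LABEL

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three counts >= 1, got {self.dims!r}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing!r}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz


@dataclass
class LabelVolume:
    """A 3D grid of {BACKGROUND, NEGATIVE, POSITIVE} labels plus geometry.

    ``labels`` has shape ``(ny, nx, nz)`` (row, col, slice) and dtype uint8;
    ``meta.dims`` is ``(nx, ny, nz)`` and must agree with the array shape.
    """

    labels: np.ndarray
    meta: VolumeMeta = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D (ny, nx, nz), got shape {labels.shape}")
        valid = np.isin(labels, [int(l) for l in Label])
        if not valid.all():
            bad = np.unique(labels[~valid])
            raise ValueError(f"labels contain values outside {{0,1,2}}: {bad.tolist()}")
        self.labels = labels.astype(np.uint8, copy=False)
        ny, nx, nz = self.labels.shape
        if self.meta is None:
            self.meta = VolumeMeta(dims=(nx, ny, nz))
        elif self.meta.dims != (nx, ny, nz):
            raise ValueError(
                f"meta.dims {self.meta.dims} disagree with label grid (nx,ny,nz)=({nx},{ny},{nz})"
            )

    def class_counts(self) -> dict[Label, int]:
        """Voxel count per class; always sums to ``meta.n_voxels``."""
        return {lab: int(np.count_nonzero(self.labels == lab)) for lab in Label}

    def tissue_mask(self) -> np.ndarray:
        """Boolean mask of tissue voxels (NEGATIVE or POSITIVE)."""
        return self.labels != Label.BACKGROUND

    def positive_fraction(self) -> float:
        """POSITIVE voxels as a fraction of tissue voxels (0 if no tissue)."""
        tissue = int(np.count_nonzero(self.tissue_mask()))
        if tissue == 0:
            return 0.0
        return int(np.count_nonzero(self.labels == Label.POSITIVE)) / tissue

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.meta)
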