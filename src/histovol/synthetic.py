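"""Synthetic serial-section stacks with known ground truth.

The generator emulates what a stitched fluorescence histology stack of a
small organ looks like to this pipeline: per slice, an elliptical tissue
silhouette whose size varies smoothly along z (an ellipsoid-like organ),
rendered dim in the red channel and brighter in green/blue (negative
tissue autofluorescence), scattered red-bright circular clusters (the
fluorescent-reporter-positive cells), extra-organ speckle blobs (imaging
noise), and a per-slice random rigid misalignment.  Damaged slices keep
their positive clusters but lose almost all tissue contrast, mimicking
sections whose background staining was too weak to classify.

Everything the pipeline must recover is emitted alongside the images as
:class:`SyntheticTruth`: the applied per-slice transforms, the full-
resolution true label grid (in the canonical, aligned frame), and analytic
landmark coordinates in both frames.  Landmarks are generated analytically
at fixed canonical positions — standing in for points a human would click —
so registration accuracy can be tested to floating-point precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .registration import RigidTransform2D, warp_nearest
from .stack_io import (
    RGBSection,
    write_image,
    write_landmark_file,
    write_manifest,
)
from .volume import Label

__all__ = [
    "StackSpec",
    "SyntheticTruth",
    "generate_stack",
    "write_fixture",
    "stack_spec_from_dict",
]


@dataclass(frozen=True)
class OrganSpec:
    """Per-slice elliptical silhouette of the organ.

    The semi-axes at slice position u in [-1, 1] (z normalised to the stack)
    are ``semi_axis * sqrt(1 - taper * u**2)`` and the centre drifts
    linearly by ``drift * u``, so the organ is a smooth single connected
    component — the topology region growing assumes.
    """

    center: tuple[float, float] = (128.0, 128.0)
    semi_axes: tuple[float, float] = (90.0, 78.0)
    taper: float = 0.6
    drift: tuple[float, float] = (6.0, -4.0)


@dataclass(frozen=True)
class TissueSpec:
    """Negative-tissue rendering: bright green/blue, dim red.

    ``mean``/``sd`` set the green and blue channels; the red channel stays
    near ``red_mean`` so negative tissue never crosses the red marking
    threshold.  With the defaults the grayscale luma of tissue is ~52,
    inside the negative classification band.
    """

    mean: float = 70.0
    sd: float = 6.0
    red_mean: float = 8.0
    red_sd: float = 3.0


@dataclass(frozen=True)
class ClusterSpec:
    """Red-bright positive cell clusters drawn inside the organ."""

    per_slice: int = 25
    radius_range: tuple[float, float] = (3.0, 7.0)
    red_range: tuple[float, float] = (180.0, 240.0)
    other_mean: float = 30.0


@dataclass(frozen=True)
class MisalignmentSpec:
    """Per-slice random rigid offset: |rotation| and |translation| bounds.

    Rotations are drawn about the image centre (a section lands rotated
    about itself, not about the image corner) and stored as the equivalent
    origin-anchored transform.
    """

    max_rotation_deg: float = 5.0
    max_translation_px: float = 10.0


@dataclass(frozen=True)
class SpeckleSpec:
    """Extra-organ noise blobs, tissue-like in colour, disconnected from it."""

    per_slice: int = 12
    radius_range: tuple[float, float] = (1.0, 3.0)


@dataclass(frozen=True)
class StackSpec:
    """Full description of a synthetic stack; defaults are the desk-scale
    stand-in for a real acquisition (256 x 256 px, 24 sections, one damaged
    slice, misalignment within 5 degrees / 10 px)."""

    n_slices: int = 24
    width: int = 256
    height: int = 256
    organ: OrganSpec = field(default_factory=OrganSpec)
    tissue: TissueSpec = field(default_factory=TissueSpec)
    clusters: ClusterSpec = field(default_factory=ClusterSpec)
    misalignment: MisalignmentSpec = field(default_factory=MisalignmentSpec)
    speckle: SpeckleSpec = field(default_factory=SpeckleSpec)
    damaged_slices: tuple[int, ...] = (11,)
    damage_tissue_scale: float = 0.04
    seed: int = 42
    n_landmarks: int = 8

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ConfigError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.width < 8 or self.height < 8:
            raise ConfigError(
                f"width/height must be >= 8, got {self.width}x{self.height}"
            )
        for name in ("mean", "sd", "red_mean", "red_sd"):
            v = getattr(self.tissue, name)
            if not (0 <= v <= 255):
                raise ConfigError(f"tissue.{name} must be in [0, 255], got {v}")
        lo, hi = self.clusters.red_range
        if not (0 <= lo <= hi <= 255):
            raise ConfigError(f"clusters.red_range must be within [0, 255], got {lo}..{hi}")
        if self.clusters.per_slice < 0:
            raise ConfigError(f"clusters.per_slice must be >= 0, got {self.clusters.per_slice}")
        bad = [d for d in self.damaged_slices if not (0 <= d < self.n_slices)]
        if bad:
            raise ConfigError(
                f"damaged_slices outside [0, {self.n_slices}): {bad}"
            )
        if self.n_landmarks < 2:
            raise ConfigError(
                f"n_landmarks must be >= 2 for a rigid fit, got {self.n_landmarks}"
            )
        if not (0 <= self.damage_tissue_scale <= 1):
            raise ConfigError(
                f"damage_tissue_scale must be in [0, 1], got {self.damage_tissue_scale}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a generated stack.

    ``applied_transforms[k]`` maps canonical (aligned-frame) coordinates
    into slice k's misaligned frame; registration should recover its
    inverse.  ``true_labels`` is the (height, width, n_slices) label grid
    in the canonical frame at full resolution; damaged slices keep their
    true tissue there.  ``landmark_sets[k]`` holds the same points in the
    canonical frame and mapped through the applied transform.
    """

    applied_transforms: list[RigidTransform2D]
    true_labels: np.ndarray
    positive_fraction: float
    landmark_sets: list[dict[str, np.ndarray]]

    def tissue_count(self, slice_index: int | None = None) -> int:
        """True tissue voxels, overall or on one slice."""
        grid = (
            self.true_labels
            if slice_index is None
            else self.true_labels[:, :, slice_index]
        )
        return int(np.count_nonzero(grid != Label.BACKGROUND))


_NESTED_SPECS = {
    "organ": OrganSpec,
    "tissue": TissueSpec,
    "clusters": ClusterSpec,
    "misalignment": MisalignmentSpec,
    "speckle": SpeckleSpec,
}


def stack_spec_from_dict(data: dict) -> StackSpec:
    """Build a :class:`StackSpec` from a plain mapping (YAML-friendly).

    Unknown keys, at any level, are configuration errors naming the key.
    """
    if not isinstance(data, dict):
        raise ConfigError("stack spec must be a mapping")
    scalar_keys = {
        "n_slices",
        "width",
        "height",
        "damaged_slices",
        "damage_tissue_scale",
        "seed",
        "n_landmarks",
    }
    unknown = set(data) - scalar_keys - set(_NESTED_SPECS)
    if unknown:
        raise ConfigError(f"unknown stack spec keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, cls in _NESTED_SPECS.items():
        if key in data:
            sub = data[key]
            if not isinstance(sub, dict):
                raise ConfigError(f"'{key}' must be a mapping")
            fields = set(cls.__dataclass_fields__)
            bad = set(sub) - fields
            if bad:
                raise ConfigError(f"unknown keys under '{key}': {sorted(bad)}")
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            kwargs[key] = cls(**sub)
    for key in scalar_keys & set(data):
        v = data[key]
        kwargs[key] = tuple(v) if isinstance(v, list) else v
    return StackSpec(**kwargs)


def _slice_geometry(spec: StackSpec, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Centre and semi-axes of the organ ellipse on slice k."""
    u = 0.0 if spec.n_slices == 1 else 2.0 * k / (spec.n_slices - 1) - 1.0
    scale = math.sqrt(max(1.0 - spec.organ.taper * u * u, 0.0))
    center = np.asarray(spec.organ.center) + np.asarray(spec.organ.drift) * u
    axes = np.asarray(spec.organ.semi_axes) * scale
    return center, axes


def _ellipse_mask(
    shape: tuple[int, int], center: np.ndarray, axes: np.ndarray
) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return ((xs - center[0]) / axes[0]) ** 2 + ((ys - center[1]) / axes[1]) ** 2 <= 1.0


def _disc_mask(
    shape: tuple[int, int], cx: float, cy: float, r: float
) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def _canonical_landmarks(spec: StackSpec) -> np.ndarray:
    """Fixed point set shared by all slices: a ring around the organ centre."""
    c = np.asarray(spec.organ.center)
    r = 0.6 * min(spec.organ.semi_axes)
    angles = 2.0 * np.pi * np.arange(spec.n_landmarks) / spec.n_landmarks + 0.3
    return np.stack([c[0] + r * np.cos(angles), c[1] + r * np.sin(angles)], axis=1)


def generate_stack(spec: StackSpec) -> tuple[list[RGBSection], SyntheticTruth]:
    """Render a misaligned synthetic stack and its ground truth.

    Identical specs (including the seed) produce byte-identical pixel
    arrays and truth.  With zero misalignment bounds every applied
    transform is exactly the identity.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    landmarks = _canonical_landmarks(spec)
    center_px = ((spec.width - 1) / 2.0, (spec.height - 1) / 2.0)

    sections: list[RGBSection] = []
    transforms: list[RigidTransform2D] = []
    landmark_sets: list[dict[str, np.ndarray]] = []
    true_labels = np.zeros(shape + (spec.n_slices,), dtype=np.uint8)
    damaged_set = set(spec.damaged_slices)

    for k in range(spec.n_slices):
        center, axes = _slice_geometry(spec, k)
        organ = _ellipse_mask(shape, center, axes)

        canonical = np.zeros(shape + (3,), dtype=np.float64)
        n_tissue = int(organ.sum())
        canonical[organ, 0] = rng.normal(spec.tissue.red_mean, spec.tissue.red_sd, n_tissue)
        canonical[organ, 1] = rng.normal(spec.tissue.mean, spec.tissue.sd, n_tissue)
        canonical[organ, 2] = rng.normal(spec.tissue.mean, spec.tissue.sd, n_tissue)

        # positive clusters: discs fully inside the organ
        cluster_mask = np.zeros(shape, dtype=bool)
        r_lo, r_hi = spec.clusters.radius_range
        for _ in range(spec.clusters.per_slice):
            r = rng.uniform(r_lo, r_hi)
            margin = 1.0 - (r + 2.0) / min(axes)
            if margin <= 0:
                continue
            ang = rng.uniform(0, 2 * np.pi)
            rad = math.sqrt(rng.uniform(0, 1)) * margin
            cx = center[0] + axes[0] * rad * math.cos(ang)
            cy = center[1] + axes[1] * rad * math.sin(ang)
            cluster_mask |= _disc_mask(shape, cx, cy, r)
        cluster_mask &= organ
        n_pos = int(cluster_mask.sum())
        if n_pos:
            canonical[cluster_mask, 0] = rng.uniform(
                spec.clusters.red_range[0], spec.clusters.red_range[1], n_pos
            )
            canonical[cluster_mask, 1] = rng.normal(
                spec.clusters.other_mean, spec.tissue.sd, n_pos
            )
            canonical[cluster_mask, 2] = rng.normal(
                spec.clusters.other_mean, spec.tissue.sd, n_pos
            )

        if k in damaged_set:
            tissue_only = organ & ~cluster_mask
            canonical[tissue_only] *= spec.damage_tissue_scale

        # extra-organ speckle, kept clear of the organ boundary
        sp_lo, sp_hi = spec.speckle.radius_range
        for _ in range(spec.speckle.per_slice):
            for _attempt in range(50):
                cx = rng.uniform(0, spec.width - 1)
                cy = rng.uniform(0, spec.height - 1)
                norm = ((cx - center[0]) / axes[0]) ** 2 + ((cy - center[1]) / axes[1]) ** 2
                if norm > 1.35:
                    break
            else:
                continue
            r = rng.uniform(sp_lo, sp_hi)
            blob = _disc_mask(shape, cx, cy, r) & ~organ
            nb = int(blob.sum())
            if nb:
                canonical[blob, 0] = rng.normal(
                    spec.tissue.red_mean, spec.tissue.red_sd, nb
                )
                canonical[blob, 1] = rng.normal(spec.tissue.mean, spec.tissue.sd, nb)
                canonical[blob, 2] = rng.normal(spec.tissue.mean, spec.tissue.sd, nb)

        canonical8 = np.clip(np.floor(canonical + 0.5), 0, 255).astype(np.uint8)

        # truth labels live in the canonical frame; damaged slices keep
        # their real tissue there (the tissue exists, it just images dark)
        slab = true_labels[:, :, k]
        slab[organ] = int(Label.NEGATIVE)
        slab[cluster_mask] = int(Label.POSITIVE)

        max_rot = math.radians(spec.misalignment.max_rotation_deg)
        max_t = spec.misalignment.max_translation_px
        theta = rng.uniform(-max_rot, max_rot) if max_rot > 0 else 0.0
        tx = rng.uniform(-max_t, max_t) if max_t > 0 else 0.0
        ty = rng.uniform(-max_t, max_t) if max_t > 0 else 0.0
        transform = RigidTransform2D.about_center(theta, (tx, ty), center_px)
        transforms.append(transform)

        misaligned = warp_nearest(canonical8, transform, shape)
        sections.append(
            RGBSection(
                pixels=misaligned,
                slice_index=k,
                damaged=k in damaged_set,
                source_name=f"synthetic_{k:03d}",
            )
        )
        landmark_sets.append(
            {"canonical": landmarks.copy(), "misaligned": transform.apply(landmarks)}
        )

    n_org = int(np.count_nonzero(true_labels != Label.BACKGROUND))
    n_pos_total = int(np.count_nonzero(true_labels == Label.POSITIVE))
    truth = SyntheticTruth(
        applied_transforms=transforms,
        true_labels=true_labels,
        positive_fraction=(n_pos_total / n_org) if n_org else 0.0,
        landmark_sets=landmark_sets,
    )
    return sections, truth


def write_fixture(
    sections: list[RGBSection],
    truth: SyntheticTruth,
    directory: Path,
    image_format: str = "tiff",
    jpeg_quality: int = 95,
) -> Path:
    """Write a generated stack as an on-disk fixture.

    Produces one image per slice (TIFF by default for lossless round
    trips), the ordered tab-separated manifest, per-slice landmark files
    (misaligned-frame coordinates, the ones a user would click), and a
    truth sidecar: a JSON file with transforms, landmark sets and the
    positive fraction, plus per-slice true-label TIFFs.

    Returns the manifest path.
    """
    if image_format not in ("tiff", "jpeg"):
        raise ConfigError(f"image_format must be 'tiff' or 'jpeg', got {image_format!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lm_dir = directory / "landmarks"
    lm_dir.mkdir(exist_ok=True)
    truth_dir = directory / "truth_labels"
    truth_dir.mkdir(exist_ok=True)

    ext = ".tif" if image_format == "tiff" else ".jpg"
    entries = []
    for section in sections:
        name = f"slice_{section.slice_index:03d}{ext}"
        write_image(directory / name, section.pixels, jpeg_quality=jpeg_quality)
        entries.append((section.slice_index, name, section.damaged))
    manifest = write_manifest(directory, entries)

    for k, lm in enumerate(truth.landmark_sets):
        write_landmark_file(lm_dir / f"slice_{k:03d}.txt", lm["misaligned"])

    for k in range(truth.true_labels.shape[2]):
        write_image(truth_dir / f"labels_{k:03d}.tif", truth.true_labels[:, :, k])

    sidecar = {
        "positive_fraction": truth.positive_fraction,
        "applied_transforms": [
            {"theta": t.theta, "tx": t.tx, "ty": t.ty} for t in truth.applied_transforms
        ],
        "landmark_sets": [
            {
                "canonical": lm["canonical"].tolist(),
                "misaligned": lm["misaligned"].tolist(),
            }
            for lm in truth.landmark_sets
        ],
        "true_label_files": [
            f"truth_labels/labels_{k:03d}.tif"
            for k in range(truth.true_labels.shape[2])
        ],
    }
    (directory / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return manifest
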