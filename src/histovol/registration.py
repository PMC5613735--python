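"""Landmark-based rigid alignment of serial sections.

Serial cryosections land on slides with an arbitrary in-plane rotation and
shift, so the z-stack must be realigned before voxels can be stacked.  Only
rigid motion (rotation + translation) is modelled: sections are neither
scaled, sheared nor flipped.  The fit is the closed-form 2D orthogonal
Procrustes / Kabsch solution from matched landmark pairs, and slices are
resampled with nearest-neighbour interpolation so intensity classes are
never blended by the warp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import RegistrationError
from .preprocess import GraySlice

__all__ = [
    "RigidTransform2D",
    "LandmarkPairSet",
    "estimate_rigid",
    "apply_rigid",
    "warp_nearest",
    "align_stack",
    "AlignmentReport",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """A rotation-then-translation map ``p' = R(theta) @ p + t``.

    Coordinates are ``(x, y)`` pixel positions (x = column, y = row); the
    transform maps *moving*-frame coordinates into the *fixed* frame.
    ``theta`` is in radians, counter-clockwise in (x, y) axes.
    """

    theta: float
    tx: float
    ty: float

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def about_center(
        cls, theta: float, t: tuple[float, float], center: tuple[float, float]
    ) -> "RigidTransform2D":
        """Rotation about ``center`` followed by translation ``t``.

        Stored in the canonical origin-anchored form
        ``p' = R p + (c - R c + t)``.
        """
        c = np.asarray(center, dtype=float)
        r = _rot(theta)
        eff = c - r @ c + np.asarray(t, dtype=float)
        return cls(float(theta), float(eff[0]), float(eff[1]))

    @property
    def t(self) -> np.ndarray:
        return np.array([self.tx, self.ty], dtype=float)

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix."""
        m = np.eye(3)
        m[:2, :2] = _rot(self.theta)
        m[:2, 2] = self.t
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points into the fixed frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ _rot(self.theta).T + self.t

    def inverse(self) -> "RigidTransform2D":
        r_inv = _rot(-self.theta)
        t_inv = -(r_inv @ self.t)
        return RigidTransform2D(-self.theta, float(t_inv[0]), float(t_inv[1]))

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        t = _rot(self.theta) @ other.t + self.t
        return RigidTransform2D(self.theta + other.theta, float(t[0]), float(t[1]))

    def is_identity(self, tol: float = 0.0) -> bool:
        return (
            abs(self.theta) <= tol and abs(self.tx) <= tol and abs(self.ty) <= tol
        )


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class LandmarkPairSet:
    """Matched (x, y) landmark coordinates, paired one-to-one by index.

    ``moving`` lives on the slice being aligned, ``fixed`` on the reference
    frame.  A rigid fit needs at least two non-coincident points.
    """

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 2:
            raise RegistrationError(
                f"moving/fixed must be matched (N, 2) arrays, got {moving.shape} vs {fixed.shape}"
            )
        if moving.shape[0] < 2:
            raise RegistrationError(
                f"rigid fit needs >= 2 landmark pairs, got {moving.shape[0]}"
            )
        for name, pts in (("moving", moving), ("fixed", fixed)):
            if np.ptp(pts, axis=0).max() == 0.0:
                raise RegistrationError(f"all {name} landmarks coincide; fit is degenerate")
        object.__setattr__(self, "moving", moving)
        object.__setattr__(self, "fixed", fixed)

    def __len__(self) -> int:
        return self.moving.shape[0]


def estimate_rigid(pairs: LandmarkPairSet) -> tuple[RigidTransform2D, float]:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` landmarks.

    Closed form: subtract centroids, form the 2x2 cross-covariance and take
    the rotation from its polar decomposition.  In 2D that reduces to
    ``theta = atan2(sum cross, sum dot)`` over the centred pairs, which is a
    pure rotation by construction — reflections cannot occur, matching the
    physical constraint that sections are never flipped.

    Returns
    -------
    (transform, rms_residual)
        ``transform`` minimises ``sum ||R m_i + t - f_i||^2``;
        ``rms_residual`` is the root-mean-square point distance after the fit.
    """
    m = pairs.moving - pairs.moving.mean(axis=0)
    f = pairs.fixed - pairs.fixed.mean(axis=0)
    # polar angle of the cross-covariance: sum of dot and perp-dot products
    dot = float(np.sum(m * f))
    cross = float(np.sum(m[:, 0] * f[:, 1] - m[:, 1] * f[:, 0]))
    theta = math.atan2(cross, dot)
    r = _rot(theta)
    t = pairs.fixed.mean(axis=0) - r @ pairs.moving.mean(axis=0)
    transform = RigidTransform2D(theta, float(t[0]), float(t[1]))
    residuals = transform.apply(pairs.moving) - pairs.fixed
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, rms


def warp_nearest(
    pixels: np.ndarray, transform: RigidTransform2D, out_shape: tuple[int, int]
) -> np.ndarray:
    """Resample a 2D (or 2D-multichannel) image into the fixed frame.

    For each output pixel centre ``q`` the source position is the inverse
    map ``T^{-1}(q)``, rounded to the nearest input pixel; positions outside
    the input frame yield 0 (non-tissue background).  An identity transform
    with matching frames returns an exact copy.
    """
    pixels = np.asarray(pixels)
    if not np.isfinite([transform.theta, transform.tx, transform.ty]).all():
        raise RegistrationError("transform parameters must be finite")
    out_h, out_w = out_shape
    in_h, in_w = pixels.shape[:2]
    if transform.is_identity() and (out_h, out_w) == (in_h, in_w):
        return pixels.copy()
    inv = transform.inverse()
    xs, ys = np.meshgrid(np.arange(out_w, dtype=float), np.arange(out_h, dtype=float))
    r = _rot(inv.theta)
    src_x = r[0, 0] * xs + r[0, 1] * ys + inv.tx
    src_y = r[1, 0] * xs + r[1, 1] * ys + inv.ty
    ix = np.rint(src_x).astype(np.int64)
    iy = np.rint(src_y).astype(np.int64)
    inside = (ix >= 0) & (ix < in_w) & (iy >= 0) & (iy < in_h)
    out_shape_full = (out_h, out_w) + pixels.shape[2:]
    out = np.zeros(out_shape_full, dtype=pixels.dtype)
    out[inside] = pixels[iy[inside], ix[inside]]
    return out


def apply_rigid(
    gray: GraySlice, transform: RigidTransform2D, out_shape: tuple[int, int] | None = None
) -> GraySlice:
    """Resample a grayscale working slice into the reference frame."""
    if out_shape is None:
        out_shape = gray.pixels.shape
    return replace(gray, pixels=warp_nearest(gray.pixels, transform, out_shape))


@dataclass(frozen=True)
class AlignmentReport:
    """Per-slice registration summary (angles in degrees for readability)."""

    rows: tuple[dict, ...]

    def to_tsv(self) -> str:
        header = "slice\ttheta_deg\ttx\tty\trms"
        lines = [header]
        for row in self.rows:
            lines.append(
                f"{row['slice']}\t{row['theta_deg']:.6f}\t{row['tx']:.6f}"
                f"\t{row['ty']:.6f}\t{row['rms']:.6f}"
            )
        return "\n".join(lines) + "\n"


def align_stack(
    slices: list[GraySlice],
    landmarks: list[np.ndarray | None],
    reference_index: int,
    mode: str = "chain",
) -> tuple[list[GraySlice], list[RigidTransform2D], AlignmentReport]:
    """Align every slice of a stack into the reference slice's frame.

    Landmark lists are per-slice (N, 2) coordinate arrays in each slice's
    own frame; rows correspond across slices (the same anatomical feature
    clicked on each section), which is what makes pairwise fits possible.

    Modes
    -----
    ``chain`` (default, serial-section practice)
        Each slice is fitted to its nearest already-registered neighbour
        toward the reference and the transforms are composed outward.
    ``direct``
        Each slice is fitted straight to the reference slice's landmarks.

    A slice with no landmarks passes through with the identity if it is
    flagged damaged (its labels are repaired later by nearest-slice
    interpolation); otherwise it is a registration error.
    """
    n = len(slices)
    if n == 0:
        raise RegistrationError("empty stack")
    if len(landmarks) != n:
        raise RegistrationError(
            f"{len(landmarks)} landmark sets for {n} slices"
        )
    if not (0 <= reference_index < n):
        raise RegistrationError(
            f"reference_index {reference_index} out of range [0, {n})"
        )
    if mode not in ("chain", "direct"):
        raise RegistrationError(f"unknown registration mode {mode!r}")
    if landmarks[reference_index] is None:
        raise RegistrationError(
            f"reference slice {reference_index} has no landmarks"
        )

    transforms: list[RigidTransform2D | None] = [None] * n
    rms_vals: list[float] = [0.0] * n
    transforms[reference_index] = RigidTransform2D.identity()

    for direction in (-1, 1):
        anchor_idx = reference_index  # last slice with landmarks on this side
        k = reference_index + direction
        while 0 <= k < n:
            if landmarks[k] is None:
                if not slices[k].damaged:
                    raise RegistrationError(
                        f"slice {k} has no landmarks and is not flagged damaged"
                    )
                transforms[k] = RigidTransform2D.identity()
            else:
                target = reference_index if mode == "direct" else anchor_idx
                pairs = LandmarkPairSet(moving=landmarks[k], fixed=landmarks[target])
                fit, rms = estimate_rigid(pairs)
                transforms[k] = transforms[target].compose(fit)  # type: ignore[union-attr]
                rms_vals[k] = rms
                anchor_idx = k
            k += direction

    frame = slices[reference_index].pixels.shape
    aligned = [
        apply_rigid(s, t, frame) for s, t in zip(slices, transforms)  # type: ignore[arg-type]
    ]
    rows = tuple(
        {
            "slice": k,
            "theta_deg": math.degrees(transforms[k].theta),  # type: ignore[union-attr]
            "tx": transforms[k].tx,  # type: ignore[union-attr]
            "ty": transforms[k].ty,  # type: ignore[union-attr]
            "rms": rms_vals[k],
        }
        for k in range(n)
    )
    return aligned, transforms, AlignmentReport(rows)  # type: ignore[return-value]
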