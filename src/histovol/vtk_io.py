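"""Legacy VTK structured-points ASCII writer and reader.

The reconstruction is delivered as a legacy (version 3.0) VTK file of
dataset type STRUCTURED_POINTS with one ``unsigned_char`` scalar per voxel,
the format ParaView and most scientific viewers open directly.  ASCII is
used deliberately: files stay diffable and byte-stable across runs.

Scalars are emitted with x varying fastest, then y, then z — the flat index
of voxel (x, y, z) is ``x + nx * (y + ny * z)`` — which is what the legacy
format mandates.  The reader consumes exactly the dialect the writer emits
and serves as its round-trip check.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .volume import Label, LabelVolume, VolumeMeta

__all__ = [
    "DEFAULT_VALUE_MAP",
    "write_vtk_structured_points",
    "read_vtk_structured_points",
]

#: Default label -> 8-bit scalar map.  Classes are separated by ~100
#: intensity steps, echoing the marking device used upstream.
DEFAULT_VALUE_MAP = {
    Label.BACKGROUND: 0,
    Label.NEGATIVE: 100,
    Label.POSITIVE: 200,
}

_HEADER_LINE = "# vtk DataFile Version 3.0"


def _fmt(x: float) -> str:
    """Stable float formatting for header fields: the shortest decimal that
    parses back to exactly the same double."""
    return repr(float(x))


def write_vtk_structured_points(
    volume: LabelVolume,
    path: Path,
    value_map: dict[Label, int] | None = None,
    title: str = "histovol label volume",
    scalar_name: str = "staining",
) -> Path:
    """Write a label volume as legacy ASCII VTK structured points.

    ``value_map`` must define an 8-bit scalar for each of the three labels.
    Output is byte-stable: the same volume always produces the same file.
    """
    if value_map is None:
        value_map = DEFAULT_VALUE_MAP
    missing = [lab.name for lab in Label if lab not in value_map]
    if missing:
        raise ValueError(f"value_map missing labels: {missing}")
    for lab, v in value_map.items():
        if not (0 <= int(v) <= 255):
            raise ValueError(f"value_map[{lab.name}] must be in [0, 255], got {v}")

    nx, ny, nz = volume.meta.dims
    dx, dy, dz = volume.meta.spacing
    x0, y0, z0 = volume.meta.origin
    lut = np.zeros(256, dtype=np.uint8)
    for lab, v in value_map.items():
        lut[int(lab)] = int(v)
    scalars = lut[volume.labels]  # (ny, nx, nz)

    lines = [
        _HEADER_LINE,
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"SPACING {_fmt(dx)} {_fmt(dy)} {_fmt(dz)}",
        f"ORIGIN {_fmt(x0)} {_fmt(y0)} {_fmt(z0)}",
        f"POINT_DATA {nx * ny * nz}",
        f"SCALARS {scalar_name} unsigned_char 1",
        "LOOKUP_TABLE default",
    ]
    # one image row (nx scalars, x fastest) per line
    for z in range(nz):
        for y in range(ny):
            lines.append(" ".join(str(int(v)) for v in scalars[y, :, z]))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def _expect(line: str, lineno: int, what: str) -> list[str]:
    tokens = line.split()
    if not tokens:
        raise FormatError(f"line {lineno}: expected {what}, got empty line")
    return tokens


def read_vtk_structured_points(path: Path) -> tuple[np.ndarray, VolumeMeta]:
    """Read a legacy ASCII structured-points file written by this package.

    Returns the raw scalar grid with shape (ny, nx, nz) and the volume
    metadata.  Any deviation from the writer's dialect (wrong dataset type,
    inconsistent POINT_DATA count, unknown trailing attributes) is a
    :class:`FormatError` citing the offending line.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    if len(raw_lines) < 10:
        raise FormatError(f"{path}: too short to be a structured-points file")

    def fail(lineno: int, msg: str) -> None:
        raise FormatError(f"{path}: line {lineno}: {msg}: {raw_lines[lineno - 1]!r}")

    if not raw_lines[0].startswith("# vtk DataFile Version"):
        fail(1, "missing VTK version header")
    if raw_lines[2].strip() != "ASCII":
        fail(3, "only ASCII files are supported")
    if raw_lines[3].split() != ["DATASET", "STRUCTURED_POINTS"]:
        fail(4, "expected DATASET STRUCTURED_POINTS")

    dims = spacing = origin = None
    n_points = None
    idx = 4
    while idx < len(raw_lines):
        tokens = raw_lines[idx].split()
        idx += 1
        if not tokens:
            continue
        key = tokens[0]
        if key == "DIMENSIONS":
            dims = tuple(int(t) for t in tokens[1:])
        elif key == "SPACING":
            spacing = tuple(float(t) for t in tokens[1:])
        elif key == "ORIGIN":
            origin = tuple(float(t) for t in tokens[1:])
        elif key == "POINT_DATA":
            n_points = int(tokens[1])
            break
        else:
            fail(idx, f"unexpected header keyword {key!r}")
    if dims is None or len(dims) != 3:
        raise FormatError(f"{path}: missing or malformed DIMENSIONS")
    if spacing is None or len(spacing) != 3:
        raise FormatError(f"{path}: missing or malformed SPACING")
    if origin is None or len(origin) != 3:
        raise FormatError(f"{path}: missing or malformed ORIGIN")
    if n_points is None:
        raise FormatError(f"{path}: missing POINT_DATA")
    nx, ny, nz = dims
    if n_points != nx * ny * nz:
        raise FormatError(
            f"{path}: POINT_DATA {n_points} != DIMENSIONS product {nx * ny * nz}"
        )

    scalars_tokens = raw_lines[idx].split() if idx < len(raw_lines) else []
    if len(scalars_tokens) != 4 or scalars_tokens[0] != "SCALARS":
        fail(idx + 1, "expected 'SCALARS <name> <type> 1'")
    if scalars_tokens[2] != "unsigned_char":
        fail(idx + 1, f"unsupported scalar type {scalars_tokens[2]!r}")
    idx += 1
    if idx >= len(raw_lines) or raw_lines[idx].split() != ["LOOKUP_TABLE", "default"]:
        fail(idx + 1, "expected 'LOOKUP_TABLE default'")
    idx += 1

    values: list[int] = []
    for lineno in range(idx, len(raw_lines)):
        tokens = raw_lines[lineno].split()
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            fail(lineno + 1, "unexpected extra attribute after scalar data")
        values.extend(int(t) for t in tokens)
    if len(values) != n_points:
        raise FormatError(
            f"{path}: expected {n_points} scalars, found {len(values)}"
        )
    arr = np.asarray(values)
    if arr.min() < 0 or arr.max() > 255:
        raise FormatError(f"{path}: unsigned_char scalars out of [0, 255]")
    # x fastest, then y, then z -> reshape to (nz, ny, nx), reorder to (ny, nx, nz)
    grid = arr.astype(np.uint8).reshape(nz, ny, nx).transpose(1, 2, 0)
    meta = VolumeMeta(dims=(nx, ny, nz), spacing=spacing, origin=origin)
    return grid, meta
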