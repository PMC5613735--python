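"""End-to-end reconstruction: section images in, VTK volume + report out.

Stage order: read -> auto-contrast -> mark/grayscale -> smooth/down-sample
-> rigid align -> classify -> repair damaged slices -> region-grow cleanup
-> XY majority down-sample -> write VTK.  The run is deterministic given
fixed inputs and configuration; a structured JSON report and a per-slice
registration table are written next to the VTK file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass

import numpy as np

from . import __version__
from .config import PipelineConfig
from .errors import HistovolError, RegistrationError
from .preprocess import preprocess_section
from .registration import AlignmentReport, align_stack
from .segmentation import (
    classify_volume,
    interpolate_damaged_slices,
    region_grow_cleanup,
    volume_downsample,
)
from .stack_io import read_landmark_file, read_stack
from .volume import VolumeMeta
from .vtk_io import write_vtk_structured_points

__all__ = ["RunReport", "run_pipeline"]

log = logging.getLogger("histovol.pipeline")


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    registration: AlignmentReport
    counts_before_cleanup: dict[str, int]
    counts_after_cleanup: dict[str, int]
    removed_voxels: int
    positive_fraction: float
    final_dims: tuple[int, int, int]
    final_spacing: tuple[float, float, float]
    damaged_slices: tuple[int, ...]
    parameters: dict
    version: str = __version__

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "registration": list(self.registration.rows),
            "counts_before_cleanup": self.counts_before_cleanup,
            "counts_after_cleanup": self.counts_after_cleanup,
            "removed_voxels": self.removed_voxels,
            "positive_fraction": self.positive_fraction,
            "final_dims": list(self.final_dims),
            "final_spacing": list(self.final_spacing),
            "damaged_slices": list(self.damaged_slices),
            "parameters": self.parameters,
        }
        return json.dumps(payload, indent=1)


class _Stage:
    """Context that tags any failure with the stage name."""

    def __init__(self, name: str):
        self.name = name
        self.t0 = 0.0

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, HistovolError):
            exc.args = (f"[{self.name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
            return False
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def _load_landmarks(config: PipelineConfig, n_slices: int) -> list[np.ndarray | None]:
    if config.landmarks_dir is None:
        return [None] * n_slices
    out: list[np.ndarray | None] = []
    for k in range(n_slices):
        path = config.landmarks_dir / f"slice_{k:03d}.txt"
        out.append(read_landmark_file(path) if path.is_file() else None)
    counts = {pts.shape[0] for pts in out if pts is not None}
    if len(counts) > 1:
        raise RegistrationError(
            f"landmark files disagree on point count: {sorted(counts)}"
        )
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full reconstruction described by ``config``.

    Returns the run report; the VTK volume, the JSON report and the
    registration table (TSV) are written to the configured output paths.
    """
    with _Stage("read"):
        sections = read_stack(config.manifest)
        n = len(sections)
        damaged = tuple(
            sorted(
                {s.slice_index for s in sections if s.damaged}
                | set(config.extra_damaged_slices)
            )
        )
        for s in sections:
            if s.slice_index in damaged:
                s.damaged = True

    with _Stage("preprocess"):
        grays = [preprocess_section(s, config.preprocess) for s in sections]
        for g in grays:
            log.info(
                "slice %d: intensity min=%d max=%d",
                g.slice_index,
                int(g.pixels.min()),
                int(g.pixels.max()),
            )

    with _Stage("register"):
        ref = n // 2 if config.reference_index == "middle" else int(config.reference_index)
        landmarks = _load_landmarks(config, n)
        if config.preprocess.downsample_factor > 1:
            f = config.preprocess.downsample_factor
            landmarks = [lm / f if lm is not None else None for lm in landmarks]
        if all(lm is None for lm in landmarks):
            # no landmark files: stack is taken as already aligned
            aligned, transforms = grays, None
            reg_report = AlignmentReport(
                rows=tuple(
                    {"slice": k, "theta_deg": 0.0, "tx": 0.0, "ty": 0.0, "rms": 0.0}
                    for k in range(n)
                )
            )
        else:
            aligned, transforms, reg_report = align_stack(
                grays, landmarks, ref, mode=config.registration_mode
            )

    with _Stage("classify"):
        h, w = aligned[0].pixels.shape
        meta = VolumeMeta(
            dims=(w, h, n),
            spacing=config.spacing,
            origin=config.origin,
            unit_label=config.unit_label,
        )
        volume = classify_volume(aligned, config.thresholds, meta)
        log.info("class counts: %s", {k.name: v for k, v in volume.class_counts().items()})

    with _Stage("repair"):
        volume = interpolate_damaged_slices(volume, list(damaged))

    counts_before = {k.name: v for k, v in volume.class_counts().items()}

    with _Stage("region_grow"):
        volume, removed = region_grow_cleanup(
            volume, connectivity=config.connectivity, seed=config.region_grow_seed
        )
        log.info("region growing removed %d extra-organ voxels", removed)

    counts_after = {k.name: v for k, v in volume.class_counts().items()}
    positive_fraction = volume.positive_fraction()

    with _Stage("downsample"):
        volume = volume_downsample(volume, config.xy_downsample_factor)

    with _Stage("write"):
        config.vtk_out.parent.mkdir(parents=True, exist_ok=True)
        write_vtk_structured_points(volume, config.vtk_out, value_map=config.value_map)
        report = RunReport(
            registration=reg_report,
            counts_before_cleanup=counts_before,
            counts_after_cleanup=counts_after,
            removed_voxels=removed,
            positive_fraction=positive_fraction,
            final_dims=volume.meta.dims,
            final_spacing=volume.meta.spacing,
            damaged_slices=damaged,
            parameters=_echo_parameters(config),
        )
        config.report_out.parent.mkdir(parents=True, exist_ok=True)
        config.report_out.write_text(report.to_json())
        config.report_out.with_suffix(".registration.tsv").write_text(
            reg_report.to_tsv()
        )
    return report


def _echo_parameters(config: PipelineConfig) -> dict:
    return {
        "reference_index": config.reference_index,
        "registration_mode": config.registration_mode,
        "red_threshold": config.preprocess.red_threshold,
        "red_threshold_overrides": dict(config.preprocess.red_threshold_overrides),
        "mark_boost": config.preprocess.mark_boost,
        "autocontrast_saturation": config.preprocess.autocontrast_saturation,
        "gaussian_sigma": config.preprocess.gaussian_sigma,
        "downsample_factor": config.preprocess.downsample_factor,
        "positive_above": config.thresholds.positive_above,
        "background_below": config.thresholds.background_below,
        "connectivity": config.connectivity,
        "region_grow_seed": list(config.region_grow_seed)
        if not isinstance(config.region_grow_seed, str)
        else config.region_grow_seed,
        "xy_downsample_factor": config.xy_downsample_factor,
        "value_map": {k.name.lower(): v for k, v in config.value_map.items()},
        "spacing": list(config.spacing),
        "unit_label": config.unit_label,
    }
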