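"""Pipeline configuration: a strict, fully-defaulted YAML schema.

Unknown keys are rejected (typo protection), every invariant is checked up
front, and every defaulted field is logged, so a run either fails before
any computation or proceeds with a completely pinned-down parameter set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .preprocess import PreprocessParams
from .segmentation import ClassThresholds
from .volume import DEFAULT_SPACING, DEFAULT_UNIT_LABEL, Label

__all__ = ["PipelineConfig", "validate_config"]

log = logging.getLogger("histovol.config")

_LABEL_KEYS = {"background": Label.BACKGROUND, "negative": Label.NEGATIVE, "positive": Label.POSITIVE}


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted configuration of one reconstruction run."""

    manifest: Path
    vtk_out: Path
    report_out: Path
    landmarks_dir: Path | None = None
    reference_index: int | str = "middle"
    registration_mode: str = "chain"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    connectivity: int = 6
    region_grow_seed: tuple[int, int, int] | str = "auto"
    xy_downsample_factor: int = 1
    value_map: dict[Label, int] = field(
        default_factory=lambda: {Label.BACKGROUND: 0, Label.NEGATIVE: 100, Label.POSITIVE: 200}
    )
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit_label: str = DEFAULT_UNIT_LABEL
    extra_damaged_slices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.registration_mode not in ("chain", "direct"):
            raise ConfigError(
                f"registration_mode must be 'chain' or 'direct', got {self.registration_mode!r}"
            )
        if self.connectivity not in (6, 26):
            raise ConfigError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.xy_downsample_factor < 1:
            raise ConfigError(
                f"xy_downsample_factor must be >= 1, got {self.xy_downsample_factor}"
            )
        if isinstance(self.reference_index, str) and self.reference_index != "middle":
            raise ConfigError(
                f"reference_index must be an integer or 'middle', got {self.reference_index!r}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing values must be > 0, got {self.spacing}")
        for lab, v in self.value_map.items():
            if not (0 <= v <= 255):
                raise ConfigError(f"value_map[{lab.name.lower()}] must be in [0, 255], got {v}")


def _take(data: dict, key: str, default, used: set[str]):
    used.add(key)
    if key in data:
        return data[key]
    log.info("config: '%s' defaulted to %r", key, default)
    return default


def validate_config(path: Path) -> PipelineConfig:
    """Parse and validate a pipeline YAML file.

    Paths are resolved relative to the config file's directory.  Raises
    :class:`ConfigError` for unknown keys or out-of-bound values, naming
    the offending field.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    base = path.parent
    used: set[str] = set()

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    if "manifest" not in data:
        raise ConfigError(f"{path}: required key 'manifest' missing")
    manifest = resolve(_take(data, "manifest", None, used))
    if not manifest.is_file():
        raise ConfigError(f"manifest does not exist: {manifest}")

    output = _take(data, "output", {}, used)
    if not isinstance(output, dict):
        raise ConfigError("'output' must be a mapping with keys 'vtk' and 'report'")
    unknown_out = set(output) - {"vtk", "report"}
    if unknown_out:
        raise ConfigError(f"unknown keys under 'output': {sorted(unknown_out)}")
    vtk_out = resolve(output.get("vtk", "volume.vtk"))
    report_out = resolve(output.get("report", "report.json"))

    lm = _take(data, "landmarks_dir", None, used)
    landmarks_dir = resolve(lm) if lm is not None else None
    if landmarks_dir is not None and not landmarks_dir.is_dir():
        raise ConfigError(f"landmarks_dir does not exist: {landmarks_dir}")

    pp_data = _take(data, "preprocess", {}, used)
    if not isinstance(pp_data, dict):
        raise ConfigError("'preprocess' must be a mapping")
    pp_known = {
        "red_threshold",
        "red_threshold_overrides",
        "mark_boost",
        "autocontrast_saturation",
        "gaussian_sigma",
        "downsample_factor",
    }
    unknown_pp = set(pp_data) - pp_known
    if unknown_pp:
        raise ConfigError(f"unknown keys under 'preprocess': {sorted(unknown_pp)}")
    overrides = {
        int(k): int(v)
        for k, v in (pp_data.get("red_threshold_overrides") or {}).items()
    }
    preprocess = PreprocessParams(
        red_threshold=int(pp_data.get("red_threshold", 25)),
        red_threshold_overrides=overrides,
        mark_boost=int(pp_data.get("mark_boost", 100)),
        autocontrast_saturation=float(pp_data.get("autocontrast_saturation", 0.0035)),
        gaussian_sigma=float(pp_data.get("gaussian_sigma", 0.0)),
        downsample_factor=int(pp_data.get("downsample_factor", 1)),
    )

    th_data = _take(data, "thresholds", {}, used)
    if not isinstance(th_data, dict):
        raise ConfigError("'thresholds' must be a mapping")
    unknown_th = set(th_data) - {"positive_above", "background_below"}
    if unknown_th:
        raise ConfigError(f"unknown keys under 'thresholds': {sorted(unknown_th)}")
    thresholds = ClassThresholds(
        positive_above=int(th_data.get("positive_above", 80)),
        background_below=int(th_data.get("background_below", 3)),
    )

    vm_data = _take(
        data, "value_map", {"background": 0, "negative": 100, "positive": 200}, used
    )
    if set(vm_data) - set(_LABEL_KEYS):
        raise ConfigError(
            f"unknown keys under 'value_map': {sorted(set(vm_data) - set(_LABEL_KEYS))}"
        )
    value_map = {Label.BACKGROUND: 0, Label.NEGATIVE: 100, Label.POSITIVE: 200}
    for k, v in vm_data.items():
        value_map[_LABEL_KEYS[k]] = int(v)

    seed = _take(data, "region_grow_seed", "auto", used)
    if isinstance(seed, (list, tuple)):
        if len(seed) != 3:
            raise ConfigError(f"region_grow_seed must be [x, y, z], got {seed}")
        seed = tuple(int(v) for v in seed)
    elif seed != "auto":
        raise ConfigError(f"region_grow_seed must be [x, y, z] or 'auto', got {seed!r}")

    spacing = tuple(float(v) for v in _take(data, "spacing", list(DEFAULT_SPACING), used))
    if len(spacing) != 3:
        raise ConfigError(f"spacing must have 3 values, got {spacing}")
    origin = tuple(float(v) for v in _take(data, "origin", [0.0, 0.0, 0.0], used))
    if len(origin) != 3:
        raise ConfigError(f"origin must have 3 values, got {origin}")

    ref = _take(data, "reference_index", "middle", used)
    if not isinstance(ref, str):
        ref = int(ref)

    config = PipelineConfig(
        manifest=manifest,
        vtk_out=vtk_out,
        report_out=report_out,
        landmarks_dir=landmarks_dir,
        reference_index=ref,
        registration_mode=str(_take(data, "registration_mode", "chain", used)),
        preprocess=preprocess,
        thresholds=thresholds,
        connectivity=int(_take(data, "connectivity", 6, used)),
        region_grow_seed=seed,
        xy_downsample_factor=int(_take(data, "xy_downsample_factor", 1, used)),
        value_map=value_map,
        spacing=spacing,  # type: ignore[arg-type]
        origin=origin,  # type: ignore[arg-type]
        unit_label=str(_take(data, "unit_label", DEFAULT_UNIT_LABEL, used)),
        extra_damaged_slices=tuple(
            int(v) for v in _take(data, "damaged_slices", [], used)
        ),
    )
    unknown = set(data) - used
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return config
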