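"""Run configuration (YAML) and validated CSV table I/O."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .segmentation import SegmentationConfig
from .synth import PopulationModel

__all__ = [
    "ConfigError",
    "TableSchemaError",
    "RunConfig",
    "PopulationSection",
    "SegmentationSection",
    "CellCycleSection",
    "SceneSection",
    "load_config",
    "save_config",
    "write_table",
    "read_table",
]


class ConfigError(ValueError):
    """Configuration file is missing, malformed, or fails validation."""


class TableSchemaError(ValueError):
    """A CSV table does not match its declared column schema."""


class PopulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    condition: str
    length_mean_um: float = Field(gt=0)
    length_sd_um: float = Field(default=0.0, ge=0)
    width_mean_um: float = Field(gt=0)
    width_sd_um: float = Field(default=0.0, ge=0)
    lw_correlation: float = Field(default=0.3, ge=-1.0, le=1.0)
    growth_rate_per_h: Optional[float] = Field(default=None, gt=0)

    def to_model(self) -> PopulationModel:
        return PopulationModel(
            condition_name=self.condition,
            length_mean_um=self.length_mean_um,
            length_sd_um=self.length_sd_um,
            width_mean_um=self.width_mean_um,
            width_sd_um=self.width_sd_um,
            lw_correlation=self.lw_correlation,
            growth_rate_per_h=self.growth_rate_per_h,
        )


class SegmentationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    threshold_offset: float = 0.0
    min_area_um2: float = Field(default=0.2, gt=0)
    max_area_um2: float = Field(default=25.0, gt=0)
    min_mean_intensity: Optional[float] = None
    max_mean_intensity: Optional[float] = None
    exclude_border: bool = True
    smoothing_sigma_px: float = Field(default=1.0, ge=0)

    def to_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            threshold_offset=self.threshold_offset,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            min_mean_intensity=self.min_mean_intensity,
            max_mean_intensity=self.max_mean_intensity,
            exclude_border=self.exclude_border,
            smoothing_sigma_px=self.smoothing_sigma_px,
        )


class CellCycleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c_min: float = Field(default=40.0, gt=0)
    d_min: float = Field(default=20.0, gt=0)


class SceneSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    image_shape_px: tuple[int, int] = (1000, 1000)
    blur_sigma_px: float = Field(default=1.0, ge=0)
    noise_sd: float = Field(default=150.0, ge=0)
    background_level: float = Field(default=10000.0, gt=0)
    cell_level: float = Field(default=3000.0, ge=0)
    halo_amplitude: float = Field(default=1500.0, ge=0)
    halo_width_um: float = Field(default=0.15, gt=0)


class RunConfig(BaseModel):
    """Validated top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(default=0, ge=0)
    pixel_size_um: float = Field(default=0.065, gt=0)
    populations: list[PopulationSection] = Field(default_factory=list)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    cellcycle: CellCycleSection = Field(default_factory=CellCycleSection)
    scene: SceneSection = Field(default_factory=SceneSection)
    output_dir: str = "results"
    log_level: str = "INFO"

    def population_models(self) -> list[PopulationModel]:
        """Configured populations, or the packaged reference models if none."""
        if self.populations:
            return [p.to_model() for p in self.populations]
        from .reference import population_models

        return population_models()


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults are filled in."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def write_table(
    frame: pd.DataFrame, path: str | Path, schema: dict[str, str] | None = None
) -> None:
    """Write a CSV table (UTF-8, '.' decimal), validating columns first."""
    if schema is not None:
        missing = set(schema) - set(frame.columns)
        if missing:
            raise TableSchemaError(f"missing columns: {sorted(missing)}")
    frame.to_csv(path, index=False, encoding="utf-8")


_KIND_CHECK = {
    "float": pd.api.types.is_numeric_dtype,
    "int": pd.api.types.is_integer_dtype,
    "str": lambda s: pd.api.types.is_object_dtype(s) or pd.api.types.is_string_dtype(s),
}


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    """Read a CSV table and validate it against ``schema`` (name -> kind).

    Kinds: ``float`` (any numeric), ``int``, ``str``.  Missing columns or
    non-coercible types raise :class:`TableSchemaError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise TableSchemaError(f"cannot read table {path}: {exc}") from exc
    missing = set(schema) - set(frame.columns)
    if missing:
        raise TableSchemaError(f"{path}: missing columns {sorted(missing)}")
    for name, kind in schema.items():
        check = _KIND_CHECK.get(kind)
        if check is None:
            raise TableSchemaError(f"unknown schema kind {kind!r} for column {name!r}")
        if not check(frame[name]):
            raise TableSchemaError(
                f"{path}: column {name!r} is not of kind {kind!r} "
                f"(dtype {frame[name].dtype})"
            )
    return frame
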