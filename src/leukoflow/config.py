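"""Run configuration: one YAML-serializable object driving every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .gating import GatingConfig
from .synth import STRONG_BATCH_EFFECTS, BatchEffectConfig


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    ``batch_effects`` selects a donor-variation preset: ``default`` (mild),
    ``strong`` (pronounced illumination/focus/size differences between
    donors) or ``none``.
    """

    seed: int = 0
    n_donors: int = 13
    cells_per_donor: int = 500
    artifact_fraction: float = 0.0
    batch_effects: str = "default"
    tile_shape: tuple[int, int] = (64, 64)
    focus_threshold: float = 55.0
    area_min: float = 30.0
    area_max: float = 1250.0
    aspect_ratio_min: float = 0.6
    classifiers: tuple[str, ...] = (
        "adaboost",
        "gradient_boosting",
        "knn",
        "random_forest",
        "svm",
    )
    n_runs: int = 10
    cv_mode: str = "subject"  # "subject" or "shuffle"
    test_fraction: float = 0.25  # shuffle mode only
    f1_average: str = "macro"

    def __post_init__(self) -> None:
        if self.batch_effects not in ("default", "strong", "none"):
            raise ValueError("batch_effects must be default, strong or none")
        if self.cv_mode not in ("subject", "shuffle"):
            raise ValueError("cv_mode must be 'subject' or 'shuffle'")

    def batch_config(self) -> BatchEffectConfig:
        if self.batch_effects == "strong":
            return STRONG_BATCH_EFFECTS
        if self.batch_effects == "none":
            return BatchEffectConfig(0.0, 0.0, 0.0)
        return BatchEffectConfig()

    def gating_config(self) -> GatingConfig:
        return GatingConfig(
            focus_threshold=self.focus_threshold,
            area_min=self.area_min,
            area_max=self.area_max,
            aspect_ratio_min=self.aspect_ratio_min,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["tile_shape"] = list(self.tile_shape)
        data["classifiers"] = list(self.classifiers)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "tile_shape" in data:
            data["tile_shape"] = tuple(data["tile_shape"])
        if "classifiers" in data:
            data["classifiers"] = tuple(data["classifiers"])
        return cls(**data)
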