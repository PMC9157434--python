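"""Run configuration: defaults, YAML merge, and echo-back serialization."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .imaging import ColorConfig, PipelineConfig, ScoreThresholds


@dataclass
class RunConfig:
    """Fully resolved configuration of one run.

    Every field has a default; a YAML document overrides fields block by
    block and the resolved config is echoed next to the outputs so a run
    can be reproduced from its own artefacts.
    """

    color: ColorConfig = field(default_factory=ColorConfig)
    thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)
    algorithm: str = "AUT1"
    opening_radius_frac: float = 0.02
    selection_policy: str = "left_default"
    deficit_tol: float = 0.05
    alteration_rel_tol: float = 0.15
    n_boot: int = 5000
    seed: Optional[int] = None

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(
            color=self.color,
            thresholds=self.thresholds,
            algorithm=self.algorithm,
            opening_radius_frac=self.opening_radius_frac,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["color"]["background_hue_window"] = list(self.color.background_hue_window)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "RunConfig":
        cfg = cls()
        if path is None:
            return cfg
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RunConfig":
        cfg = cls()
        color_doc = dict(doc.pop("color", {}) or {})
        if "background_hue_window" in color_doc:
            color_doc["background_hue_window"] = tuple(
                color_doc["background_hue_window"]
            )
        thr_doc = dict(doc.pop("thresholds", {}) or {})
        color = dataclasses.replace(cfg.color, **color_doc)
        thresholds = dataclasses.replace(cfg.thresholds, **thr_doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(color=color, thresholds=thresholds, **doc)
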