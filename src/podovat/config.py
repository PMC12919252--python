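"""Run configuration: defaults, YAML round-trip, provenance hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the published defaults.

    Thresholds: section thickness fallback 4.54 μm, shape coefficient
    0.72, Weibel–Gomez β 1.38 / size coefficient 1.01, fat window
    −150..−50 HU, VO threshold 100 cm², closing radius 2 px.
    """

    annotations: Optional[str] = None  # file or directory of GeoJSON slides
    ct_image: Optional[str] = None
    cavity_mask: Optional[str] = None
    cohort_csv: Optional[str] = None
    output_dir: str = "podovat_out"
    pixel_size_um: float = 0.5
    thickness_T: float = 4.54
    shape_k: float = 0.72
    wg_beta: float = 1.38
    wg_size_coef: float = 1.01
    hu_min: float = -150.0
    hu_max: float = -50.0
    vo_threshold_cm2: float = 100.0
    closing_radius: int = 2
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "thickness_T", "shape_k", "wg_beta",
                     "wg_size_coef", "vo_threshold_cm2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.hu_min >= self.hu_max:
            raise ValueError("hu_min must be below hu_max")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        """Short SHA-256 of the canonical YAML dump, for run provenance."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
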