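"""Run configuration: YAML round-trip and hashing for reproducible runs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate -> process -> analyze run."""

    mode: str = "phantom"  # "phantom" | "invivo"
    agent: str = "glucose"
    B0: float = 7.0
    B1: float = 3.0
    duration_s: float = 5.0
    offset_step_ppm: float = 0.2
    offset_half_range_ppm: float = 6.0
    analysis_offset_ppm: float = 1.2
    s0_offset_ppm: float = -10.0
    r2_threshold: float = 0.97
    segmentation_fraction: float = 0.1
    matrix: tuple[int, int] = (64, 64)
    snr: float = 50.0
    seed: int = 0
    # phantom mode
    pH_values: tuple[float, ...] = (7.4, 7.0, 6.8, 6.6, 6.4, 6.2, 6.0)
    concentration_mM: float = 20.0
    fieldmap_amplitude_ppm: float = 0.0
    # invivo mode
    uptake_kind: str = "rising"
    dose_g_per_kg: float = 3.0
    n_post_frames: int = 5
    frame_interval_min: float = 6.0
    medium: str | None = None  # default: solution for phantom, tissue for invivo
    output_dir: str = "glucocest_out"

    def __post_init__(self) -> None:
        if self.mode not in ("phantom", "invivo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.matrix = tuple(int(v) for v in self.matrix)  # type: ignore[assignment]
        self.pH_values = tuple(float(v) for v in self.pH_values)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["matrix"] = list(self.matrix)
        d["pH_values"] = list(self.pH_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable short hash of the canonicalised configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
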