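"""Pipeline configuration with paper-faithful defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """Every analysis knob in one serializable bundle.

    Defaults reproduce the published analysis choices: raw MAD (no
    consistency constant), centre-then-scale normalization, 99th percentile
    with linear interpolation, strict Iverson bracket, four baseline
    frames, 8-connectivity with a 5-pixel minimum cluster area, a
    mean + 3 SD end-point rule and a 50% mutual-blocking threshold.
    """

    percentile: float = 99.0
    percentile_method: str = "linear"
    mad_constant: float = 1.0
    normalization_order: str = "center_then_scale"
    iverson_strict: bool = True
    n_baseline_frames: int = 4
    cluster_connectivity: int = 8
    cluster_min_area: int = 5
    endpoint_sd_multiplier: float = 3.0
    blocking_threshold: float = 50.0
    min_self_separation: float = 0.25
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in output logs."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
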