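"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .morphometry import SegmentationConfig

__all__ = ["PipelineConfig", "load_config", "default_config_path"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    output_dir: str = "erymorph_out"
    calibration: float = 0.05  # um per pixel
    # synthetic panel
    n_sheep: int = 36
    cells_per_sheep: int = 110
    # demo smear image
    demo_image: bool = True
    demo_image_cells: int = 20
    # segmentation
    threshold: float | None = None
    min_area_um2: float = 6.0
    max_area_um2: float = 32.0
    min_solidity: float = 0.95
    smooth_sigma: float = 2.0
    # typing
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    strict_multiplier: float = 3.0
    min_proportion: float = 0.05
    # grouping: parameter -> (cutoff, rule); None = published cut-offs
    groupings: dict | None = None

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            threshold=self.threshold,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            min_solidity=self.min_solidity,
            smooth_sigma=self.smooth_sigma,
        )

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML (default file if None)."""
    path = Path(path) if path is not None else default_config_path()
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "k_range" in raw:
        raw["k_range"] = tuple(raw["k_range"])
    return PipelineConfig(**raw)
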