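"""Pipeline configuration: YAML-loadable, validated, fully logged.

The configuration mirrors the processing chain: simulation span and scene
composition, per-detector parameter blocks, the VCT calibration block, the
random-forest block, the ensemble scheme, and age-encoding constants.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import yaml

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    span: tuple = (1986, 2021)
    obs_per_year: int = 8
    reference_year: int = 2020
    min_year: int = 1987
    scheme: str = "vcr2"
    seed: int = 0
    scene: dict = field(
        default_factory=lambda: {
            "n_rows": 20,
            "n_cols": 20,
            "noise_sd": 0.015,
            "cloud_fraction": 0.3,
            "establishment_range": (1990, 2018),
        }
    )
    macd: dict = field(default_factory=lambda: {"window": 3, "persistence": 2})
    lt: dict = field(
        default_factory=lambda: {
            "max_segments": 6,
            "recovery_threshold": 0.4,
            "despike_threshold": 0.9,
        }
    )
    vct: dict = field(default_factory=lambda: {"consecutive": 2, "prior_nonforest_consecutive": 3})
    ccdc: dict = field(
        default_factory=lambda: {
            "k_sigma": 3.0,
            "run_length": 6,
            "max_segments": 6,
            "n_init": 12,
        }
    )
    rf: dict = field(default_factory=lambda: {"n_trees": 500})
    calibration: dict = field(
        default_factory=lambda: {
            "cell_size": 3.0,
            "min_samples": 100,
            "percentile": 0.95,
            "min_threshold": 0.5,
            "n_stable_samples": 120,
            "n_secondary_samples": 100,
        }
    )

    def __post_init__(self) -> None:
        self.span = tuple(int(y) for y in self.span)
        if len(self.span) != 2 or self.span[1] <= self.span[0]:
            raise ValueError("span must be (start_year, end_year)")
        if not self.min_year <= self.reference_year:
            raise ValueError("min_year must not exceed reference_year")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, apply overrides, validate, and log the result."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    log.info("resolved config: %s", cfg.to_dict())
    return cfg
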