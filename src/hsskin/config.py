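"""Run configuration: a validated, YAML-round-trippable parameter set."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .classify import ModelConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline/experiment run needs, with defaults recorded."""

    # scene generation
    n_scenes: int = 17
    height_px: int = 256
    width_px: int = 256
    noise_sd: float = 0.005
    class_mix: dict = field(default_factory=lambda: {"bcc": 10 / 17, "id_nevus": 7 / 17})
    # light geometry
    elevation_deg: float = 60.0
    azimuths_deg: tuple = (90.0, 330.0, 210.0)
    # processing
    tv_weight: float = 10.0
    epsilon: float = 1e-8
    clamp_nz: float = 0.01
    depth_wavelength_nm: float = 575.0
    # sampling / windowing
    window: int = 30
    step: int = 5
    margin: int = 15
    n_lesion: int = 250
    n_healthy: int = 100
    # model
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_scenes < 1:
            raise ValueError("n_scenes must be >= 1")
        if self.window != 2 * self.margin:
            raise ValueError("window must be twice the sampling margin")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.tv_weight <= 0 or self.epsilon <= 0:
            raise ValueError("tv_weight and epsilon must be > 0")

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        if "model" in raw and isinstance(raw["model"], dict):
            m = raw["model"]
            for key in ("conv3d_blocks", "conv2d_blocks"):
                if key in m:
                    m[key] = tuple(
                        (int(f), tuple(k), tuple(p)) for f, k, p in m[key]
                    )
            if "dense_units" in m:
                m["dense_units"] = tuple(m["dense_units"])
            raw["model"] = ModelConfig(**m)
        if "azimuths_deg" in raw:
            raw["azimuths_deg"] = tuple(raw["azimuths_deg"])
        return cls(**raw)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, model=replace(self.model, seed=seed))
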