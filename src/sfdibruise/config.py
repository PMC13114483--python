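"""Pipeline configuration loaded from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import forward
from .nn.losses import LAMBDA_L1

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Shared knobs of the simulation/prediction/discrimination pipeline."""

    fx_ac: float = forward.DEFAULT_FX_AC
    n: float = forward.DEFAULT_N
    mueff_dialect: str = "squared"
    lambda_l1: float = LAMBDA_L1
    norm_ranges: tuple[float, float] = (0.5, 4.0)
    image_size: int = 64
    noise_sd: float = 0.005
    seed: int = 0
    k_height: float = 1.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fx_ac <= 0:
            raise ValueError("fx_ac must be > 0")
        if self.mueff_dialect not in ("squared", "printed"):
            raise ValueError(f"unknown dialect {self.mueff_dialect!r}")

    def save(self, path) -> None:
        d = asdict(self)
        d["norm_ranges"] = list(d["norm_ranges"])
        Path(path).write_text(yaml.safe_dump(d))


def load_config(path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extras"}
    kwargs = {k: v for k, v in d.items() if k in known}
    if "norm_ranges" in kwargs:
        kwargs["norm_ranges"] = tuple(kwargs["norm_ranges"])
    extras = {k: v for k, v in d.items() if k not in known}
    return PipelineConfig(**kwargs, extras=extras)
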