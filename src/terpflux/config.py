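"""Run configuration: a validated bundle of the pipeline's tunables."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .megan import MeganConfig
from .standardization import StandardizationConstants

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All pipeline parameters in one place.

    ``seed`` drives every stochastic command; LOQ, station pressure, the
    local-time offset, the temperature bin width and the reference
    temperature mirror the defaults documented in the individual modules.
    """

    seed: int = 0
    loq_pptv: float = 2.0
    pressure_kpa: float = 96.0
    timezone_offset_h: int = -9            # Alaska standard time
    bin_width_c: float = 2.0
    reference_t_c: float = 20.0
    windows: dict = field(default_factory=lambda: {
        "daytime": (10, 20), "midday": (11, 14), "nighttime": (23, 5)})
    standardization: StandardizationConstants = field(
        default_factory=StandardizationConstants)
    megan: MeganConfig = field(default_factory=MeganConfig)

    def __post_init__(self) -> None:
        if self.loq_pptv <= 0:
            raise ValueError("loq_pptv must be positive")
        if self.pressure_kpa <= 0:
            raise ValueError("pressure_kpa must be positive")
        if self.bin_width_c <= 0:
            raise ValueError("bin_width_c must be positive")
        for name, (a, b) in self.windows.items():
            if not (0 <= a <= 24 and 0 <= b <= 24):
                raise ValueError(f"window {name!r} hours must lie in [0, 24]")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file (missing keys default)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    std = raw.pop("standardization", None)
    meg = raw.pop("megan", None)
    windows = raw.pop("windows", None)
    cfg = RunConfig(**raw)
    if windows is not None:
        cfg.windows = {k: tuple(v) for k, v in windows.items()}
        cfg.__post_init__()
    if std is not None:
        cfg.standardization = StandardizationConstants(**std)
    if meg is not None:
        cfg.megan = MeganConfig(**meg)
    return cfg
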