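"""Run configuration: restart probability, logistic/GIP parameters, variant.

Defaults follow the published parameterization: restart probability
alpha = 0.3, convergence tolerance 1e-6 on the elementwise max-abs
difference, logistic parameters c = -15 and d = log(9999) (so that
L(0) = 0.0001 and L(0.3) < 0.01), neighbor threshold 0.4 on String-style
confidence scores, and GIP bandwidth multipliers gamma'_r = gamma'_t = 1.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

VARIANTS = ("full", "no_gip", "equal_weights")


@dataclass
class RunConfig:
    alpha: float = 0.3
    tolerance: float = 1e-6
    max_iterations: int = 1000
    logistic_c: float = -15.0
    logistic_d: float = field(default_factory=lambda: math.log(9999.0))
    neighbor_threshold: float = 0.4
    gamma_r: float = 1.0
    gamma_t: float = 1.0
    fingerprint_bits: int = 2048
    fingerprint_radius: int = 2
    variant: str = "full"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")
        if not 0.0 <= self.neighbor_threshold <= 1.0:
            raise ValueError("neighbor_threshold must be in [0, 1]")
        if self.gamma_r <= 0 or self.gamma_t <= 0:
            raise ValueError("GIP bandwidth multipliers must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise TypeError(f"config file {path} must contain a mapping")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
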