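"""Run configuration: central defaults, validation, file loading.

The standard parameter set (inferred defaults, see docs/methods.md):
L=4, s=0.05, eps=1.0, mu=1e-5, r=0.05, deterministic fixation threshold
0.99, stochastic threshold 0.95, 50 replicates per arm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunable parameters with their central defaults.

    Every field is echoed verbatim into output manifests so any screen row
    can be replayed.
    """

    # landscape
    L: int = 4
    s: float = 0.05
    eps: float = 1.0
    # deterministic dynamics
    mu: float = 1e-5
    r: float = 0.05
    det_fixation_threshold: float = 0.99
    t_max: float = 1e6
    rate_convention: str = "total"  # r is total per genome; each locus r/L
    # stochastic dynamics
    N0: int = 10_000
    B: float = 1.0
    stoch_fixation_threshold: float = 0.95
    n_reps: int = 50
    tau_leap_threshold: float = 100.0
    stoch_t_max: float | None = None
    # screening
    max_lfgs: int = 10
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got L={self.L}")
        if self.s <= 0 or self.eps <= 0:
            raise ValueError(f"s and eps must be positive (s={self.s}, eps={self.eps})")
        if self.s * self.L ** self.eps > 1:
            raise ValueError(
                f"negative fitness at the all-0 genotype: "
                f"s*L**eps = {self.s * self.L ** self.eps:.4g} > 1 "
                f"(s={self.s}, L={self.L}, eps={self.eps})")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be >= 0")
        for name in ("det_fixation_threshold", "stoch_fixation_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.rate_convention not in ("total", "per_locus"):
            raise ValueError(f"unknown rate_convention {self.rate_convention!r}")
        if self.N0 < 2 or self.B <= 0 or self.n_reps < 1:
            raise ValueError("need N0 >= 2, B > 0, n_reps >= 1")
        n_inter = (1 << self.L) - 2
        if not 0 <= self.max_lfgs <= n_inter:
            raise ValueError(f"max_lfgs must be in [0, {n_inter}]")

    def to_manifest(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file and apply keyword overrides.

    Unknown keys are rejected; the effective configuration is validated as
    a whole. With no path, defaults plus overrides are used.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_manifest(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_manifest(), indent=2) + "\n")
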