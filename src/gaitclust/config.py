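"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clustering import DEFAULT_K_RANGE, DEFAULT_N_RESTARTS, DEFAULT_REPETITIONS
from .selection import DEFAULT_REPEATABILITY_THRESHOLD
from .synthetic import DEFAULT_SIZES

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the reference analysis settings
    (k 2-5, 50 restarts, 10 repetitions, alpha 0.05, cohort 5/12/12/8)."""

    cohort_csv: str | None = None
    nd_csv: str | None = None
    output_dir: str = "gaitclust_out"
    k_range: tuple[int, ...] = DEFAULT_K_RANGE
    n_restarts: int = DEFAULT_N_RESTARTS
    n_repetitions: int = DEFAULT_REPETITIONS
    repeatability_threshold: float = DEFAULT_REPEATABILITY_THRESHOLD
    alpha: float = 0.05
    master_seed: int = 0
    sizes: tuple[int, ...] = DEFAULT_SIZES
    amplitude_scale: float = 1.0
    noise_sd: float = 3.25
    noise_corr_len: float = 10.0

    def validate(self) -> "PipelineConfig":
        ks = tuple(sorted(int(k) for k in self.k_range))
        if not ks or ks[0] < 2:
            raise ValueError(f"k_range must contain integers >= 2, got {self.k_range}")
        self.k_range = ks
        if self.n_restarts < 1 or self.n_repetitions < 1:
            raise ValueError("n_restarts and n_repetitions must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0 <= self.repeatability_threshold <= 100):
            raise ValueError("repeatability_threshold must be in [0, 100]")
        self.sizes = tuple(int(s) for s in self.sizes)
        if len(self.sizes) != 4 or any(s < 0 for s in self.sizes):
            raise ValueError(f"sizes must be 4 non-negative integers, got {self.sizes}")
        if self.noise_sd < 0 or self.noise_corr_len <= 0:
            raise ValueError("noise_sd must be >= 0 and noise_corr_len > 0")
        return self

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["sizes"] = list(self.sizes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data).validate()
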