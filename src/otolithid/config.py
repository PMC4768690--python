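"""Run configuration shared by the CLI commands.

All pipeline parameters with their standard defaults: binarization threshold
0.1, small-object filter 50,000 px, resampling to 1,000 samples, Gaussian
window of 100 samples with 40-sample overlap (16 segments, 129 bins),
combined 32-element features, uniform DA priors. Precedence when running
the CLI is flag > config file > default, and the effective configuration is
written next to every output for auditability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidInputError
from .spectral import WINDOW_KINDS, WindowSpec

__all__ = ["RunConfig"]

_FEATURE_SETS = ("abs_only", "ang_only", "combined")


@dataclass
class RunConfig:
    threshold: float = 0.1
    min_area: int = 50_000
    ordering: str = "traversal"
    resample_n: int = 1000
    window_kind: str = "gaussian"
    window_length: int = 100
    window_overlap: int = 40
    window_shape_param: float | None = None
    nfft: int | None = None  # None -> max(256, next power of two >= window_length)
    zscore_ddof: int = 1
    feature_set: str = "combined"
    prior: str = "uniform"
    ridge: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise InvalidInputError("threshold must be in (0, 1)")
        if self.window_kind not in WINDOW_KINDS:
            raise InvalidInputError(f"unknown window kind {self.window_kind!r}")
        if not 0 <= self.window_overlap < self.window_length:
            raise InvalidInputError("need 0 <= overlap < window length")
        if self.window_length > self.resample_n:
            raise InvalidInputError("window length exceeds resampled signal length")
        if self.feature_set not in _FEATURE_SETS:
            raise InvalidInputError(f"feature_set must be one of {_FEATURE_SETS}")
        if self.ordering not in ("traversal", "angle_sorted"):
            raise InvalidInputError("ordering must be 'traversal' or 'angle_sorted'")
        if self.zscore_ddof not in (0, 1):
            raise InvalidInputError("zscore_ddof must be 0 or 1")

    @property
    def window(self) -> WindowSpec:
        return WindowSpec(
            kind=self.window_kind,
            length=self.window_length,
            overlap=self.window_overlap,
            shape_param=self.window_shape_param,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON (decided by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
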