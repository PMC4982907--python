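"""Run configuration: every analysis knob in one serialisable record.

All downstream outputs embed the configuration hash and master seed so a
result can always be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .types import ClassifierThresholds


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings.

    sdf_bandwidth : Gaussian kernel SD of the spike density function, s.
    sdf_dt        : grid step of the spike density function, s.
    latency_frac  : latency threshold as a fraction of the window peak.
    latency_min_dur : minimum supra-threshold duration for a latency, s.
    duration_window : response-duration integration window, s.
    direction_mode  : "count" (default) uses the mean firing rate during
                      the bar transit per direction, "peak" the SDF peak.
    chi2_correction : apply the Yates continuity correction to 2x2 tests.
    """

    seed: int = 0
    sdf_bandwidth: float = 0.025
    sdf_dt: float = 0.002
    latency_frac: float = 0.1
    latency_min_dur: float = 0.050
    duration_window: float = 0.5
    direction_mode: str = "count"
    n_trials: int = 5
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    chi2_correction: bool = False
    density_grid_um: float = 100.0
    density_min_density: float = 0.25

    def __post_init__(self) -> None:
        if self.sdf_bandwidth <= 0 or self.sdf_dt <= 0:
            raise ValueError("sdf_bandwidth and sdf_dt must be > 0")
        if not (0 < self.latency_frac < 1):
            raise ValueError("latency_frac must lie in (0, 1)")
        if self.latency_min_dur <= 0 or self.duration_window <= 0:
            raise ValueError("latency_min_dur and duration_window must be > 0")
        if self.direction_mode not in ("peak", "count"):
            raise ValueError("direction_mode must be 'peak' or 'count'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        thr = d.pop("thresholds", None)
        cfg = cls(**d) if thr is None else cls(
            **d, thresholds=ClassifierThresholds(**thr)
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)

    @property
    def config_hash(self) -> str:
        """Short sha256 of the canonical YAML form."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
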