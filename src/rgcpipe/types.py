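"""Core domain types shared across the pipeline.

Units follow the conventions used throughout: times in seconds, positions and
stimulus sizes in micrometres (μm), speeds in μm/s, firing rates in action
potentials per second (AP/s), angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class Polarity(str, Enum):
    """Response polarity: firing increases at light onset, offset, or both."""

    ON = "ON"
    OFF = "OFF"
    ON_OFF = "ON_OFF"


class Protocol(str, Enum):
    """The five stimulus protocols every cell is assayed with."""

    CONTRAST_STEP = "contrast_step"
    SIZE_SERIES = "size_series"
    DIRECTION_SERIES = "direction_series"
    SPEED_SERIES = "speed_series"
    TEMPORAL_MODULATION = "temporal_modulation"


class ClassLabel(str, Enum):
    """Six functional groups plus a catch-all for cells matching none."""

    ON_OFF_DS = "ON_OFF_DS"
    OFF_SUSTAINED = "OFF_SUSTAINED"
    OFF_TRANSIENT = "OFF_TRANSIENT"
    ON_SUSTAINED = "ON_SUSTAINED"
    ON_TRANSIENT = "ON_TRANSIENT"
    ON_SMALL_TRANSIENT = "ON_SMALL_TRANSIENT"
    UNCLASSIFIED = "UNCLASSIFIED"


SIX_CLASSES = (
    ClassLabel.ON_OFF_DS,
    ClassLabel.OFF_SUSTAINED,
    ClassLabel.OFF_TRANSIENT,
    ClassLabel.ON_SUSTAINED,
    ClassLabel.ON_TRANSIENT,
    ClassLabel.ON_SMALL_TRANSIENT,
)


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus condition; trials reference an epoch by ``epoch_id``.

    ``onset`` is the stimulus-on time within the trial and ``duration`` the
    stimulus-on interval; ``trial_duration`` is the full recorded window so a
    pre-onset baseline and a post-offset tail are available.
    """

    epoch_id: str
    protocol: Protocol
    onset: float
    duration: float
    trial_duration: float
    diameter: Optional[float] = None
    contrast: float = 1.0
    direction: Optional[float] = None
    speed: Optional[float] = None
    frequency: Optional[float] = None
    background_level: float = 0.0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"epoch {self.epoch_id}: onset must be >= 0")
        if self.duration <= 0:
            raise ValueError(f"epoch {self.epoch_id}: duration must be > 0")
        if self.trial_duration < self.onset + self.duration:
            raise ValueError(
                f"epoch {self.epoch_id}: trial_duration shorter than onset+duration"
            )
        if self.direction is not None and not (0 <= self.direction < 360):
            raise ValueError(f"epoch {self.epoch_id}: direction must lie in [0, 360)")
        if self.diameter is not None and not (50 <= self.diameter <= 800):
            raise ValueError(f"epoch {self.epoch_id}: diameter must lie in [50, 800] μm")
        if self.speed is not None and not (50 <= self.speed <= 3200):
            raise ValueError(f"epoch {self.epoch_id}: speed must lie in [50, 3200] μm/s")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class CellTypeParams:
    """Generative ground-truth parameters of one synthetic cell.

    ``kinetics_tau`` sets the decay of the step response (large = sustained,
    small = transient); ``ds_kappa`` is a von Mises concentration (0 means
    direction-flat); size and speed tuning follow a gamma-shaped gain.
    """

    polarity: Polarity
    spontaneous_rate: float = 5.0
    peak_gain: float = 60.0
    kinetics_tau: float = 0.08
    ds_kappa: float = 0.0
    preferred_direction: float = 0.0
    size_shape: float = 2.0
    size_scale: float = 400.0
    speed_shape: float = 2.0
    speed_scale: float = 800.0
    tf_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.spontaneous_rate < 0 or self.peak_gain < 0:
            raise ValueError("rates and gains must be >= 0")
        if self.ds_kappa < 0:
            raise ValueError("ds_kappa must be >= 0")
        if not (0 <= self.preferred_direction < 360):
            raise ValueError("preferred_direction must lie in [0, 360)")
        for name in ("kinetics_tau", "size_shape", "size_scale", "speed_shape",
                     "speed_scale", "tf_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one trial, tied to a stimulus epoch."""

    cell_id: str
    trial_id: str
    epoch_id: str
    spike_times: np.ndarray
    trial_duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError(f"trial {self.trial_id}: spike times must be sorted")
            if t[0] < 0 or t[-1] >= self.trial_duration:
                raise ValueError(
                    f"trial {self.trial_id}: spike times must lie in [0, trial_duration)"
                )

    def __len__(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class RateFunction:
    """Firing rate on a uniform time grid (the smoothed spike density)."""

    t0: float
    dt: float
    rates: np.ndarray
    bandwidth: float
    n_trials: int = 1

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", r)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if r.ndim != 1 or r.size == 0:
            raise ValueError("rates must be a non-empty 1-D array")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.rates.size)

    @property
    def span(self) -> tuple[float, float]:
        return (self.t0, self.t0 + self.dt * (self.rates.size - 1))

    def integral(self) -> float:
        """Trapezoidal integral of the rate over the grid span (spikes/trial)."""
        return float(np.trapezoid(self.rates, dx=self.dt))


@dataclass(frozen=True)
class TuningCurve:
    """Trial-averaged peak response as a function of one stimulus variable."""

    variable: str  # size | speed | direction | frequency
    x: np.ndarray
    responses: np.ndarray
    n_trials: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "responses", r)
        if x.size != r.size:
            raise ValueError("x and responses must have equal length")
        if x.size and np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("responses must be >= 0")

    @property
    def x_range(self) -> float:
        return float(self.x[-1] - self.x[0])


@dataclass(frozen=True)
class GammaFitResult:
    """Result of a gamma-function fit to a tuning curve.

    ``best_x_fit`` is the argmax of the fitted curve (the interpolated best
    size/speed). ``flags`` may contain ``fit_failed`` or
    ``unbounded_within_range`` when the fitted optimum lies at or beyond the
    largest tested stimulus.
    """

    baseline: float
    amplitude: float
    shape: float
    scale: float
    best_x_fit: float
    rmse: Optional[float]
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.rmse is not None and "fit_failed" not in self.flags


@dataclass
class CellMetrics:
    """Every per-cell scalar the pipeline measures. ``None`` = undefined."""

    cell_id: str
    spontaneous_rate: Optional[float] = None
    latency: Optional[float] = None
    response_duration: Optional[float] = None
    nvsl: Optional[float] = None
    preferred_direction: Optional[float] = None
    best_size: Optional[float] = None
    best_size_fit: Optional[float] = None
    size_tuning_width: Optional[float] = None
    best_speed: Optional[float] = None
    speed_tuning_width: Optional[float] = None
    cutoff_frequency: Optional[float] = None
    polarity: Optional[Polarity] = None
    on_off_index: Optional[float] = None


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the six-group classifier."""

    nvsl_ds: float = 0.2
    duration_sustained: float = 0.4
    small_width_max: float = 500.0
    small_best_size_max: float = 200.0

    def __post_init__(self) -> None:
        if not (0 < self.duration_sustained < 1):
            raise ValueError("duration_sustained must lie in (0, 1)")
        for name in ("nvsl_ds", "small_width_max", "small_best_size_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Gaussian2DFit:
    """Moment-based 2D Gaussian summary of a labelled-cell point cloud."""

    center: np.ndarray          # (x, y) μm
    sd_major: float
    sd_minor: float
    orientation: float          # deg, CCW from +x, of the major axis
    n_points: int
    cov: np.ndarray = field(default=None)  # 2x2 covariance, kept for Mahalanobis use

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.cov is not None:
            object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.sd_major < self.sd_minor:
            raise ValueError("sd_major must be >= sd_minor")
        if self.sd_minor < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 projection-group by class-membership counts."""

    counts: np.ndarray
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")

    @property
    def margins(self) -> tuple[np.ndarray, np.ndarray]:
        return self.counts.sum(axis=1), self.counts.sum(axis=0)
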