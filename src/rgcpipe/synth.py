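"""Synthetic recordings and retinal label maps with known ground truth.

The generative response model is deliberately minimal and separable:

    rate(t) = spontaneous + peak_gain * contrast * K(t) * G_dir * G_size * G_speed

where ``K(t)`` is a polarity kernel (exponential decay with time constant
``kinetics_tau`` triggered at stimulus onset and/or offset for stationary
spots, or during the transit window for moving bars, or a rectified raised
cosine scaled by a first-order low-pass gain for sinusoidal luminance
modulation), ``G_dir`` is a von Mises gain in (direction − preferred),
and ``G_size`` / ``G_speed`` are gamma-shaped gains normalised to a peak
of one over the tested stimulus range. Spikes are drawn from the resulting
inhomogeneous Poisson rate by thinning on the discrete grid.

The default population composition mirrors the published class counts in
each projection group (superior colliculus vs. dLGN); see
``default_population``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    CellTypeParams,
    ClassLabel,
    Polarity,
    Protocol,
    RateFunction,
    SpikeTrain,
    StimulusEpoch,
)

# Stimulus ranges over which size/speed gamma gains are normalised.
SIZE_RANGE = (50.0, 800.0)
SPEED_RANGE = (50.0, 3200.0)

DEFAULT_SIZES = (50.0, 100.0, 200.0, 400.0, 800.0)
DEFAULT_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))
DEFAULT_SPEEDS = (50.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0)
DEFAULT_FREQUENCIES = (1.0, 2.0, 4.0)
DEFAULT_DIRECTION_SPEED = 800.0

# Duration of the moving-bar transit burst: the time the leading and
# trailing edges of a bar take to cross a receptive field at 800 μm/s.
MOTION_TRANSIT_S = 0.5


def _gamma_gain(x: np.ndarray | float, shape: float, scale: float,
                lo: float, hi: float) -> np.ndarray | float:
    """Gamma-shaped gain (x/scale)^(shape-1) e^(-x/scale), peak-1 over [lo, hi]."""
    x = np.asarray(x, dtype=float)
    g = np.power(x / scale, shape - 1.0) * np.exp(-x / scale)
    if shape > 1:
        mode = (shape - 1.0) * scale
        ref = min(max(mode, lo), hi)
    else:
        ref = lo  # monotone decreasing: max over the range sits at the low end
    gmax = (ref / scale) ** (shape - 1.0) * np.exp(-ref / scale)
    return g / gmax


def _von_mises_gain(direction: float, preferred: float, kappa: float) -> float:
    """exp(kappa * (cos Δ − 1)); equals 1 at the preferred direction, flat at κ=0."""
    d = np.deg2rad(direction - preferred)
    return float(np.exp(kappa * (np.cos(d) - 1.0)))


def _lowpass_gain(freq: float, cutoff: float) -> float:
    """First-order low-pass amplitude gain with corner frequency ``cutoff``."""
    return 1.0 / np.sqrt(1.0 + (freq / cutoff) ** 2)


def rate_template(
    params: CellTypeParams,
    epoch: StimulusEpoch,
    t0: float = 0.0,
    dt: float = 0.001,
    n: Optional[int] = None,
) -> RateFunction:
    """Noise-free firing-rate template of a cell for one stimulus epoch.

    The grid starts at ``t0`` (trial clock) with step ``dt`` and spans the
    trial unless ``n`` is given. Rates are in AP/s and never negative; with
    zero stimulus drive the template sits at the spontaneous rate.
    """
    if not isinstance(epoch.protocol, Protocol):
        raise ValueError(f"unknown protocol: {epoch.protocol!r}")
    if dt <= 0:
        raise ValueError("grid step must be > 0")
    if n is None:
        n = int(round((epoch.trial_duration - t0) / dt)) + 1
    t = t0 + dt * np.arange(n)
    if t[0] > epoch.onset or t[-1] < epoch.offset:
        raise ValueError("grid must cover the stimulus epoch")

    gain = float(epoch.contrast)
    if epoch.direction is not None:
        gain *= _von_mises_gain(epoch.direction, params.preferred_direction,
                                params.ds_kappa)
    if epoch.diameter is not None:
        gain *= float(_gamma_gain(epoch.diameter, params.size_shape,
                                  params.size_scale, *SIZE_RANGE))
    if epoch.speed is not None:
        gain *= float(_gamma_gain(epoch.speed, params.speed_shape,
                                  params.speed_scale, *SPEED_RANGE))

    tau = params.kinetics_tau
    rel = t - epoch.onset
    drive = np.zeros_like(t)
    if epoch.protocol in (Protocol.CONTRAST_STEP, Protocol.SIZE_SERIES):
        during = (rel >= 0) & (rel < epoch.duration)
        after = rel >= epoch.duration
        if params.polarity in (Polarity.ON, Polarity.ON_OFF):
            drive[during] += np.exp(-rel[during] / tau)
        if params.polarity in (Polarity.OFF, Polarity.ON_OFF):
            drive[after] += np.exp(-(rel[after] - epoch.duration) / tau)
    elif epoch.protocol in (Protocol.DIRECTION_SERIES, Protocol.SPEED_SERIES):
        # transit of a moving bar: a smooth raised-cosine burst lasting the
        # passage of the leading and trailing edges across the receptive
        # field (several hundred ms at 800 μm/s), for every polarity
        w = epoch.duration  # the epoch is the transit
        m = (rel >= 0) & (rel < w)
        drive[m] = 0.5 * (1.0 - np.cos(2 * np.pi * rel[m] / w))
    elif epoch.protocol is Protocol.TEMPORAL_MODULATION:
        if epoch.frequency is None:
            raise ValueError("temporal_modulation epoch requires a frequency")
        during = (rel >= 0) & (rel < epoch.duration)
        mod = 0.5 * (1.0 - np.cos(2 * np.pi * epoch.frequency * rel[during]))
        drive[during] = _lowpass_gain(epoch.frequency, params.tf_cutoff) * mod

    rates = params.spontaneous_rate + params.peak_gain * gain * drive
    # bandwidth 0 marks an unsmoothed template rather than a kernel estimate
    return RateFunction(float(t[0]), dt, np.clip(rates, 0.0, None),
                        bandwidth=0.0, n_trials=1)


def sample_spikes(rate: RateFunction, seed) -> np.ndarray:
    """Draw one spike train from an inhomogeneous Poisson rate by thinning.

    Candidates come from a homogeneous Poisson process at the grid maximum
    and are kept with probability rate(t)/max; the rate is held piecewise
    constant at the grid resolution and at most one spike is retained per
    grid bin. Identical seeds give identical trains.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t0, t1 = rate.span
    rmax = float(rate.rates.max())
    if rmax <= 0 or t1 <= t0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * (t1 - t0))
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    idx = np.minimum(((cand - t0) / rate.dt).astype(int), rate.rates.size - 1)
    keep = rng.uniform(0, 1, size=n_cand) < rate.rates[idx] / rmax
    spikes = cand[keep]
    if spikes.size:
        bins = ((spikes - t0) / rate.dt).astype(int)
        _, first = np.unique(bins, return_index=True)
        spikes = spikes[first]
    return spikes


# ---------------------------------------------------------------------------
# population-level simulation
# ---------------------------------------------------------------------------

# Class archetypes. Sustained classes use a long step-response time constant
# (>= 0.4 s), transient ones a short one (<= 0.08 s); the small-transient On
# group carries a narrow gamma size gain peaking near 100 μm.
CLASS_PARAMS: dict[ClassLabel, CellTypeParams] = {
    ClassLabel.ON_OFF_DS: CellTypeParams(
        polarity=Polarity.ON_OFF, spontaneous_rate=2.0, peak_gain=150.0,
        kinetics_tau=0.08, ds_kappa=2.0, size_shape=2.0, size_scale=150.0,
        speed_shape=2.0, speed_scale=800.0, tf_cutoff=4.0),
    ClassLabel.OFF_SUSTAINED: CellTypeParams(
        polarity=Polarity.OFF, spontaneous_rate=8.0, peak_gain=150.0,
        kinetics_tau=0.6, size_shape=2.0, size_scale=400.0,
        speed_shape=2.0, speed_scale=600.0, tf_cutoff=3.0),
    ClassLabel.OFF_TRANSIENT: CellTypeParams(
        polarity=Polarity.OFF, spontaneous_rate=6.0, peak_gain=150.0,
        kinetics_tau=0.06, size_shape=2.0, size_scale=400.0,
        speed_shape=2.0, speed_scale=800.0, tf_cutoff=4.0),
    ClassLabel.ON_SUSTAINED: CellTypeParams(
        polarity=Polarity.ON, spontaneous_rate=6.0, peak_gain=150.0,
        kinetics_tau=0.6, size_shape=2.0, size_scale=400.0,
        speed_shape=2.0, speed_scale=600.0, tf_cutoff=3.0),
    ClassLabel.ON_TRANSIENT: CellTypeParams(
        polarity=Polarity.ON, spontaneous_rate=4.0, peak_gain=150.0,
        kinetics_tau=0.06, size_shape=2.0, size_scale=400.0,
        speed_shape=2.0, speed_scale=800.0, tf_cutoff=4.0),
    ClassLabel.ON_SMALL_TRANSIENT: CellTypeParams(
        polarity=Polarity.ON, spontaneous_rate=2.0, peak_gain=150.0,
        kinetics_tau=0.06, size_shape=3.0, size_scale=50.0,
        speed_shape=2.0, speed_scale=400.0, tf_cutoff=3.0),
}

# Projection-specific overrides: dLGN-projecting transient Off cells fire
# markedly more in darkness than SC-projecting ones (10.7 vs 1.8 AP/s).
GROUP_OVERRIDES: dict[tuple[str, ClassLabel], dict] = {
    ("dLGN", ClassLabel.OFF_TRANSIENT): {"spontaneous_rate": 10.7},
    ("SC", ClassLabel.OFF_TRANSIENT): {"spontaneous_rate": 1.8},
}


@dataclass(frozen=True)
class GroupSpec:
    """Cell count and class composition of one projection group."""

    n_cells: int
    fractions: dict

    def __post_init__(self) -> None:
        total = float(sum(self.fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"class fractions must sum to 1 (got {total:.6f})"
            )

    def counts(self) -> dict[ClassLabel, int]:
        """Largest-remainder apportionment of n_cells across classes."""
        items = list(self.fractions.items())
        raw = [self.n_cells * f for _, f in items]
        base = [int(np.floor(r)) for r in raw]
        short = self.n_cells - sum(base)
        order = np.argsort([b - r for b, r in zip(base, raw)])
        for i in order[:short]:
            base[i] += 1
        return {lab: c for (lab, _), c in zip(items, base) if c > 0}


def _counts_to_spec(counts: dict[ClassLabel, int]) -> GroupSpec:
    n = sum(counts.values())
    return GroupSpec(n, {k: v / n for k, v in counts.items()})


def default_population() -> dict[str, GroupSpec]:
    """Default composition: the classified cells of each projection group.

    Counts follow the published composition — dLGN: 10 On-Off DS, 11
    sustained / 8 transient Off, 45 On (1 of them small-transient); SC: 20
    On-Off DS, 8 sustained / 15 transient Off, 36 On (8 small-transient).
    """
    dlgn = {
        ClassLabel.ON_OFF_DS: 10,
        ClassLabel.OFF_SUSTAINED: 11,
        ClassLabel.OFF_TRANSIENT: 8,
        ClassLabel.ON_SUSTAINED: 30,
        ClassLabel.ON_TRANSIENT: 14,
        ClassLabel.ON_SMALL_TRANSIENT: 1,
    }
    sc = {
        ClassLabel.ON_OFF_DS: 20,
        ClassLabel.OFF_SUSTAINED: 8,
        ClassLabel.OFF_TRANSIENT: 15,
        ClassLabel.ON_SUSTAINED: 12,
        ClassLabel.ON_TRANSIENT: 16,
        ClassLabel.ON_SMALL_TRANSIENT: 8,
    }
    return {"dLGN": _counts_to_spec(dlgn), "SC": _counts_to_spec(sc)}


def default_protocols(params: CellTypeParams) -> list[tuple[StimulusEpoch, ...]]:
    """The full stimulus battery for one cell, as one epoch list.

    Moving stimuli use the cell's best size and, for the speed series, its
    preferred direction (mirroring the recording procedure).
    """
    best_size = min(max((params.size_shape - 1.0) * params.size_scale,
                        SIZE_RANGE[0]), SIZE_RANGE[1])
    epochs: list[StimulusEpoch] = []

    def add(**kw):
        key = "_".join(
            f"{k}{kw[k]}" for k in
            ("protocol", "diameter", "direction", "speed", "frequency")
            if kw.get(k) is not None
        )
        kw["epoch_id"] = key.replace("Protocol.", "").replace(".0", "")
        epochs.append(StimulusEpoch(**kw))

    # step probe at the cell's own best size, as in the recording procedure
    add(protocol=Protocol.CONTRAST_STEP, onset=0.5, duration=1.0,
        trial_duration=2.5, diameter=best_size)
    for d in DEFAULT_SIZES:
        add(protocol=Protocol.SIZE_SERIES, onset=0.5, duration=0.5,
            trial_duration=2.0, diameter=d)
    for ang in DEFAULT_DIRECTIONS:
        add(protocol=Protocol.DIRECTION_SERIES, onset=0.2,
            duration=MOTION_TRANSIT_S, trial_duration=1.0,
            diameter=best_size, direction=ang, speed=DEFAULT_DIRECTION_SPEED)
    pref = float(params.preferred_direction % 360)
    for v in DEFAULT_SPEEDS:
        add(protocol=Protocol.SPEED_SERIES, onset=0.2,
            duration=MOTION_TRANSIT_S, trial_duration=1.0,
            diameter=best_size, direction=pref, speed=v)
    for f in DEFAULT_FREQUENCIES:
        add(protocol=Protocol.TEMPORAL_MODULATION, onset=0.2, duration=2.0,
            trial_duration=2.5, diameter=800.0, frequency=f)
    return epochs


@dataclass
class SimulatedDataset:
    """Spike/epoch/ground-truth tables of one simulated experiment."""

    spikes: pd.DataFrame        # cell_id, trial_id, epoch_id, spike_time_s
    epochs: pd.DataFrame        # one row per (cell_id, epoch_id)
    ground_truth: pd.DataFrame  # one row per cell
    seed: int

    def epoch_objects(self, cell_id: str) -> dict[str, StimulusEpoch]:
        sub = self.epochs[self.epochs.cell_id == cell_id]
        out = {}
        for row in sub.itertuples(index=False):
            out[row.epoch_id] = StimulusEpoch(
                epoch_id=row.epoch_id,
                protocol=Protocol(row.protocol),
                onset=row.onset_s,
                duration=row.duration_s,
                trial_duration=row.trial_duration_s,
                diameter=None if pd.isna(row.diameter_um) else row.diameter_um,
                contrast=row.contrast,
                direction=None if pd.isna(row.direction_deg) else row.direction_deg,
                speed=None if pd.isna(row.speed_um_s) else row.speed_um_s,
                frequency=None if pd.isna(row.frequency_hz) else row.frequency_hz,
            )
        return out


def simulate_cell(
    cell_id: str,
    params: CellTypeParams,
    epochs: list[StimulusEpoch],
    rng: np.random.Generator,
    n_trials: int = 5,
    dt: float = 0.001,
) -> list[SpikeTrain]:
    trains = []
    for ep in epochs:
        template = rate_template(params, ep, t0=0.0, dt=dt)
        for k in range(n_trials):
            t = sample_spikes(template, rng)
            trains.append(SpikeTrain(cell_id, f"{ep.epoch_id}__t{k}", ep.epoch_id,
                                     t, ep.trial_duration))
    return trains


def simulate_experiment(
    population: Optional[dict[str, GroupSpec]] = None,
    seed: int = 0,
    n_trials: int = 5,
    dt: float = 0.001,
    jitter: float = 0.1,
) -> SimulatedDataset:
    """Simulate the full recording campaign with known ground truth.

    Every cell receives the complete stimulus battery (contrast step, five
    sizes, eight directions at 800 μm/s, seven speeds, 1/2/4 Hz luminance
    modulation) with ``n_trials`` repeats. Per-cell RNG streams are keyed by
    (master seed, cell index) so the dataset is reproducible regardless of
    generation order. ``jitter`` is the relative SD of log-normal cell-to-cell
    variation applied to gains and time constants.
    """
    population = default_population() if population is None else population
    spike_rows, epoch_rows, truth_rows = [], [], []
    cell_index = 0
    for group in sorted(population):
        spec = population[group]
        for label, count in spec.counts().items():
            base = CLASS_PARAMS[label]
            over = GROUP_OVERRIDES.get((group, label), {})
            for _ in range(count):
                rng = np.random.default_rng([seed % (2**31), cell_index])
                cell_id = f"{group.lower()}_{cell_index:04d}"
                lognorm = lambda v: float(v * np.exp(rng.normal(0, jitter)))
                params = replace(
                    base,
                    spontaneous_rate=lognorm(over.get("spontaneous_rate",
                                                      base.spontaneous_rate)),
                    peak_gain=lognorm(base.peak_gain),
                    kinetics_tau=lognorm(base.kinetics_tau),
                    preferred_direction=float(rng.uniform(0, 360)),
                )
                epochs = default_protocols(params)
                trains = simulate_cell(cell_id, params, epochs, rng,
                                       n_trials=n_trials, dt=dt)
                for ep in epochs:
                    epoch_rows.append(dict(
                        cell_id=cell_id, epoch_id=ep.epoch_id,
                        protocol=ep.protocol.value, onset_s=ep.onset,
                        duration_s=ep.duration, trial_duration_s=ep.trial_duration,
                        diameter_um=ep.diameter, contrast=ep.contrast,
                        direction_deg=ep.direction, speed_um_s=ep.speed,
                        frequency_hz=ep.frequency,
                    ))
                for tr in trains:
                    if len(tr):
                        spike_rows.append((cell_id, tr.trial_id, tr.epoch_id,
                                           tr.spike_times))
                truth_rows.append(dict(
                    cell_id=cell_id, group=group, class_label=label.value,
                    polarity=params.polarity.value,
                    spontaneous_rate=params.spontaneous_rate,
                    peak_gain=params.peak_gain,
                    kinetics_tau=params.kinetics_tau,
                    ds_kappa=params.ds_kappa,
                    preferred_direction=params.preferred_direction,
                    size_shape=params.size_shape, size_scale=params.size_scale,
                    speed_shape=params.speed_shape,
                    speed_scale=params.speed_scale,
                    tf_cutoff=params.tf_cutoff,
                ))
                cell_index += 1
    if spike_rows:
        lens = [len(t) for _, _, _, t in spike_rows]
        spikes = pd.DataFrame({
            "cell_id": np.repeat([c for c, _, _, _ in spike_rows], lens),
            "trial_id": np.repeat([t for _, t, _, _ in spike_rows], lens),
            "epoch_id": np.repeat([e for _, _, e, _ in spike_rows], lens),
            "spike_time_s": np.concatenate([t for _, _, _, t in spike_rows]),
        })
    else:
        spikes = pd.DataFrame(columns=["cell_id", "trial_id", "epoch_id",
                                       "spike_time_s"])
    return SimulatedDataset(
        spikes=spikes,
        epochs=pd.DataFrame(epoch_rows),
        ground_truth=pd.DataFrame(truth_rows),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# retinal label maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorophore channel: cluster size, centre and spread."""

    n_cells: int
    center: tuple[float, float]
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("cluster_sd must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass(frozen=True)
class RetinaMapParams:
    """Generative description of one retrogradely labelled retina.

    ``colabel`` maps (reference_channel, test_channel) to the probability
    that a reference-labelled cell also carries the test label.
    """

    channels: dict
    colabel: dict = field(default_factory=dict)
    retina_radius: float = 2500.0

    def __post_init__(self) -> None:
        for pair, p in self.colabel.items():
            if not (0 <= p <= 1):
                raise ValueError(f"colabel_prob for {pair} must lie in [0, 1]")
        if self.retina_radius <= 0:
            raise ValueError("retina_radius must be > 0")


@dataclass
class LabeledCellMap:
    """2D retinal point cloud with per-channel boolean labels.

    Coordinates are μm relative to the optic nerve head at the origin.
    """

    retina_id: str
    cells: pd.DataFrame  # x_um, y_um, label_<channel> boolean columns
    optic_nerve_head: tuple[float, float] = (0.0, 0.0)

    @property
    def channels(self) -> list[str]:
        return [c[len("label_"):] for c in self.cells.columns
                if c.startswith("label_")]

    def points(self, channel: str) -> np.ndarray:
        sel = self.cells[self.cells[f"label_{channel}"]]
        return sel[["x_um", "y_um"]].to_numpy(dtype=float)


def simulate_retina_map(
    params: RetinaMapParams, seed: int, retina_id: str = "synthetic"
) -> LabeledCellMap:
    """Draw clustered labelled-cell positions with known co-label rates.

    Each channel's cells are isotropic Gaussian around its cluster centre,
    rejection-sampled to stay within the retina radius; co-labels are
    Bernoulli draws on the reference channel's cells.
    """
    rng = np.random.default_rng(seed)
    names = sorted(params.channels)
    rows = []
    for name in names:
        spec = params.channels[name]
        pts = np.empty((0, 2))
        while pts.shape[0] < spec.n_cells:
            draw = rng.normal(spec.center, spec.sd,
                              size=(max(spec.n_cells * 2, 16), 2))
            draw = draw[np.hypot(draw[:, 0], draw[:, 1]) <= params.retina_radius]
            pts = np.vstack([pts, draw])
        pts = pts[: spec.n_cells]
        for x, y in pts:
            labels = {f"label_{n}": (n == name) for n in names}
            rows.append(dict(x_um=float(x), y_um=float(y), **labels))
    cells = pd.DataFrame(
        rows, columns=["x_um", "y_um"] + [f"label_{n}" for n in names]
    )
    if cells.empty:
        cells = pd.DataFrame(
            columns=["x_um", "y_um"] + [f"label_{n}" for n in names]
        )
    for (ref, test), p in params.colabel.items():
        mask = cells[f"label_{ref}"].to_numpy(dtype=bool)
        hits = rng.uniform(0, 1, size=int(mask.sum())) < p
        col = cells[f"label_{test}"].to_numpy(dtype=bool)
        col[np.flatnonzero(mask)] |= hits
        cells[f"label_{test}"] = col
    return LabeledCellMap(retina_id=retina_id, cells=cells)
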