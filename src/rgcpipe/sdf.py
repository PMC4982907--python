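"""Spike-train processing: alignment, spike density functions, latencies,
peak responses and spontaneous rates.

The spike density function (SDF) is an edge-corrected Gaussian kernel
estimate averaged across trials: each spike contributes a Gaussian of SD
``bandwidth`` renormalised so that its mass *within the analysis span* is
exactly one, which keeps the integral of the SDF equal to the mean spike
count per trial regardless of how close spikes sit to the span edges.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .types import RateFunction, SpikeTrain, StimulusEpoch


def align_to_onset(train: SpikeTrain, epoch: StimulusEpoch) -> np.ndarray:
    """Express spike times relative to the stimulus onset of their epoch."""
    if train.epoch_id != epoch.epoch_id:
        raise ValueError(
            f"trial {train.trial_id} references epoch {train.epoch_id}, "
            f"not {epoch.epoch_id}"
        )
    return train.spike_times - epoch.onset


def compute_sdf(
    aligned_trains: Sequence[np.ndarray] | Sequence[Iterable[float]],
    bandwidth: float,
    dt: float,
    span: tuple[float, float],
) -> RateFunction:
    """Trial-averaged, edge-corrected Gaussian-kernel rate estimate.

    Parameters
    ----------
    aligned_trains
        One array of spike times per trial, on a common clock (typically
        onset-aligned). Empty trials are allowed and count toward the
        trial average.
    bandwidth
        Gaussian kernel SD in seconds.
    dt, span
        Grid step and (t_start, t_end) of the uniform evaluation grid.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if len(aligned_trains) == 0:
        raise ValueError("at least one trial is required")
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span must be non-degenerate")
    n = int(round((t1 - t0) / dt)) + 1
    grid = t0 + dt * np.arange(n)

    spikes = np.concatenate([np.asarray(tr, dtype=float) for tr in aligned_trains]) \
        if any(len(np.atleast_1d(tr)) for tr in aligned_trains) else np.empty(0)
    # only spikes inside the span enter the estimate; each one contributes
    # unit mass within it, so the integral equals the mean in-span count
    spikes = spikes[(spikes >= t0) & (spikes <= t1)]
    n_trials = len(aligned_trains)
    if spikes.size == 0:
        return RateFunction(t0, dt, np.zeros(n), bandwidth, n_trials)

    # Mass of each spike's kernel inside the span (edge correction).
    mass = ndtr((t1 - spikes) / bandwidth) - ndtr((t0 - spikes) / bandwidth)
    z = (grid[:, None] - spikes[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z) / (bandwidth * np.sqrt(2 * np.pi))
    rates = (dens / mass[None, :]).sum(axis=1) / n_trials
    return RateFunction(t0, dt, np.clip(rates, 0.0, None), bandwidth, n_trials)


def detect_latency(
    sdf: RateFunction,
    frac: float = 0.1,
    min_dur: float = 0.050,
    onset: float = 0.0,
    baseline: float = 0.0,
) -> Optional[float]:
    """Earliest post-onset time at which the SDF stays above ``frac`` of the
    response-window peak for at least ``min_dur``; ``None`` if never.

    The threshold is referenced to the peak *after onset* (the stimulus
    response window), not the global trace maximum. When a spontaneous
    ``baseline`` rate is supplied, both peak and threshold are measured
    above it (threshold = baseline + frac x (peak - baseline)), so a
    tonically active cell does not trigger on its own resting discharge;
    with the default baseline of 0 the criterion is the plain
    frac-of-peak rule.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must lie in (0, 1)")
    if min_dur <= 0:
        raise ValueError("min_dur must be > 0")
    t = sdf.times
    post = t >= onset
    if not post.any():
        raise ValueError("SDF span contains no post-onset samples")
    peak = float(sdf.rates[post].max())
    if peak <= baseline or peak <= 0:
        return None
    thr = baseline + frac * (peak - baseline)
    above = (sdf.rates > thr) & post
    need = int(np.ceil(min_dur / sdf.dt))
    # scan runs of consecutive supra-threshold samples
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        if (idx[e] - idx[s]) >= need:
            return float(t[idx[s]])
    return None


def spontaneous_rate(
    trains: Sequence[SpikeTrain] | Sequence[np.ndarray],
    baseline_window: tuple[float, float],
) -> float:
    """Mean firing rate in a pre-stimulus (or blank) window, AP/s.

    Total baseline spikes divided by (number of trials x window length);
    accepts SpikeTrain objects or plain arrays of (aligned) times.
    """
    w0, w1 = baseline_window
    if w1 <= w0:
        raise ValueError("baseline window must have positive length")
    total = 0
    for tr in trains:
        t = tr.spike_times if isinstance(tr, SpikeTrain) else np.asarray(tr, float)
        total += int(np.count_nonzero((t >= w0) & (t < w1)))
    return total / (len(trains) * (w1 - w0))


def peak_response(
    sdf: RateFunction, window: tuple[float, float]
) -> tuple[float, float]:
    """Maximum SDF rate within ``window`` and the time it occurs.

    The rate is baseline-unsubtracted; ties go to the earliest time.
    """
    lo, hi = sdf.span
    w0, w1 = window
    if w0 < lo - 1e-9 or w1 > hi + 1e-9:
        raise ValueError("window must lie within the SDF span")
    t = sdf.times
    sel = (t >= w0 - 1e-12) & (t <= w1 + 1e-12)
    if not sel.any():
        raise ValueError("window contains no grid points")
    r = sdf.rates[sel]
    i = int(np.argmax(r))  # argmax returns the first (earliest) maximum
    return float(r[i]), float(t[sel][i])
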