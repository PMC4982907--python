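"""Per-cell functional metrics: response duration, direction selectivity
(normalised vector sum), tuning curves and widths, gamma fits, cutoff
frequency and response polarity — plus the orchestrator that computes the
full metrics row for a cell from its spike and epoch tables.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import sdf as sdfmod
from .config import RunConfig
from .types import (
    CellMetrics,
    GammaFitResult,
    Polarity,
    Protocol,
    RateFunction,
    SpikeTrain,
    StimulusEpoch,
    TuningCurve,
)


def response_duration(
    sdf: RateFunction, latency: Optional[float], window: float = 0.5
) -> Optional[float]:
    """Normalised response persistence in [0, 1].

    Integral of the SDF over ``window`` seconds starting at the response
    latency, divided by (peak within that window x window length); 1 means
    the rate held at its peak throughout, small values mean a transient
    response. ``None`` when no latency was detected.
    """
    if latency is None:
        return None
    lo, hi = sdf.span
    if latency < lo - 1e-9 or latency + window > hi + 1e-9:
        raise ValueError("SDF span does not cover the duration window")
    t = sdf.times
    sel = (t >= latency - 1e-12) & (t <= latency + window + 1e-12)
    r = sdf.rates[sel]
    peak = float(r.max())
    if peak <= 0:
        return None
    integral = float(np.trapezoid(r, dx=sdf.dt))
    return min(integral / (peak * window), 1.0)


def compute_nvsl(
    directions: Sequence[float], responses: Sequence[float]
) -> tuple[Optional[float], Optional[float]]:
    """Normalised vector sum length and preferred direction.

    nvsl = |Σ r_j e^{iθ_j}| / Σ r_j, in [0, 1]; the argument of the vector
    sum (in [0, 360)) is the preferred direction. Undefined (None, None)
    when every response is zero.
    """
    th = np.deg2rad(np.asarray(directions, dtype=float))
    r = np.asarray(responses, dtype=float)
    if th.size != r.size or th.size < 2:
        raise ValueError("need responses for at least two directions")
    if np.any(r < 0):
        raise ValueError("responses must be >= 0")
    total = float(r.sum())
    if total == 0:
        return None, None
    vec = complex(np.sum(r * np.exp(1j * th)))
    nvsl = abs(vec) / total
    pref = math.degrees(math.atan2(vec.imag, vec.real)) % 360.0
    return float(nvsl), float(pref)


def build_tuning_curve(
    x: Sequence[float],
    responses: Sequence[float],
    variable: str,
    n_trials: Optional[Sequence[int]] = None,
) -> TuningCurve:
    """Average duplicate-x responses and sort by x into a TuningCurve."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(responses, dtype=float)
    df = pd.DataFrame({"x": x, "r": r})
    if n_trials is not None:
        df["n"] = np.asarray(n_trials)
        agg = df.groupby("x", sort=True).agg(r=("r", "mean"), n=("n", "sum"))
        nt = agg["n"].to_numpy()
    else:
        agg = df.groupby("x", sort=True).agg(r=("r", "mean"))
        nt = None
    if len(agg) < 2:
        raise ValueError("need at least two distinct x values")
    return TuningCurve(variable, agg.index.to_numpy(), agg["r"].to_numpy(), nt)


def best_x(curve: TuningCurve) -> float:
    """Measured stimulus value with the largest response; ties → smaller x."""
    if curve.x.size == 0:
        raise ValueError("empty tuning curve")
    return float(curve.x[int(np.argmax(curve.responses))])


def tuning_width(curve: TuningCurve) -> Optional[float]:
    """Normalised area (trapezoidal integral / peak) of the curve.

    Has the units of x; equals the x-range for a flat curve and shrinks as
    the curve narrows. Undefined (None) for an all-zero curve.
    """
    peak = float(curve.responses.max())
    if peak <= 0:
        return None
    return float(np.trapezoid(curve.responses, curve.x) / peak)


def _gamma_model(x: np.ndarray, b: float, a: float, k: float, xstar: float
                 ) -> np.ndarray:
    """b + a * (x/x*)^(k-1) exp(-(x - x*) (k-1)/x*): peak-1 bump at x*.

    Evaluated in log space; the exponent (k-1)(ln(x/x*) + 1 - x/x*) is
    always <= 0, so the bump term never overflows.
    """
    u = x / xstar
    return b + a * np.exp((k - 1.0) * (np.log(u) + 1.0 - u))


def _gamma_jac(x: np.ndarray, b: float, a: float, k: float, xstar: float
               ) -> np.ndarray:
    u = x / xstar
    g = np.log(u) + 1.0 - u
    e = np.exp((k - 1.0) * g)
    return np.column_stack([
        np.ones_like(x),
        e,
        a * e * g,
        a * e * (k - 1.0) * (u - 1.0) / xstar,
    ])


def fit_gamma(curve: TuningCurve, n_starts: int = 4) -> GammaFitResult:
    """Least-squares gamma-function fit of a size or speed tuning curve.

    The model is R(x) = baseline + amplitude · (x/scale)^(shape−1) e^(−x/scale),
    normalised so ``amplitude`` is the fitted peak above baseline and the
    fitted optimum ``best_x_fit`` = (shape−1)·scale is a free parameter
    bounded to [min(x)/2, 2·max(x)]. Multi-start; a fit that never converges
    is returned flagged with rmse None, and an optimum at or beyond the
    largest tested x is flagged ``unbounded_within_range``.
    """
    x, y = curve.x, curve.responses
    if x.size < 4:
        raise ValueError("gamma fit requires at least 4 points")
    ymax, ymin = float(y.max()), float(y.min())
    span = max(ymax - ymin, 1e-9)
    lo = np.array([0.0, 0.0, 1.0 + 1e-6, x[0] / 2.0])
    hi = np.array([max(ymax, 1e-9), 2.0 * max(ymax, 1e-9), 60.0, 2.0 * x[-1]])

    best = None
    xstar_starts = np.geomspace(max(x[0], x[0] / 2 + 1e-9), 2.0 * x[-1], n_starts)
    for xstar0 in xstar_starts:
        for k0 in (2.0, 4.0):
            p0 = np.clip(np.array([ymin, span, k0, xstar0]), lo, hi)
            try:
                res = least_squares(
                    lambda p: _gamma_model(x, *p) - y, p0,
                    jac=lambda p: _gamma_jac(x, *p),
                    bounds=(lo, hi), method="trf", max_nfev=500,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return GammaFitResult(float("nan"), float("nan"), float("nan"),
                              float("nan"), float("nan"), None, ("fit_failed",))
    b, a, k, xstar = (float(v) for v in best.x)
    rmse = float(np.sqrt(np.mean((_gamma_model(x, b, a, k, xstar) - y) ** 2)))
    flags = ()
    if xstar >= x[-1]:
        flags = ("unbounded_within_range",)
    return GammaFitResult(baseline=b, amplitude=a, shape=k,
                          scale=xstar / (k - 1.0), best_x_fit=xstar,
                          rmse=rmse, flags=flags)


def cutoff_frequency(curve: TuningCurve) -> Optional[float]:
    """Corner frequency: where the response falls to half its maximum.

    The crossing is located above the argmax by linear interpolation in
    log2(frequency) between adjacent tested frequencies; ``None`` if the
    response never falls to half max (or the curve is all zero).
    """
    f, r = curve.x, curve.responses
    m = float(r.max())
    if m <= 0:
        return None
    half = m / 2.0
    i0 = int(np.argmax(r))
    for i in range(i0, r.size - 1):
        if r[i] >= half >= r[i + 1]:
            if r[i] == r[i + 1]:
                return float(f[i + 1])
            frac = (r[i] - half) / (r[i] - r[i + 1])
            lf = np.log2(f[i]) + frac * (np.log2(f[i + 1]) - np.log2(f[i]))
            return float(2.0 ** lf)
    return None


def polarity(
    on_peak: float, off_peak: float, threshold: float = 0.5
) -> tuple[Optional[Polarity], Optional[float]]:
    """Polarity label and On-Off index from baseline-subtracted step peaks.

    index = (on − off)/(on + off) ∈ [−1, 1]; ON when index ≥ +threshold,
    OFF when index ≤ −threshold, otherwise ON_OFF. Both peaks zero means
    the cell did not respond: (None, None).
    """
    if on_peak < 0 or off_peak < 0:
        raise ValueError("peaks must be >= 0 (baseline-subtracted, clipped)")
    total = on_peak + off_peak
    if total == 0:
        return None, None
    idx = (on_peak - off_peak) / total
    if idx >= threshold:
        return Polarity.ON, idx
    if idx <= -threshold:
        return Polarity.OFF, idx
    return Polarity.ON_OFF, idx


# ---------------------------------------------------------------------------
# per-cell orchestration
# ---------------------------------------------------------------------------


def _condition_sdf(
    trains: Sequence[SpikeTrain],
    epoch: StimulusEpoch,
    cfg: RunConfig,
    pre: float,
    post: float,
) -> RateFunction:
    aligned = [sdfmod.align_to_onset(tr, epoch) for tr in trains]
    span = (-pre, epoch.duration + post)
    return sdfmod.compute_sdf(aligned, cfg.sdf_bandwidth, cfg.sdf_dt, span)


def compute_cell_metrics(
    spikes: pd.DataFrame,
    epochs: dict[str, StimulusEpoch],
    cell_id: str,
    cfg: RunConfig,
    trial_index: Optional[pd.DataFrame] = None,
) -> CellMetrics:
    """Compute the full CellMetrics row for one cell.

    ``spikes`` holds (cell_id, trial_id, epoch_id, spike_time_s) rows;
    ``epochs`` maps epoch_id to its StimulusEpoch. Trials with no spikes are
    recovered from ``trial_index`` (cell_id, trial_id, epoch_id) when given,
    otherwise the nominal trial count ``cfg.n_trials`` is assumed per epoch.
    """
    m = CellMetrics(cell_id=cell_id)
    sub = spikes[spikes.cell_id == cell_id]

    def trains_for(epoch_id: str) -> list[SpikeTrain]:
        ep = epochs[epoch_id]
        grp = sub[sub.epoch_id == epoch_id]
        by_trial = {
            tid: np.sort(g.spike_time_s.to_numpy(dtype=float))
            for tid, g in grp.groupby("trial_id", sort=True)
        }
        if trial_index is not None:
            tids = trial_index[
                (trial_index.cell_id == cell_id)
                & (trial_index.epoch_id == epoch_id)
            ].trial_id.tolist()
        else:
            tids = sorted(by_trial)
            # pad silent trials up to the nominal count
            k = 0
            while len(tids) < cfg.n_trials:
                tids.append(f"__silent{k}")
                k += 1
        return [
            SpikeTrain(cell_id, tid, epoch_id,
                       by_trial.get(tid, np.empty(0)), ep.trial_duration)
            for tid in sorted(tids)
        ]

    by_protocol: dict[Protocol, list[str]] = {}
    for eid, ep in epochs.items():
        by_protocol.setdefault(ep.protocol, []).append(eid)

    # --- contrast step: spontaneous rate, latency, polarity, duration ----
    step_ids = by_protocol.get(Protocol.CONTRAST_STEP, [])
    if step_ids:
        eid = step_ids[0]
        ep = epochs[eid]
        trains = trains_for(eid)
        pre = min(ep.onset, 0.5)
        post = ep.trial_duration - ep.offset
        rate = _condition_sdf(trains, ep, cfg, pre=pre, post=post)
        aligned = [sdfmod.align_to_onset(tr, ep) for tr in trains]
        m.spontaneous_rate = sdfmod.spontaneous_rate(aligned, (-pre, 0.0))
        base = m.spontaneous_rate
        # keep the smoothed offset response from leaking into the on window
        guard = 3.0 * cfg.sdf_bandwidth
        on_peak, _ = sdfmod.peak_response(rate, (0.0, max(ep.duration - guard,
                                                          ep.duration / 2)))
        off_hi = min(ep.duration + cfg.duration_window, rate.span[1])
        off_peak, _ = sdfmod.peak_response(rate, (ep.duration, off_hi))
        m.polarity, m.on_off_index = polarity(max(on_peak - base, 0.0),
                                              max(off_peak - base, 0.0))
        # the latency search starts at the luminance transition that drives
        # the cell: light onset for On / On-Off cells, offset for Off cells
        search_from = ep.duration if m.polarity is Polarity.OFF else 0.0
        m.latency = sdfmod.detect_latency(rate, cfg.latency_frac,
                                          cfg.latency_min_dur,
                                          onset=search_from, baseline=base)
        if m.latency is not None and \
                m.latency + cfg.duration_window <= rate.span[1] + 1e-9:
            m.response_duration = response_duration(rate, m.latency,
                                                    cfg.duration_window)

    # --- size series ------------------------------------------------------
    size_ids = by_protocol.get(Protocol.SIZE_SERIES, [])
    if len(size_ids) >= 2:
        xs, peaks = [], []
        for eid in size_ids:
            ep = epochs[eid]
            rate = _condition_sdf(trains_for(eid), ep, cfg, pre=0.2,
                                  post=ep.trial_duration - ep.offset)
            pk, _ = sdfmod.peak_response(rate, (0.0, rate.span[1]))
            xs.append(ep.diameter)
            peaks.append(pk)
        curve = build_tuning_curve(xs, peaks, "size")
        m.best_size = best_x(curve)
        m.size_tuning_width = tuning_width(curve)
        if curve.x.size >= 4:
            fit = fit_gamma(curve)
            m.best_size_fit = fit.best_x_fit if fit.ok else m.best_size

    # --- direction series -------------------------------------------------
    dir_ids = by_protocol.get(Protocol.DIRECTION_SERIES, [])
    if len(dir_ids) >= 2:
        angles, resp = [], []
        for eid in dir_ids:
            ep = epochs[eid]
            trains = trains_for(eid)
            if cfg.direction_mode == "count":
                # mean firing rate during the bar transit
                counts = [
                    int(np.count_nonzero(
                        (a >= 0) & (a < ep.duration)))
                    for a in (sdfmod.align_to_onset(tr, ep) for tr in trains)
                ]
                r = float(np.mean(counts)) / ep.duration
            else:
                rate = _condition_sdf(trains, ep, cfg, pre=0.1,
                                      post=ep.trial_duration - ep.offset)
                r, _ = sdfmod.peak_response(rate, (0.0, rate.span[1]))
            angles.append(ep.direction)
            resp.append(r)
        m.nvsl, m.preferred_direction = compute_nvsl(angles, resp)

    # --- speed series -----------------------------------------------------
    speed_ids = by_protocol.get(Protocol.SPEED_SERIES, [])
    if len(speed_ids) >= 2:
        xs, peaks = [], []
        for eid in speed_ids:
            ep = epochs[eid]
            rate = _condition_sdf(trains_for(eid), ep, cfg, pre=0.1,
                                  post=ep.trial_duration - ep.offset)
            pk, _ = sdfmod.peak_response(rate, (0.0, rate.span[1]))
            xs.append(ep.speed)
            peaks.append(pk)
        curve = build_tuning_curve(xs, peaks, "speed")
        m.best_speed = best_x(curve)
        m.speed_tuning_width = tuning_width(curve)

    # --- temporal modulation ---------------------------------------------
    freq_ids = by_protocol.get(Protocol.TEMPORAL_MODULATION, [])
    if len(freq_ids) >= 2:
        xs, peaks = [], []
        for eid in freq_ids:
            ep = epochs[eid]
            rate = _condition_sdf(trains_for(eid), ep, cfg, pre=0.1, post=0.1)
            pk, _ = sdfmod.peak_response(rate, (0.0, ep.duration))
            xs.append(ep.frequency)
            peaks.append(pk)
        curve = build_tuning_curve(xs, peaks, "frequency")
        m.cutoff_frequency = cutoff_frequency(curve)

    return m


def compute_metrics_table(dataset, cfg: RunConfig) -> pd.DataFrame:
    """One CellMetrics row per cell of a SimulatedDataset (or equivalent)."""
    rows = []
    by_cell = dict(tuple(dataset.spikes.groupby("cell_id", sort=False)))
    empty = dataset.spikes.iloc[0:0]
    for cell_id in dataset.ground_truth.cell_id:
        epochs = dataset.epoch_objects(cell_id)
        m = compute_cell_metrics(by_cell.get(cell_id, empty), epochs,
                                 cell_id, cfg)
        d = m.__dict__.copy()
        d["polarity"] = None if m.polarity is None else m.polarity.value
        rows.append(d)
    df = pd.DataFrame(rows)
    return df
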