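"""Tuning-metric tests: response duration, NVSL, tuning curves/widths,
gamma fits, cutoff frequency and polarity, each against analytic values or
independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rgcpipe import synth, tuning
from rgcpipe.types import (
    CellTypeParams,
    Polarity,
    Protocol,
    RateFunction,
    StimulusEpoch,
    TuningCurve,
)

EIGHT_DIRS = np.arange(0, 360, 45.0)


def make_sdf(rates, dt=0.001):
    return RateFunction(0.0, dt, np.asarray(rates, float), bandwidth=0.025)


class TestResponseDuration:
    def test_constant_at_peak_is_one(self):
        s = make_sdf(np.full(1001, 30.0))
        assert tuning.response_duration(s, 0.0) == pytest.approx(1.0, abs=1e-6)

    def test_peak_for_50ms_then_zero_is_point_one(self):
        rates = np.zeros(1001)
        rates[:51] = 40.0
        s = make_sdf(rates)
        assert tuning.response_duration(s, 0.0) == pytest.approx(0.1, abs=0.005)

    def test_linear_decay_is_half(self):
        rates = np.linspace(80.0, 0.0, 501)
        s = make_sdf(np.concatenate([rates, np.zeros(500)]))
        assert tuning.response_duration(s, 0.0) == pytest.approx(0.5, abs=0.005)

    def test_no_latency_propagates_none(self):
        assert tuning.response_duration(make_sdf(np.ones(1000)), None) is None

    def test_sustained_template_exceeds_transient_for_any_bandwidth(self):
        # noise-free templates: τ=0.6 s vs τ=0.06 s
        ep = StimulusEpoch("e", Protocol.CONTRAST_STEP, onset=0.0,
                           duration=1.0, trial_duration=1.5)
        for tau_s, tau_t in [(0.4, 0.08), (0.6, 0.06), (1.0, 0.05)]:
            ds = []
            for tau in (tau_s, tau_t):
                p = CellTypeParams(polarity=Polarity.ON, spontaneous_rate=2.0,
                                   kinetics_tau=tau)
                r = synth.rate_template(p, ep)
                ds.append(tuning.response_duration(r, 0.0))
            assert ds[0] > ds[1]


class TestNvsl:
    def test_symmetric_responses_cancel(self):
        nvsl, _ = tuning.compute_nvsl(EIGHT_DIRS, np.full(8, 5.0))
        assert nvsl == pytest.approx(0.0, abs=1e-12)

    def test_single_direction_gives_one(self):
        r = np.zeros(8)
        r[2] = 30.0  # 90°
        nvsl, pref = tuning.compute_nvsl(EIGHT_DIRS, r)
        assert nvsl == pytest.approx(1.0)
        assert pref == pytest.approx(90.0)

    def test_cosine_tuning_gives_half(self):
        # r_j = 1 + cos θ_j on the 8 canonical directions → NVSL 0.5, pref 0°
        r = 1 + np.cos(np.deg2rad(EIGHT_DIRS))
        nvsl, pref = tuning.compute_nvsl(EIGHT_DIRS, r)
        assert nvsl == pytest.approx(0.5)
        assert pref % 360 == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_undefined(self):
        nvsl, pref = tuning.compute_nvsl(EIGHT_DIRS, np.zeros(8))
        assert nvsl is None and pref is None

    @given(st.floats(0.01, 100.0),
           st.lists(st.floats(0.0, 50.0), min_size=8, max_size=8))
    def test_positive_scaling_invariance(self, c, resp):
        resp = np.asarray(resp)
        if resp.sum() == 0:
            return
        n1, p1 = tuning.compute_nvsl(EIGHT_DIRS, resp)
        n2, p2 = tuning.compute_nvsl(EIGHT_DIRS, c * resp)
        assert n1 == pytest.approx(n2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_nvsl_monotone_in_kappa_on_templates(self):
        # measured NVSL never decreases as the generator concentration grows
        ep_base = dict(protocol=Protocol.DIRECTION_SERIES, onset=0.2,
                       duration=1.0, trial_duration=1.5, diameter=200.0,
                       speed=800.0)
        nvsls = []
        for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
            p = CellTypeParams(polarity=Polarity.ON_OFF, spontaneous_rate=2.0,
                               ds_kappa=kappa, preferred_direction=90.0)
            resp = []
            for ang in EIGHT_DIRS:
                r = synth.rate_template(
                    p, StimulusEpoch(epoch_id=f"d{ang}", direction=float(ang),
                                     **ep_base))
                resp.append(r.rates.max())
            nvsl, _ = tuning.compute_nvsl(EIGHT_DIRS, resp)
            nvsls.append(nvsl)
        assert all(a <= b + 1e-12 for a, b in zip(nvsls, nvsls[1:]))


class TestTuningCurve:
    def test_two_point_curve(self):
        c = tuning.build_tuning_curve([100, 200], [10, 20], "size")
        assert np.allclose(c.x, [100, 200])
        assert np.allclose(c.responses, [10, 20])

    def test_duplicate_x_averaged(self):
        c = tuning.build_tuning_curve([100, 100, 200], [10, 20, 5], "size")
        assert np.allclose(c.x, [100, 200])
        assert np.allclose(c.responses, [15, 5])

    def test_single_x_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tuning.build_tuning_curve([100, 100], [1, 2], "size")

    def test_best_x_and_tie_rule(self):
        c = TuningCurve("size", [100, 200, 400], [5, 9, 3])
        assert tuning.best_x(c) == 200
        flat = TuningCurve("size", [100, 200, 400], [5, 5, 5])
        assert tuning.best_x(flat) == 100

    def test_best_x_matches_brute_force(self, rng):
        x = np.sort(rng.uniform(50, 800, 6))
        r = rng.uniform(0, 50, 6)
        c = TuningCurve("size", x, r)
        assert tuning.best_x(c) == x[max(range(6), key=lambda i: r[i])]


class TestTuningWidth:
    def test_flat_curve_width_equals_range(self):
        c = TuningCurve("size", [50, 100, 200, 400, 800], np.full(5, 20.0))
        assert tuning.tuning_width(c) == pytest.approx(750.0)

    def test_triangle_width_is_half_range(self):
        c = TuningCurve("size", [0, 400, 800], [0, 60, 0])
        assert tuning.tuning_width(c) == pytest.approx(400.0)

    def test_matches_trapezoid_oracle(self, rng):
        x = np.sort(rng.uniform(50, 800, 5))
        r = rng.uniform(1, 60, 5)
        c = TuningCurve("size", x, r)
        oracle = sum((r[i] + r[i + 1]) / 2 * (x[i + 1] - x[i])
                     for i in range(4)) / r.max()
        assert tuning.tuning_width(c) == pytest.approx(oracle, abs=1e-9)

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=8))
    def test_width_never_exceeds_range(self, resp):
        x = 50.0 * np.arange(1, len(resp) + 1)
        c = TuningCurve("size", x, np.asarray(resp))
        assert tuning.tuning_width(c) <= c.x_range + 1e-9

    def test_all_zero_curve_undefined(self):
        c = TuningCurve("size", [50, 100, 200], np.zeros(3))
        assert tuning.tuning_width(c) is None


class TestFitGamma:
    def test_recovers_noise_free_gamma(self):
        # shape 3, scale 100 → analytic argmax at 200
        x = np.array([25, 50, 100, 150, 200, 300, 500, 800], float)
        g = (x / 100) ** 2 * np.exp(-x / 100)
        y = 4.0 + 50.0 * g / g.max()
        fit = tuning.fit_gamma(TuningCurve("size", x, y))
        assert fit.ok
        assert fit.best_x_fit == pytest.approx(200.0, rel=0.01)
        assert fit.baseline == pytest.approx(4.0, abs=0.5)

    def test_flat_curve_degenerates_to_baseline(self):
        x = np.array([50, 100, 200, 400, 800], float)
        fit = tuning.fit_gamma(TuningCurve("size", x, np.full(5, 12.0)))
        assert fit.ok
        assert fit.amplitude == pytest.approx(0.0, abs=0.5)
        assert fit.baseline + fit.amplitude == pytest.approx(12.0, abs=0.5)

    def test_monotone_increasing_flagged_unbounded(self):
        # truncated rising limb of a gamma: optimum beyond the tested range
        x = np.array([50, 100, 200, 400, 800], float)
        g = (x / 2000) ** 2 * np.exp(-x / 2000)
        y = 2.0 + 80.0 * g / g.max()
        fit = tuning.fit_gamma(TuningCurve("size", x, y))
        assert fit.best_x_fit >= 800.0
        assert "unbounded_within_range" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            tuning.fit_gamma(TuningCurve("size", [1, 2, 3], [1, 2, 3]))


class TestCutoffFrequency:
    def test_crossing_exactly_at_last_point(self):
        c = TuningCurve("frequency", [1, 2, 4], [100, 100, 50])
        assert tuning.cutoff_frequency(c) == pytest.approx(4.0)

    def test_never_half_maximal_gives_none(self):
        c = TuningCurve("frequency", [1, 2, 4], [100, 90, 80])
        assert tuning.cutoff_frequency(c) is None

    def test_interpolated_crossing_matches_dense_oracle(self):
        c = TuningCurve("frequency", [1, 2, 4], [100, 80, 20])
        got = tuning.cutoff_frequency(c)
        # dense log2-linear interpolation oracle
        lf = np.linspace(1, 2, 100001)  # log2 f from 2 to 4 Hz
        r = np.interp(lf, [1, 2], [80, 20])
        oracle = 2.0 ** lf[np.argmin(np.abs(r - 50.0))]
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_all_zero_gives_none(self):
        c = TuningCurve("frequency", [1, 2, 4], [0, 0, 0])
        assert tuning.cutoff_frequency(c) is None


class TestPolarity:
    def test_pure_on(self):
        lab, idx = tuning.polarity(40.0, 0.0)
        assert lab is Polarity.ON and idx == 1.0

    def test_balanced_on_off(self):
        lab, idx = tuning.polarity(25.0, 25.0)
        assert lab is Polarity.ON_OFF and idx == 0.0

    def test_boundary_index_is_off(self):
        # on=10, off=30 → index exactly −0.5 → OFF (boundary inclusive)
        lab, idx = tuning.polarity(10.0, 30.0)
        assert idx == pytest.approx(-0.5)
        assert lab is Polarity.OFF

    def test_unresponsive(self):
        lab, idx = tuning.polarity(0.0, 0.0)
        assert lab is None and idx is None


class TestPreferredDirectionRecovery:
    def test_ds_cells_recover_preferred_direction(self):
        # κ=2, 5 trials/direction: within ±10° for nearly all of 40 cells
        # (the full 200-cell panel runs in the acceptance suite)
        # no diameter/speed gain so the effective peak drive is exactly 60
        n_cells, hits = 40, 0
        ep_base = dict(protocol=Protocol.DIRECTION_SERIES, onset=0.2,
                       duration=1.0, trial_duration=1.5)
        from rgcpipe import sdf as sdfmod
        for i in range(n_cells):
            rng = np.random.default_rng([99, i])
            true_pref = float(rng.uniform(0, 360))
            p = CellTypeParams(polarity=Polarity.ON_OFF, spontaneous_rate=2.0,
                               peak_gain=60.0, ds_kappa=2.0,
                               preferred_direction=true_pref)
            resp = []
            for ang in EIGHT_DIRS:
                ep = StimulusEpoch(epoch_id=f"d{ang}", direction=float(ang),
                                   **ep_base)
                template = synth.rate_template(p, ep)
                trains = [synth.sample_spikes(template, rng) - ep.onset
                          for _ in range(5)]
                r = sdfmod.compute_sdf(trains, 0.025, 0.002,
                                       (-0.1, ep.duration + 0.3))
                pk, _ = sdfmod.peak_response(r, (0.0, r.span[1]))
                resp.append(pk)
            _, pref = tuning.compute_nvsl(EIGHT_DIRS, resp)
            err = abs(pref - true_pref) % 360
            if min(err, 360 - err) <= 10.0:
                hits += 1
        assert hits / n_cells >= 0.95
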