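"""Generator tests: rate templates, Poisson sampling, experiment and
retina-map simulation, all against analytic or Monte-Carlo expectations."""

import numpy as np
import pytest

from rgcpipe import synth
from rgcpipe.types import CellTypeParams, ClassLabel, Polarity, Protocol, StimulusEpoch


def step_epoch(**kw):
    base = dict(epoch_id="e", protocol=Protocol.CONTRAST_STEP, onset=0.5,
                duration=1.0, trial_duration=2.5, diameter=400.0)
    base.update(kw)
    return StimulusEpoch(**base)


def motion_epoch(direction, **kw):
    base = dict(epoch_id="m", protocol=Protocol.DIRECTION_SERIES, onset=0.2,
                duration=1.0, trial_duration=1.5, diameter=200.0,
                direction=direction, speed=800.0)
    base.update(kw)
    return StimulusEpoch(**base)


class TestRateTemplate:
    def test_blank_stimulus_gives_spontaneous_rate(self):
        p = CellTypeParams(polarity=Polarity.ON, spontaneous_rate=7.0)
        r = synth.rate_template(p, step_epoch(contrast=0.0))
        assert np.allclose(r.rates, 7.0)

    def test_zero_kappa_is_direction_flat(self):
        p = CellTypeParams(polarity=Polarity.ON_OFF, ds_kappa=0.0)
        r1 = synth.rate_template(p, motion_epoch(0.0))
        r2 = synth.rate_template(p, motion_epoch(180.0))
        assert np.array_equal(r1.rates, r2.rates)

    def test_von_mises_drive_ratio_preferred_vs_null(self):
        # κ=2, preferred 90°: drive above baseline at 90° vs 270° is e^4
        p = CellTypeParams(polarity=Polarity.ON_OFF, spontaneous_rate=0.0,
                           ds_kappa=2.0, preferred_direction=90.0)
        r_pref = synth.rate_template(p, motion_epoch(90.0))
        r_null = synth.rate_template(p, motion_epoch(270.0))
        assert r_pref.rates.max() / r_null.rates.max() == pytest.approx(np.e ** 4)

    def test_polarity_determines_response_timing(self):
        ep = step_epoch()
        for pol, t_expect in [(Polarity.ON, ep.onset), (Polarity.OFF, ep.offset)]:
            p = CellTypeParams(polarity=pol, spontaneous_rate=0.0)
            r = synth.rate_template(p, ep)
            t_peak = r.times[np.argmax(r.rates)]
            assert t_peak == pytest.approx(t_expect, abs=2 * r.dt)
        p = CellTypeParams(polarity=Polarity.ON_OFF, spontaneous_rate=0.0,
                           kinetics_tau=0.05)
        r = synth.rate_template(p, ep)
        # both transitions drive the On-Off cell
        on_idx = np.searchsorted(r.times, ep.onset + 0.01)
        off_idx = np.searchsorted(r.times, ep.offset + 0.01)
        assert r.rates[on_idx] > 10 and r.rates[off_idx] > 10

    def test_rates_never_negative_and_revert_to_spontaneous(self):
        p = CellTypeParams(polarity=Polarity.ON, spontaneous_rate=4.0,
                           kinetics_tau=0.05)
        r = synth.rate_template(p, step_epoch())
        assert (r.rates >= 0).all()
        pre = r.rates[r.times < 0.5]
        assert np.allclose(pre, 4.0)

    def test_nonuniform_grid_rejected_via_bad_step(self):
        p = CellTypeParams(polarity=Polarity.ON)
        with pytest.raises(ValueError):
            synth.rate_template(p, step_epoch(), dt=-0.001)

    def test_grid_must_cover_epoch(self):
        p = CellTypeParams(polarity=Polarity.ON)
        with pytest.raises(ValueError):
            synth.rate_template(p, step_epoch(), t0=0.0, dt=0.001, n=100)


class TestSampleSpikes:
    def test_zero_rate_gives_empty_train(self):
        r = synth.rate_template(
            CellTypeParams(polarity=Polarity.ON, spontaneous_rate=0.0),
            step_epoch(contrast=0.0))
        assert synth.sample_spikes(r, seed=0).size == 0

    def test_constant_rate_monte_carlo_mean(self):
        # r = 10 AP/s over 2 s: mean count over 1000 seeds within 3·√(rT/1000)
        from rgcpipe.types import RateFunction
        rate = RateFunction(0.0, 0.001, np.full(2001, 10.0), bandwidth=0.0)
        counts = [synth.sample_spikes(rate, seed=s).size for s in range(1000)]
        expected = 20.0
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 1000)

    def test_sorted_unique_within_span_and_deterministic(self):
        p = synth.CLASS_PARAMS[ClassLabel.ON_SUSTAINED]
        r = synth.rate_template(p, step_epoch())
        a = synth.sample_spikes(r, seed=42)
        b = synth.sample_spikes(r, seed=42)
        assert np.array_equal(a, b)
        assert (np.diff(a) > 0).all()
        # unique at grid resolution
        bins = (a / r.dt).astype(int)
        assert np.unique(bins).size == bins.size
        assert a.min() >= r.span[0] and a.max() <= r.span[1]


class TestSimulateExperiment:
    def test_requested_cell_counts_and_ground_truth(self):
        pop = {"SC": synth.GroupSpec(10, {ClassLabel.ON_SUSTAINED: 1.0})}
        ds = synth.simulate_experiment(pop, seed=1)
        assert len(ds.ground_truth) == 10
        assert (ds.ground_truth.class_label == "ON_SUSTAINED").all()

    def test_same_seed_identical_dataset(self):
        pop = {"SC": synth.GroupSpec(2, {ClassLabel.ON_OFF_DS: 1.0})}
        a = synth.simulate_experiment(pop, seed=5)
        b = synth.simulate_experiment(pop, seed=5)
        assert a.spikes.equals(b.spikes)
        assert a.ground_truth.equals(b.ground_truth)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.GroupSpec(10, {ClassLabel.ON_SUSTAINED: 0.5})

    def test_full_protocol_battery_per_cell(self):
        pop = {"SC": synth.GroupSpec(1, {ClassLabel.OFF_TRANSIENT: 1.0})}
        ds = synth.simulate_experiment(pop, seed=2)
        eps = ds.epoch_objects(ds.ground_truth.cell_id[0])
        by_proto = {}
        for ep in eps.values():
            by_proto.setdefault(ep.protocol, []).append(ep)
        assert len(by_proto[Protocol.SIZE_SERIES]) == 5
        assert len(by_proto[Protocol.DIRECTION_SERIES]) == 8
        assert all(e.speed == 800.0 for e in by_proto[Protocol.DIRECTION_SERIES])
        assert len(by_proto[Protocol.SPEED_SERIES]) == 7
        assert len(by_proto[Protocol.TEMPORAL_MODULATION]) == 3
        assert Protocol.CONTRAST_STEP in by_proto

    def test_default_population_mirrors_published_counts(self):
        pop = synth.default_population()
        dlgn = pop["dLGN"].counts()
        sc = pop["SC"].counts()
        assert dlgn[ClassLabel.ON_OFF_DS] == 10
        assert sc[ClassLabel.ON_OFF_DS] == 20
        assert dlgn[ClassLabel.OFF_SUSTAINED] == 11
        assert sc[ClassLabel.OFF_TRANSIENT] == 15


class TestSimulateRetinaMap:
    def test_empty_channel(self):
        params = synth.RetinaMapParams(channels={
            "gfp": synth.ChannelSpec(0, (0, 0), 100.0),
            "mcherry": synth.ChannelSpec(5, (500, 0), 100.0)})
        m = synth.simulate_retina_map(params, seed=0)
        assert m.points("gfp").shape[0] == 0
        assert m.points("mcherry").shape[0] == 5

    def test_cluster_center_recovered_within_clt_bound(self):
        # n=500, sd=150 μm: sample mean within 4·150/√500 per axis
        center = (1200.0, -300.0)
        params = synth.RetinaMapParams(channels={
            "gfp": synth.ChannelSpec(500, center, 150.0)})
        m = synth.simulate_retina_map(params, seed=3)
        mean = m.points("gfp").mean(axis=0)
        bound = 4 * 150 / np.sqrt(500)
        assert abs(mean[0] - center[0]) < bound
        assert abs(mean[1] - center[1]) < bound

    def test_colabel_prob_one_labels_every_reference_cell(self):
        params = synth.RetinaMapParams(
            channels={"gfp": synth.ChannelSpec(50, (0, 0), 100.0),
                      "did": synth.ChannelSpec(10, (300, 300), 100.0)},
            colabel={("gfp", "did"): 1.0})
        m = synth.simulate_retina_map(params, seed=1)
        gfp = m.cells[m.cells.label_gfp]
        assert gfp.label_did.all()

    def test_points_stay_within_retina_radius(self):
        params = synth.RetinaMapParams(
            channels={"gfp": synth.ChannelSpec(200, (2000, 0), 400.0)},
            retina_radius=2200.0)
        m = synth.simulate_retina_map(params, seed=2)
        pts = m.points("gfp")
        assert (np.hypot(pts[:, 0], pts[:, 1]) <= 2200.0).all()

    def test_invalid_colabel_prob_rejected(self):
        with pytest.raises(ValueError):
            synth.RetinaMapParams(
                channels={"a": synth.ChannelSpec(1, (0, 0), 10.0)},
                colabel={("a", "a"): 1.5})
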