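"""Retinal-wave generator and burst scheduler statistics."""

import numpy as np
import pytest

from retmap import (
    SpikeTrain,
    build_retina,
    generate_waves,
    binocular_streams,
    onoff_spikes,
    spikes_from_waves,
    wave_statistics,
)
from retmap.config import BurstParams, WaveParams
from retmap.geometry import CLASS_ON
from retmap.waves import WaveEvent, _burst


@pytest.fixture(scope="module")
def wave_retina():
    return build_retina(2500, seed=11, radius_mm=2.25)


@pytest.fixture(scope="module")
def waves_3h(wave_retina):
    return generate_waves(wave_retina, 3 * 3600, seed=12)


class TestWaveGeneration:
    def test_zero_duration_empty(self, wave_retina):
        assert generate_waves(wave_retina, 0.0, seed=1) == []

    def test_small_retina_warns(self):
        tiny = build_retina(100, seed=0, radius_mm=0.4)
        with pytest.warns(UserWarning):
            generate_waves(tiny, 200.0, seed=1)

    def test_arrival_nondecreasing_with_distance(self, wave_retina, waves_3h):
        for w in waves_3h[:20]:
            xy = wave_retina.xy_mm[w.cell_ids]
            d = np.hypot(xy[:, 0] - w.origin_mm[0], xy[:, 1] - w.origin_mm[1])
            order = np.argsort(d)
            assert np.all(np.diff(w.arrival[order]) >= -1e-12)

    def test_statistics_match_configuration(self, wave_retina, waves_3h):
        # >= 100 waves; velocity, per-location interval and area within 10%
        assert len(waves_3h) >= 100
        train = spikes_from_waves(waves_3h, wave_retina.n_cells, 3 * 3600, seed=13)
        s = wave_statistics(waves_3h, wave_retina, train=train)
        assert abs(s["mean_velocity_um_s"] - 130.0) / 130.0 < 0.1
        assert abs(s["mean_interval_s"] - 90.0) / 90.0 < 0.1
        assert abs(s["mean_area_mm2"] - 0.95) / 0.95 < 0.1
        assert abs(s["mean_rate_hz"] - 0.5) / 0.5 < 0.1

    def test_deterministic_per_seed(self, wave_retina):
        a = generate_waves(wave_retina, 1200, seed=5)
        b = generate_waves(wave_retina, 1200, seed=5)
        assert len(a) == len(b)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.cell_ids, wb.cell_ids)
            np.testing.assert_allclose(wa.arrival, wb.arrival)


class TestWaveStatisticsOracle:
    """wave_statistics on constructed inputs with known answers."""

    def _constant_speed_wave(self, retina, origin, t0, v_um_s):
        xy = retina.xy_mm
        d = np.hypot(xy[:, 0] - origin[0], xy[:, 1] - origin[1])
        cov = np.flatnonzero(d <= 0.8)
        return WaveEvent(
            origin_mm=np.asarray(origin), start_time=t0, speed=v_um_s,
            radius_mm=0.8, area_mm2=np.pi * 0.64,
            cell_ids=cov.astype(np.int32),
            arrival=t0 + d[cov] * 1000.0 / v_um_s,
        )

    def test_velocity_recovered_exactly(self, wave_retina):
        w1 = self._constant_speed_wave(wave_retina, (0.0, 0.0), 0.0, 200.0)
        w2 = self._constant_speed_wave(wave_retina, (0.0, 0.0), 90.0, 200.0)
        s = wave_statistics([w1, w2], wave_retina, n_locations=50)
        assert s["mean_velocity_um_s"] == pytest.approx(200.0, rel=1e-6)

    def test_interval_of_two_covering_waves(self, wave_retina):
        w1 = self._constant_speed_wave(wave_retina, (0.0, 0.0), 0.0, 130.0)
        w2 = self._constant_speed_wave(wave_retina, (0.0, 0.0), 90.0, 130.0)
        s = wave_statistics([w1, w2], wave_retina, n_locations=400, seed=3)
        assert s["mean_interval_s"] == pytest.approx(90.0)

    def test_single_wave_rejected(self, wave_retina):
        w1 = self._constant_speed_wave(wave_retina, (0.0, 0.0), 0.0, 130.0)
        with pytest.raises(ValueError):
            wave_statistics([w1], wave_retina)


class TestBursts:
    def test_burst_arithmetic(self):
        # 20 Hz x 2.5 s: 50 spikes at 50 ms spacing
        t = _burst(0.0, 20.0, 2.5)
        assert len(t) == 50
        assert np.all(np.diff(t) == 50)

    def test_empty_wave_list(self):
        train = spikes_from_waves([], 100, 10.0, seed=0)
        assert train.n_spikes == 0

    def test_spikes_sorted_unique_ms(self, wave_retina, waves_3h):
        train = spikes_from_waves(waves_3h, wave_retina.n_cells, 3 * 3600, seed=1)
        for spikes in train.per_cell()[:50]:
            assert np.all(np.diff(spikes) > 0)

    def test_nearby_cells_more_correlated_than_distant(self, wave_retina, waves_3h):
        train = spikes_from_waves(waves_3h, wave_retina.n_cells, 3 * 3600, seed=2)
        per = train.per_cell()
        bins = np.arange(0, 3 * 3600 * 1000 + 1, 1000)

        def counts(c):
            return np.histogram(per[c], bins=bins)[0]

        xy = wave_retina.xy
        d = np.hypot(*(xy - xy[0]).T)
        near = np.argsort(d)[1:6]
        far = np.argsort(d)[-5:]
        c0 = counts(0)
        r_near = np.mean([np.corrcoef(c0, counts(c))[0, 1] for c in near])
        r_far = np.mean([np.corrcoef(c0, counts(c))[0, 1] for c in far])
        assert r_near > r_far + 0.2

    def test_replay_identical(self, wave_retina, waves_3h):
        a = spikes_from_waves(waves_3h, wave_retina.n_cells, 3600, seed=9)
        b = spikes_from_waves(waves_3h, wave_retina.n_cells, 3600, seed=9)
        np.testing.assert_array_equal(a.times_ms, b.times_ms)
        np.testing.assert_array_equal(a.cells, b.cells)


@pytest.fixture(scope="module")
def onoff_setup():
    retina = build_retina(1500, class_scheme="onoff", seed=3, radius_mm=2.25)
    waves = generate_waves(retina, 2 * 3600, seed=4)
    train = onoff_spikes(waves, retina, 2 * 3600, seed=5)
    return retina, waves, train


class TestOnOff:
    def test_on_participation_fraction(self, onoff_setup):
        retina, waves, train = onoff_setup
        per = train.per_cell()
        n_cov = n_join = 0
        for w in waves:
            for cid, arr in zip(w.cell_ids, w.arrival):
                if retina.cell_class[cid] == CLASS_ON:
                    n_cov += 1
                    t0 = int(arr * 1000)
                    sp = per[cid]
                    lo = np.searchsorted(sp, t0 - 1)
                    if lo < len(sp) and sp[lo] <= t0 + 50:
                        n_join += 1
        assert n_cov > 100
        assert abs(n_join / n_cov - 0.67) < 0.03

    def test_off_cells_three_cycles_every_wave(self, onoff_setup):
        retina, waves, train = onoff_setup
        bp = BurstParams()
        per = train.per_cell()
        w = waves[5]
        checked = 0
        for cid, arr in zip(w.cell_ids, w.arrival):
            if retina.cell_class[cid] != CLASS_ON and checked < 10:
                sp = per[cid]
                for c in range(bp.cycles_per_wave):
                    start = (arr + bp.on_lead + c * bp.cycle_period) * 1000
                    n = ((sp >= start - 1) & (sp < start + bp.off_duration * 1000)).sum()
                    assert n >= bp.off_rate * bp.off_duration * 0.9
                checked += 1
        assert checked > 0

    def test_on_leads_off_by_one_second(self, onoff_setup):
        retina, waves, train = onoff_setup
        per = train.per_cell()
        w = waves[3]
        on = [c for c in w.cell_ids if retina.cell_class[c] == CLASS_ON]
        off = [c for c in w.cell_ids if retina.cell_class[c] != CLASS_ON]
        arr = dict(zip(w.cell_ids, w.arrival))
        # find a co-participating ON cell (first spike at its arrival time)
        for c in on:
            sp = per[c]
            t0 = int(round(arr[c] * 1000))
            if np.any(sp == t0):
                t_on_first = t0
                c_off = min(off, key=lambda o: abs(arr[o] - arr[c]))
                t_off_burst = int(round((arr[c_off] + 1.0) * 1000))
                assert np.any(np.abs(per[c_off] - t_off_burst) <= 1)
                break
        else:
            pytest.fail("no participating ON cell found")

    def test_on_rate_is_24hz_within_burst(self, onoff_setup):
        retina, waves, train = onoff_setup
        bp = BurstParams()
        # a participating ON burst contains round(24 * duration) spikes
        per = train.per_cell()
        w = waves[2]
        for cid, arr in zip(w.cell_ids, w.arrival):
            if retina.cell_class[cid] == CLASS_ON:
                sp = per[cid]
                t0 = int(round(arr * 1000))
                if np.any(sp == t0):
                    n = ((sp >= t0) & (sp < t0 + bp.on_duration * 1000)).sum()
                    assert n == round(bp.on_rate * bp.on_duration)
                    return
        pytest.fail("no participating ON cell found")


class TestBinocular:
    def test_correlated_streams_identical(self):
        rl = build_retina(800, eye="L", seed=6, radius_mm=2.25)
        rr = build_retina(800, eye="R", seed=6, radius_mm=2.25)
        tl, tr, wl, wr = binocular_streams(rl, rr, True, 1800.0, seeds=(1, 2))
        np.testing.assert_array_equal(tl.times_ms, tr.times_ms)
        np.testing.assert_array_equal(tl.cells, tr.cells)
        for a, b in zip(wl, wr):
            np.testing.assert_array_equal(a.cell_ids, b.cell_ids)

    def test_uncorrelated_streams_decorrelated(self):
        rl = build_retina(800, eye="L", seed=6, radius_mm=2.25)
        rr = build_retina(800, eye="R", seed=6, radius_mm=2.25)
        tl, tr, _, _ = binocular_streams(rl, rr, False, 3600.0, seeds=(1, 2))
        bins = np.arange(0, 3600_000 + 1, 1000)
        rs = []
        per_l, per_r = tl.per_cell(), tr.per_cell()
        for c in range(0, 800, 80):
            a = np.histogram(per_l[c], bins=bins)[0]
            b = np.histogram(per_r[c], bins=bins)[0]
            if a.std() > 0 and b.std() > 0:
                rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 0.05
        # same statistics in both eyes
        assert abs(tl.mean_rate() - tr.mean_rate()) < 0.1


class TestSpikeTrainRoundTrip:
    def test_table_round_trip(self, wave_retina, waves_3h):
        train = spikes_from_waves(waves_3h, wave_retina.n_cells, 600, seed=1)
        back = SpikeTrain.from_table(
            train.to_table(), wave_retina.n_cells, 600
        )
        np.testing.assert_array_equal(train.times_ms, back.times_ms)
        np.testing.assert_array_equal(train.cells, back.cells)
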