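import numpy as np
import pytest

import epimap as em
from epimap.errors import InvalidArgumentError


def _amap(times, valid=None, ids=None):
    times = np.asarray(times, dtype=float)
    valid = np.ones(times.size, bool) if valid is None else np.asarray(valid)
    ids = np.arange(times.size) if ids is None else np.asarray(ids)
    return em.ActivationMap(
        beat_index=0,
        channel_ids=ids,
        times_ms=np.where(valid, times, np.nan),
        slope_mv_per_ms=np.ones(times.size),
        valid=valid,
    )


class TestSegmentBeats:
    def test_counts_scheduled_beats(self, layout16):
        scenario = em.sinus_scenario(layout16, rate_bpm=120.0)
        rec, truth = em.render_recording(layout16, scenario, duration_s=2.0, seed=1)
        windows = em.segment_beats(em.bandpass(rec))
        assert len(windows) == truth.beat_times_ms.size == 4

    def test_flat_recording_empty(self):
        rec = em.ElectrogramRecording(2048.0, np.zeros((4, 4096)), np.arange(4))
        assert em.segment_beats(rec) == []

    def test_windows_sorted_and_disjoint(self, sinus_fixture):
        rec, _, _ = sinus_fixture
        windows = em.segment_beats(em.bandpass(rec))
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            assert a0 < a1 <= b0 < b1


class TestDetectActivation:
    def test_noise_free_matches_truth_within_one_sample(self, sinus_fixture):
        rec, truth, _ = sinus_fixture
        rec = em.bandpass(rec)
        windows = em.segment_beats(rec)
        sample_ms = 1000.0 / rec.sample_rate
        for b, w in enumerate(windows):
            amap = em.detect_activation(rec, w, beat_index=b)
            assert np.all(np.abs(amap.times_ms - truth.activation_ms[b]) <= sample_ms + 1e-9)

    def test_polarity_modes_agree_on_wavelet(self, sinus_fixture):
        rec, _, _ = sinus_fixture
        rec = em.bandpass(rec)
        w = em.segment_beats(rec)[0]
        a1 = em.detect_activation(rec, w, polarity="steepest_negative")
        a2 = em.detect_activation(rec, w, polarity="steepest_absolute")
        assert np.array_equal(a1.times_ms, a2.times_ms)

    def test_tie_breaks_to_earliest_sample(self):
        fs = 1000.0
        x = np.zeros(100)
        x[10:14] = [1.0, -1.0, 1.0, -1.0]  # two equal extreme slopes
        rec = em.ElectrogramRecording(fs, x[None, :], np.array([0]))
        amap = em.detect_activation(rec, (0.0, 99.0))
        deriv = np.gradient(x)
        first = np.flatnonzero(deriv == deriv.min())[0]
        assert amap.times_ms[0] == pytest.approx(first / fs * 1000.0)

    def test_bad_channel_gets_no_time(self, sinus_fixture):
        rec, _, _ = sinus_fixture
        rec = em.bandpass(rec)
        w = em.segment_beats(rec)[0]
        amap = em.detect_activation(rec, w, invalid_channels={3, 9})
        assert np.isnan(amap.times_ms[3]) and not amap.valid[9]

    def test_window_too_short_rejected(self, sinus_fixture):
        rec, _, _ = sinus_fixture
        with pytest.raises(InvalidArgumentError):
            em.detect_activation(rec, (100.0, 100.01))


class TestIsochrones:
    def test_15_equal_bands_one_channel_each(self):
        iso = em.build_isochrones(_amap(np.arange(15.0)), n_bands=15)
        widths = np.diff(iso.edges_ms)
        assert widths.size == 15
        assert np.allclose(widths, widths[0])
        assert np.array_equal(np.sort(iso.band), np.arange(15))

    def test_degenerate_all_equal(self):
        iso = em.build_isochrones(_amap(np.full(8, 3.0)))
        assert iso.degenerate
        assert np.all(iso.band == 0)

    def test_max_time_in_last_band(self):
        iso = em.build_isochrones(_amap([0.0, 7.0, 15.0]), n_bands=15)
        assert iso.band[2] == 14

    def test_band_monotone_in_time(self, sinus_fixture):
        rec, _, _ = sinus_fixture
        rec = em.bandpass(rec)
        amap = em.detect_activation(rec, em.segment_beats(rec)[0])
        iso = em.build_isochrones(amap)
        order = np.argsort(amap.times_ms)
        assert np.all(np.diff(iso.band[order]) >= 0)

    def test_early_red_late_blue_convention_tagged(self):
        iso = em.build_isochrones(_amap(np.arange(15.0)))
        assert "early=red" in iso.color_convention

    def test_invalid_map_rejected(self):
        with pytest.raises(InvalidArgumentError):
            _amap([1.0, 2.0], valid=np.zeros(2, bool))


class TestActivationFrames:
    def test_frame_count_arithmetic(self):
        frames = em.activation_frames(_amap(np.linspace(0, 20, 21)), 5.0)
        assert len(frames) == 4

    def test_frames_partition_valid_channels(self, sinus_fixture):
        rec, _, _ = sinus_fixture
        rec = em.bandpass(rec)
        amap = em.detect_activation(rec, em.segment_beats(rec)[0])
        frames = em.activation_frames(amap, 5.0)
        union = np.concatenate(frames)
        assert np.array_equal(np.sort(union), np.sort(amap.channel_ids[amap.valid]))

    def test_plane_wave_frames_are_column_bands(self, layout16, graph16):
        scenario = em.sinus_scenario(layout16, cv_m_per_s=1.0)
        times, _ = em.geodesic_activation_times(layout16, graph16, scenario)
        amap = _amap(times, ids=layout16.channel_ids)
        frames = em.activation_frames(amap, 5.0)
        seen = set()
        for frame in frames:
            cols = set(layout16.cols[layout16.index_of(frame)].tolist())
            assert not (cols & seen)  # each column activates in exactly one frame
            seen |= cols

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(InvalidArgumentError):
            em.activation_frames(_amap([0.0, 1.0]), 0.0)


class TestConductionVelocity:
    def test_exact_plane_wave_unit_speed(self, layout16):
        times = layout16.positions[:, 0] / 1.0  # T = x, CV 1 m/s
        cv = em.estimate_cv(_amap(times, ids=layout16.channel_ids), layout16)
        assert cv.cv_m_per_s[cv.valid] == pytest.approx(1.0)
        assert cv.mean_m_per_s == pytest.approx(1.0)

    def test_half_speed_direction_plus_x(self, layout16):
        times = layout16.positions[:, 0] / 0.5
        cv = em.estimate_cv(_amap(times, ids=layout16.channel_ids), layout16)
        assert cv.mean_m_per_s == pytest.approx(0.5)
        # direction is defined up to the tangent-basis sign; check the axis
        d = cv.direction[cv.valid]
        assert np.allclose(np.abs(d[:, 0]), 1.0, atol=1e-6)

    def test_noisy_fixture_recovers_scenario_cv(self, layout16, graph16):
        scenario = em.sinus_scenario(layout16, cv_m_per_s=1.04)
        clean, _ = em.render_recording(layout16, scenario, duration_s=2.0, seed=0)
        noise = em.snr_noise_rms(clean.signals, 20.0)
        rec, _ = em.render_recording(
            layout16, scenario, duration_s=2.0, noise_rms=noise, seed=17
        )
        rec = em.bandpass(rec)
        amap = em.detect_activation(rec, em.segment_beats(rec)[0])
        cv = em.estimate_cv(amap, layout16, graph=graph16)
        assert cv.mean_m_per_s == pytest.approx(1.04, rel=0.05)

    def test_error_vanishes_with_noise(self, layout16, graph16):
        """CV estimator consistency: plane-wave error shrinks as noise does."""
        scenario = em.sinus_scenario(layout16, cv_m_per_s=1.0)
        clean, _ = em.render_recording(layout16, scenario, duration_s=2.0, seed=0)
        errs = {}
        for frac in (0.0, 0.01, 0.05):
            noise = frac * np.sqrt(np.mean(clean.signals**2))
            rec, _ = em.render_recording(
                layout16, scenario, duration_s=2.0, noise_rms=noise, seed=23
            )
            rec = em.bandpass(rec)
            amap = em.detect_activation(rec, em.segment_beats(rec)[0])
            cv = em.estimate_cv(amap, layout16, graph=graph16)
            errs[frac] = abs(cv.mean_m_per_s - 1.0)
        assert errs[0.0] < 0.01   # only sample-quantization error remains
        assert errs[0.01] < 0.02
        assert errs[0.05] < 0.05

    def test_all_skipped_rejected(self):
        layout = em.grid_layout(1, 3, 1.0)
        with pytest.raises(InvalidArgumentError):
            # collinear layout: no 2-D neighbourhood anywhere
            em.estimate_cv(_amap([0.0, 1.0, 2.0]), layout)


class TestOriginLocalization:
    def test_focal_fixture_source_recovered(self, layout16, graph16):
        src = int(16 * 5 + 5)
        scenario = em.focal_scenario(layout16, src)
        rec, _ = em.render_recording(layout16, scenario, duration_s=2.0, seed=2)
        rec = em.bandpass(rec)
        amap = em.detect_activation(rec, em.segment_beats(rec)[0])
        origin = em.localize_origin(amap, layout16, graph=graph16)
        assert origin.channel_id == src

    def test_paced_pair_returns_one_of_pair(self, layout16, graph16):
        pair = (16 * 15 + 7, 16 * 15 + 8)  # two adjacent bottom-row electrodes
        scenario = em.paced_scenario(layout16, pair)
        rec, _ = em.render_recording(layout16, scenario, duration_s=2.0, seed=2)
        rec = em.bandpass(rec)
        amap = em.detect_activation(rec, em.segment_beats(rec)[0])
        origin = em.localize_origin(amap, layout16, graph=graph16)
        assert origin.channel_id in pair

    def test_tie_breaks_to_greatest_neighbor_delay(self, layout3, graph3):
        # channels 0 and 8 share the minimum; 8's neighbours lag more
        times = np.array([0.0, 0.1, 0.2, 0.1, 0.2, 0.9, 0.2, 0.9, 0.0])
        origin = em.localize_origin(_amap(times), layout3, graph=graph3)
        assert origin.channel_id == 8


class TestScenarioInvariants:
    def test_lesion_detour_delays_far_side(self, layout16, graph16):
        """A 3x3 lesion block between source and far edge strictly delays
        the far edge, and detection matches the geodesic oracle."""
        lesions = frozenset(
            int(16 * r + c) for r in (6, 7, 8) for c in (7, 8, 9)
        )
        src = int(16 * 7 + 0)  # middle of the left edge, lesion in the path
        base = em.focal_scenario(layout16, src)
        blocked = em.PropagationScenario(
            sources=base.sources, cv_m_per_s=base.cv_m_per_s,
            lesions=lesions, rate_bpm=base.rate_bpm, rhythm="focal",
        )
        t_base, _ = em.geodesic_activation_times(layout16, graph16, base)
        t_block, reach = em.geodesic_activation_times(layout16, graph16, blocked)
        far_edge = layout16.cols == 15
        shadow = far_edge & (np.abs(layout16.rows - 7) <= 1)
        assert np.all(t_block[shadow] > t_base[shadow])

        rec, truth = em.render_recording(
            layout16, blocked, duration_s=2.0, seed=4
        )
        rec = em.bandpass(rec)
        amap = em.detect_activation(rec, em.segment_beats(rec)[0])
        sample_ms = 1000.0 / rec.sample_rate
        ok = reach
        assert np.all(
            np.abs(amap.times_ms[ok] - truth.activation_ms[0][ok]) <= sample_ms + 1e-9
        )

    def test_ischemic_slowing_is_local_and_monotone(self, layout16, graph16):
        """Halving CV inside a zone delays that zone but not the early
        channels on the source side."""
        center = layout16.positions[layout16.index_of(16 * 7 + 11)]
        cv_base = em.sinus_scenario(layout16, cv_m_per_s=1.0)
        cv_slow = em.slow_zone_cv(layout16, 1.0, center, radius_mm=8.0, factor=0.5)
        slow = em.sinus_scenario(layout16, cv_m_per_s=cv_slow)
        t0, _ = em.geodesic_activation_times(layout16, graph16, cv_base)
        t1, _ = em.geodesic_activation_times(layout16, graph16, slow)
        zone = np.linalg.norm(layout16.positions - center, axis=1) <= 8.0
        early = layout16.cols <= 2
        assert np.all(t1[zone] > t0[zone])
        assert np.allclose(t1[early], t0[early])
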