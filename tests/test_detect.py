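import numpy as np
import pytest

from stripekin.stack_io import FrameSeries
from stripekin.detect import (
    NucleusROI, IntensityTrace, segment_nuclei, detect_damage_site,
    make_background_ring, measure_trace, classify_recruitment, compute_fold_change,
)
from stripekin.kinetics import TraceModel
from stripekin.simulate import simulate_trace, default_timebase


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


class TestSegmentNuclei:
    def test_all_zero_frame_yields_empty_list(self):
        assert segment_nuclei(np.zeros((64, 64))) == []

    def test_two_disks_found_at_generated_centers(self):
        frame = np.full((128, 128), 100.0)
        centers = [(40, 35), (90, 95)]
        for c in centers:
            frame[disk_mask(frame.shape, c, 20)] = 1000.0
        rois = segment_nuclei(frame, min_area_px=500)
        assert len(rois) == 2
        found = sorted(r.centroid for r in rois)
        for got, want in zip(found, sorted(centers)):
            assert np.hypot(got[0] - want[0], got[1] - want[1]) < 2.0

    def test_border_touching_disk_excluded(self):
        frame = np.full((96, 96), 100.0)
        frame[disk_mask(frame.shape, (5, 48), 20)] = 1000.0
        assert segment_nuclei(frame, exclude_border=True) == []
        assert len(segment_nuclei(frame, exclude_border=False)) == 1


class TestBackgroundRing:
    def test_point_site_matches_brute_force_dilation(self):
        nucleus = np.ones((21, 21), bool)
        site = np.zeros((21, 21), bool)
        site[10, 10] = True
        ring = make_background_ring(site, nucleus, width_px=2)
        # oracle: Chebyshev distance <= 2 (8-connected dilation), minus the site
        yy, xx = np.mgrid[0:21, 0:21]
        oracle = (np.maximum(np.abs(yy - 10), np.abs(xx - 10)) <= 2) & ~site
        np.testing.assert_array_equal(ring, oracle)
        assert ring.sum() == 24

    def test_ring_clipped_at_nucleus_edge_stays_disjoint(self):
        nucleus = disk_mask((31, 31), (15, 15), 10)
        site = np.zeros((31, 31), bool)
        site[15, 24] = True  # adjacent to the nucleus boundary
        ring = make_background_ring(site, nucleus, width_px=2)
        assert ring.any()
        assert not (ring & site).any()
        assert not (ring & ~nucleus).any()

    def test_site_filling_nucleus_fails(self):
        nucleus = disk_mask((21, 21), (10, 10), 6)
        with pytest.raises(ValueError):
            make_background_ring(nucleus.copy(), nucleus)

    def test_site_outside_nucleus_rejected(self):
        nucleus = disk_mask((21, 21), (10, 10), 5)
        site = np.zeros((21, 21), bool)
        site[0, 0] = True
        with pytest.raises(ValueError):
            make_background_ring(site, nucleus)


def _series_with_stripe(gain=1.5, noise=0.0, seed=0, n_frames=12, irr=5.0):
    """Frames with one nucleus; stripe pixels brighten after irradiation."""
    rng = np.random.default_rng(seed)
    shape = (96, 96)
    nucleus = disk_mask(shape, (48, 48), 30)
    stripe = np.zeros(shape, bool)
    stripe[34:62, 46:49] = True  # ~28 px long, 3 px wide vertical stripe
    stripe &= nucleus
    t = np.arange(n_frames, dtype=float)
    frames = np.full((n_frames, *shape), 100.0)
    frames[:, nucleus] = 600.0
    post = t >= irr
    for i in np.where(post)[0]:
        f = frames[i]
        f[stripe] = 600.0 * gain
        frames[i] = f
    if noise:
        frames = frames + rng.normal(0, noise, frames.shape)
    roi = NucleusROI(label=1, mask=nucleus, centroid=(48.0, 48.0), area_px=int(nucleus.sum()))
    return FrameSeries(frames, t), roi, stripe


class TestDetectDamageSite:
    def test_no_intensity_change_yields_none(self):
        series, roi, _ = _series_with_stripe(gain=1.0, noise=2.0)
        assert detect_damage_site(series, roi, 5.0) is None

    def test_synthetic_stripe_recovered(self):
        series, roi, stripe = _series_with_stripe(gain=1.5, noise=5.0)
        site = detect_damage_site(series, roi, 5.0)
        assert site is not None
        overlap = (site.site_mask & stripe).sum() / stripe.sum()
        assert overlap >= 0.8
        assert not (site.site_mask & site.ring_mask).any()
        assert not (site.ring_mask & ~roi.mask).any()

    def test_elongated_component_preferred_over_blob(self):
        series, roi, stripe = _series_with_stripe(gain=1.5)
        blob = disk_mask(series.frames.shape[1:], (60, 62), 5) & roi.mask
        for i in range(5, series.n_frames):
            f = series.frames[i]
            f[blob] = 900.0
            series.frames[i] = f
        site = detect_damage_site(series, roi, 5.0)
        assert site is not None
        assert (site.site_mask & stripe).sum() > (site.site_mask & blob).sum()

    def test_insufficient_pre_frames_rejected(self):
        series, roi, _ = _series_with_stripe()
        with pytest.raises(ValueError):
            detect_damage_site(series, roi, irradiation_time_s=1.0)


class TestMeasureTrace:
    def _series(self, site_value, ring_value, n=10):
        shape = (32, 32)
        nucleus = disk_mask(shape, (16, 16), 12)
        site = np.zeros(shape, bool)
        site[14:19, 15:18] = True
        ring = make_background_ring(site, nucleus)
        frames = np.full((n, *shape), 50.0)
        frames[:, site] = site_value
        frames[:, ring] = ring_value
        from stripekin.detect import DamageSiteROI
        roi = DamageSiteROI(nucleus_label=1, site_mask=site, ring_mask=ring)
        return FrameSeries(frames, np.arange(float(n))), roi

    def test_identical_site_and_ring_cancel(self):
        series, roi = self._series(120.0, 120.0)
        trace = measure_trace(series, roi, irradiation_time_s=5.0)
        np.testing.assert_allclose(trace.corrected, 0.0, atol=1e-12)
        np.testing.assert_allclose(trace.normalized, 0.0, atol=1e-12)

    def test_constant_offset_removed_by_normalization(self):
        series, roi = self._series(200.0, 150.0)
        trace = measure_trace(series, roi, irradiation_time_s=5.0)
        np.testing.assert_allclose(trace.corrected, 50.0)
        np.testing.assert_allclose(trace.normalized, 0.0, atol=1e-12)

    def test_no_pre_irradiation_frames_rejected(self):
        series, roi = self._series(100.0, 100.0)
        with pytest.raises(ValueError):
            measure_trace(series, roi, irradiation_time_s=-1.0)

    def test_pre_irradiation_mean_of_normalized_is_zero(self, timebase):
        model = TraceModel(delta_max=1.0, k_on=0.05, k_off=0.01, tB=23.0, tD=150.0)
        trace = simulate_trace(model, timebase, 0.05, seed=9)
        pre = trace.pre_mask
        assert abs(trace.normalized[pre].mean()) < 1e-9


class TestClassifyRecruitment:
    def _noise_trace(self, sigma=1.0, seed=0, signal=None):
        t = default_timebase()
        rng = np.random.default_rng(seed)
        ring = np.full_like(t, 100.0)
        site = 150.0 + rng.normal(0, sigma, t.shape)
        if signal is not None:
            site = site + signal(t)
        corrected = site - ring
        pre = t < 10.0
        return IntensityTrace(t, site, ring, corrected,
                              corrected - corrected[pre].mean(), 10.0)

    def test_pure_noise_not_recruiting(self):
        assert classify_recruitment(self._noise_trace()) is False

    def test_large_sustained_step_recruiting(self):
        # 30 sigma and 20% fold change: passes both classifier gates
        step = lambda t: 30.0 * (t >= 20.0)
        assert classify_recruitment(self._noise_trace(signal=step)) is True

    def test_high_sigma_but_tiny_fold_change_rejected(self):
        step = lambda t: 10.0 * (t >= 20.0)  # 10 sigma yet fold change 10/150 < 0.1
        assert classify_recruitment(self._noise_trace(signal=step)) is False

    def test_single_frame_spike_rejected_by_consecutive_rule(self):
        t = default_timebase()
        spike_time = t[30]
        spike = lambda tt: 10.0 * (tt == spike_time)
        assert classify_recruitment(self._noise_trace(signal=spike)) is False

    def test_offset_invariance_and_gain_equivariance(self):
        trace = self._noise_trace(signal=lambda t: 10.0 * (t >= 20.0))
        shifted = IntensityTrace(trace.timestamps, trace.site_mean + 500,
                                 trace.ring_mean + 500, trace.corrected,
                                 trace.normalized, trace.irradiation_time_s)
        np.testing.assert_allclose(
            shifted.site_mean - shifted.ring_mean, trace.corrected)
        g = 2.5
        scaled_site = trace.site_mean * g
        scaled_ring = trace.ring_mean * g
        corr = scaled_site - scaled_ring
        pre = trace.pre_mask
        scaled = IntensityTrace(trace.timestamps, scaled_site, scaled_ring, corr,
                                corr - corr[pre].mean(), trace.irradiation_time_s)
        np.testing.assert_allclose(scaled.normalized, g * trace.normalized, atol=1e-9)
        assert compute_fold_change(scaled) == pytest.approx(compute_fold_change(trace))
        assert classify_recruitment(scaled) == classify_recruitment(trace)


class TestFoldChange:
    def test_formula(self):
        t = np.arange(10.0)
        site = np.full(10, 100.0)
        site[6:] = 250.0
        trace = IntensityTrace(t, site, np.zeros(10), site, site - 100.0, 5.0)
        assert compute_fold_change(trace) == pytest.approx(1.5)

    def test_no_recruitment_gives_zero(self):
        t = np.arange(10.0)
        site = np.full(10, 100.0)
        trace = IntensityTrace(t, site, np.zeros(10), site, site - 100.0, 5.0)
        assert compute_fold_change(trace) == pytest.approx(0.0)
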