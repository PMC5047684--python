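"""Spark pipeline: normalization, detection, morphometry, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calcimetry.simulate import LineScanSimConfig, generate_linescan
from calcimetry.sparks import (LineScanImage, NormalizationError,
                               SparkDetectionConfig, SparkEvent,
                               detect_sparks, exclude_transient_regions,
                               fdhm_amplitude_r2, measure_spark,
                               normalize_linescan, spark_frequency,
                               summarize_sparks)

from _oracles import brute_force_spark_regions
from conftest import make_single_spark_image


class TestNormalize:
    def test_constant_image_normalizes_to_zero(self):
        img = LineScanImage(np.full((10, 40), 50.0), 0.155, 500.0)
        norm = normalize_linescan(img)
        np.testing.assert_allclose(norm.dff0, 0.0)
        assert norm.background_sd == 0.0

    def test_single_hot_pixel(self):
        values = np.full((10, 40), 50.0)
        values[4, 20] = 100.0
        norm = normalize_linescan(LineScanImage(values, 0.155, 500.0))
        assert norm.dff0[4, 20] == pytest.approx(1.0)

    def test_zero_baseline_raises_with_positions(self):
        values = np.full((5, 20), 10.0)
        values[2, :] = 0.0
        with pytest.raises(NormalizationError, match="2"):
            normalize_linescan(LineScanImage(values, 0.155, 500.0))

    def test_baseline_window_validated(self):
        img = LineScanImage(np.full((5, 20), 10.0), 0.155, 500.0)
        with pytest.raises(ValueError):
            normalize_linescan(img, baseline_window=(10, 50))

    def test_noise_free_simulated_amplitude_recovered(self):
        cfg = LineScanSimConfig(spark_rate=3.0, noise_sd=0.0, duration_s=2.0,
                                seed=21)
        img, truth = generate_linescan(cfg)
        norm = normalize_linescan(img)
        planted = max(e.amplitude for e in truth.of_kind("spark"))
        assert norm.dff0.max() == pytest.approx(planted, rel=0.01)


class TestMask:
    def test_no_transients_leaves_mask_full(self, single_spark_norm):
        out = exclude_transient_regions(single_spark_norm, [])
        assert out.analyzed_mask.all()

    def test_full_mask_gives_empty_detection_and_missing_frequency(
            self, single_spark_norm):
        out = exclude_transient_regions(
            single_spark_norm, [(0.0, 10.0)])
        assert not out.analyzed_mask.any()
        assert detect_sparks(out) == []
        assert spark_frequency([], out) is None

    def test_masked_spark_not_detected(self, single_spark_norm):
        # the fixture's spark peaks at 200 ms
        assert len(detect_sparks(single_spark_norm)) == 1
        out = exclude_transient_regions(single_spark_norm, [(0.1, 0.4)])
        assert detect_sparks(out) == []

    def test_no_event_peak_in_masked_pixels(self):
        cfg = LineScanSimConfig(spark_rate=8.0, noise_sd=0.05, duration_s=2.0,
                                seed=13)
        img, _ = generate_linescan(cfg)
        norm = exclude_transient_regions(normalize_linescan(img),
                                         [(0.5, 0.9), (1.4, 1.6)])
        for c in detect_sparks(norm):
            assert norm.analyzed_mask[c.peak_ix, c.peak_it]


class TestDetect:
    def test_single_planted_spark_one_candidate(self, single_spark_norm):
        cands = detect_sparks(single_spark_norm)
        assert len(cands) == 1
        assert cands[0].peak_it == pytest.approx(100, abs=2)

    def test_two_separated_sparks_two_candidates(self):
        img1 = make_single_spark_image(peak_ms=150.0).values
        img2 = make_single_spark_image(peak_ms=700.0).values
        both = LineScanImage(img1 + img2 - 100.0, 0.155, 500.0)
        norm = normalize_linescan(both, baseline_window=(0, 40))
        assert len(detect_sparks(norm)) == 2

    def test_criteria_monotonicity(self):
        cfg = LineScanSimConfig(spark_rate=6.0, noise_sd=0.08, duration_s=2.0,
                                seed=17)
        img, _ = generate_linescan(cfg)
        norm = normalize_linescan(img)
        counts = [len(detect_sparks(norm, SparkDetectionConfig(criteria=c)))
                  for c in (2.0, 3.0, 3.8, 5.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_oracle_on_small_images(self):
        cfg_det = SparkDetectionConfig()
        rng = np.random.default_rng(0)
        for rep in range(8):
            dff0 = rng.normal(0.0, 0.1, size=(40, 120))
            # plant a couple of blobs
            for _ in range(2):
                i, j = rng.integers(8, 32), rng.integers(20, 100)
                dff0[i - 2:i + 3, j - 4:j + 5] += rng.uniform(0.5, 1.0)
            norm = normalize_linescan(
                LineScanImage(100.0 * (1 + dff0), 0.155, 500.0))
            got = [(c.peak_ix, c.peak_it, c.area_px)
                   for c in detect_sparks(norm, cfg_det)]
            thr = norm.background_mean + cfg_det.criteria * norm.background_sd
            want = brute_force_spark_regions(
                norm.dff0, norm.analyzed_mask, thr, cfg_det.min_area_px,
                cfg_det.merge_gap_px, cfg_det.smooth_px)
            assert got == want


class TestMeasure:
    def test_gaussian_fwhm_recovered(self):
        sigma = 1.0
        img = make_single_spark_image(fwhm_um=2.355 * sigma)
        norm = normalize_linescan(img, baseline_window=(0, 50))
        (cand,) = detect_sparks(norm)
        ev = measure_spark(norm, cand)
        assert ev.fwhm_um == pytest.approx(2.355, abs=norm.pixel_size_um)

    def test_triangular_profile_fdhm_is_crossing_distance(self):
        # temporal profile crossing half-max at 10 ms and 40 ms -> 30 ms
        def tri(t_ms):
            up = np.clip(t_ms - 180.0, 0, 20) / 20.0
            down = 1.0 - np.clip(t_ms - 200.0, 0, 40) / 40.0
            return np.where(t_ms < 200.0, up, np.clip(down, 0, 1))

        img = make_single_spark_image(temporal_profile=tri)
        norm = normalize_linescan(img, baseline_window=(0, 50))
        (cand,) = detect_sparks(norm)
        ev = measure_spark(norm, cand)
        assert ev.fdhm_ms == pytest.approx(30.0, abs=3.0)

    def test_amplitude_is_peak_dff0(self, single_spark_norm):
        (cand,) = detect_sparks(single_spark_norm)
        ev = measure_spark(single_spark_norm, cand)
        assert ev.amplitude == pytest.approx(0.8, rel=0.02)

    def test_edge_spark_flagged_truncated(self):
        img = make_single_spark_image(peak_ms=2.0)  # rises at the very edge
        norm = normalize_linescan(img, baseline_window=(300, 500))
        cands = detect_sparks(norm)
        assert cands
        ev = measure_spark(norm, cands[0])
        assert ev.truncated
        assert math.isnan(ev.fdhm_ms)


class TestFrequency:
    def _norm(self, scan_length_um, duration_s):
        ns = int(round(scan_length_um / 0.1))
        nt = int(round(duration_s * 500))
        img = LineScanImage(np.full((ns, nt), 10.0), 0.1, 500.0)
        return normalize_linescan(img)

    @pytest.mark.parametrize("n_events,scan,dur,expected", [
        (5, 50.0, 2.0, 5.0),
        (0, 50.0, 2.0, 0.0),
        (10, 100.0, 10.0, 1.0),
    ])
    def test_frequency_formula(self, n_events, scan, dur, expected):
        norm = self._norm(scan, dur)
        events = [SparkEvent(0, 0, 1.0, 1.0, 1.0)] * n_events
        assert spark_frequency(events, norm) == pytest.approx(expected)


class TestSummary:
    def _events(self, rng, n, fdhm_mean=30.0):
        return [SparkEvent(0.0, 0.0,
                           amplitude=rng.normal(0.6, 0.1),
                           fwhm_um=rng.normal(2.0, 0.3),
                           fdhm_ms=rng.normal(fdhm_mean, 5.0))
                for _ in range(n)]

    def test_kde_integrates_to_one(self, single_spark_norm):
        rng = np.random.default_rng(0)
        summ = summarize_sparks(self._events(rng, 50), single_spark_norm)
        for name, kde in summ.kde.items():
            integral = np.trapezoid(kde["density"], kde["grid"])
            assert integral == pytest.approx(1.0, abs=1e-6)

    def test_single_event_kde_is_kernel_at_value(self, single_spark_norm):
        ev = SparkEvent(1.0, 10.0, amplitude=0.7, fwhm_um=2.0, fdhm_ms=30.0)
        summ = summarize_sparks([ev], single_spark_norm)
        kde = summ.kde["fdhm_ms"]
        assert kde["grid"][np.argmax(kde["density"])] == pytest.approx(
            30.0, abs=np.diff(kde["grid"])[0])

    def test_mean_recovery_over_measured_sparks(self):
        # planted FDHM mean recovered within 3 standard errors
        fdhms = []
        seed = 0
        while len(fdhms) < 200:
            cfg = LineScanSimConfig(spark_rate=6.0, noise_sd=0.08,
                                    duration_s=2.0, spark_fdhm_ms_mean=30.0,
                                    spark_fdhm_ms_sd=5.0, seed=seed)
            img, _ = generate_linescan(cfg)
            norm = normalize_linescan(img)
            for c in detect_sparks(norm):
                ev = measure_spark(norm, c)
                if not ev.truncated:
                    fdhms.append(ev.fdhm_ms)
            seed += 1
        fdhms = np.array(fdhms)
        se = fdhms.std(ddof=1) / math.sqrt(fdhms.size)
        # allow the measurement bias budget on top of sampling error
        assert abs(fdhms.mean() - 30.0) < 3 * se + 0.1 * 30.0

    def test_truncated_events_excluded_from_width_summaries(
            self, single_spark_norm):
        evs = [SparkEvent(0, 0, 0.5, 2.0, 30.0),
               SparkEvent(0, 0, 0.9, math.nan, math.nan, truncated=True)]
        summ = summarize_sparks(evs, single_spark_norm)
        assert summ.n_events == 2
        assert summ.stats["fdhm_ms"]["n"] == 1
        assert summ.stats["amplitude"]["n"] == 2


class TestFdhmAmplitudeR2:
    def test_exact_linear_relation(self):
        evs = [SparkEvent(0, 0, a, 2.0, 10.0 + 20.0 * a)
               for a in (0.2, 0.4, 0.6, 0.8)]
        assert fdhm_amplitude_r2(evs) == pytest.approx(1.0)

    def test_independent_parameters_give_weak_r2(self):
        rng = np.random.default_rng(1)
        evs = [SparkEvent(0, 0, rng.normal(0.6, 0.1), 2.0,
                          rng.normal(30.0, 5.0)) for _ in range(500)]
        assert fdhm_amplitude_r2(evs) < 0.05

    def test_too_few_events_raise(self):
        evs = [SparkEvent(0, 0, 0.5, 2.0, 30.0)] * 2
        with pytest.raises(ValueError):
            fdhm_amplitude_r2(evs)

    def test_zero_amplitude_variance_missing(self):
        evs = [SparkEvent(0, 0, 0.5, 2.0, 10.0 * k) for k in range(1, 5)]
        assert fdhm_amplitude_r2(evs) is None


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.floats(min_value=4.0, max_value=8.0))
def test_raising_criteria_never_adds_events(criteria):
    cfg = LineScanSimConfig(spark_rate=6.0, noise_sd=0.08, duration_s=1.0,
                            scan_length_um=20.0, seed=23)
    img, _ = generate_linescan(cfg)
    norm = normalize_linescan(img)
    lo = len(detect_sparks(norm, SparkDetectionConfig(criteria=criteria)))
    hi = len(detect_sparks(norm,
                           SparkDetectionConfig(criteria=criteria + 0.5)))
    assert hi <= lo
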