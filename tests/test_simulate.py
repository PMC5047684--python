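"""Generator contracts: determinism, planted truth, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from calcimetry.simulate import (ConfigurationError, FieldPotentialSimParams,
                                 LeakLoadSimParams, LineScanSimConfig,
                                 generate_ct_table, generate_field_potential,
                                 generate_leakload_trace, generate_linescan,
                                 spark_decay_tau, spark_temporal_profile)


class TestLineScan:
    def test_seeded_determinism(self):
        cfg = LineScanSimConfig(spark_rate=5.0, transient_rate_hz=0.5,
                                wave_rate_per_s=0.2, duration_s=3.0, seed=7)
        img1, t1 = generate_linescan(cfg)
        img2, t2 = generate_linescan(cfg)
        np.testing.assert_array_equal(img1.values, img2.values)
        assert t1.events == t2.events

    def test_null_process_constant_baseline(self, quiet_config):
        img, truth = generate_linescan(quiet_config)
        assert truth.events == []
        np.testing.assert_allclose(img.values, quiet_config.baseline_f0)

    def test_noise_free_peak_matches_planted_amplitude(self):
        # rendered peak vs closed-form kernel value at the truth location
        cfg = LineScanSimConfig(spark_rate=8.0, noise_sd=0.0, duration_s=2.0,
                                seed=11)
        img, truth = generate_linescan(cfg)
        sparks = truth.of_kind("spark")
        assert sparks, "expected at least one planted spark"
        dff0 = img.values / cfg.baseline_f0 - 1.0
        for e in sparks:
            ix = int(round(e.position_um / cfg.pixel_size_um))
            it = int(round(e.peak_time_s * cfg.line_rate_hz))
            # tolerate overlap with a neighbouring spark's tail
            assert dff0[ix, it] >= e.amplitude * 0.99
            lone = all(abs(o.peak_time_s - e.peak_time_s) > 0.3 or o is e
                       for o in sparks)
            if lone:
                assert dff0[ix, it] == pytest.approx(e.amplitude, rel=0.01)

    def test_events_inside_extent_and_sorted(self):
        cfg = LineScanSimConfig(spark_rate=6.0, transient_rate_hz=0.5,
                                wave_rate_per_s=0.3, duration_s=4.0, seed=5)
        _, truth = generate_linescan(cfg)
        times = [e.time_s for e in truth.events]
        assert times == sorted(times)
        for e in truth.events:
            assert 0.0 <= e.time_s <= cfg.duration_s
            if math.isfinite(e.position_um):
                assert 0.0 <= e.position_um <= cfg.scan_length_um

    def test_spark_rate_calibration(self):
        # mean planted count over replicates ~ rate * (L/100) * T
        cfg0 = LineScanSimConfig(scan_length_um=30.0, duration_s=1.0,
                                 spark_rate=8.0, noise_sd=0.0)
        expected = 8.0 * 0.3 * 1.0
        counts = []
        for seed in range(120):
            _, truth = generate_linescan(
                LineScanSimConfig(**{**cfg0.__dict__, "seed": seed}))
            counts.append(len(truth.of_kind("spark")))
        counts = np.array(counts)
        se = counts.std(ddof=1) / math.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * se + 1e-9

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_linescan(LineScanSimConfig(scan_length_um=-1.0))
        with pytest.raises(ConfigurationError):
            generate_linescan(LineScanSimConfig(spark_rate=-2.0))

    def test_decay_tau_gives_planted_fdhm(self):
        # half-max width of the closed-form kernel equals the requested FDHM
        t = np.linspace(0.0, 500.0, 200001)
        for fdhm in (15.0, 30.0, 80.0):
            prof = spark_temporal_profile(t, 0.0, fdhm, rise_ms=5.0)
            above = t[prof >= 0.5]
            assert above[-1] - above[0] == pytest.approx(fdhm, abs=0.02)


class TestLeakLoad:
    def test_paced_peaks_at_planted_amplitude(self):
        p = LeakLoadSimParams(transient_amplitude_true=2.0, f0_diastolic=1.0,
                              noise_sd=0.0)
        trace, seg, _ = generate_leakload_trace(p)
        w = trace.window(*seg["paced_nt"])
        assert trace.value[w].max() == pytest.approx(3.0, rel=1e-9)
        assert trace.value[w].min() == pytest.approx(1.0, rel=1e-9)

    def test_tetracaine_minimum_is_planted_leak(self):
        p = LeakLoadSimParams(leak_true=0.2, noise_sd=0.0)
        trace, seg, _ = generate_leakload_trace(p)
        w = trace.window(*seg["tetracaine"])
        assert trace.value[w].min() == pytest.approx(0.8, rel=1e-9)

    def test_caffeine_peak_is_planted_load(self):
        p = LeakLoadSimParams(leak_true=0.2, load_true=3.0, noise_sd=0.0)
        trace, seg, _ = generate_leakload_trace(p)
        w = trace.window(*seg["caffeine"])
        assert trace.value[w].max() == pytest.approx(0.8 * 4.0, rel=1e-9)

    def test_oscillations_only_before_tetracaine(self):
        p = LeakLoadSimParams(oscillation_rate=0.5, seed=3)
        _, seg, truth = generate_leakload_trace(p)
        t_tet = seg["tetracaine"][0]
        t_zero = seg["zero_na_ca"][0]
        assert truth.oscillations, "expected planted oscillations"
        for t0, _amp in truth.oscillations:
            assert t_zero < t0 < t_tet

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            LeakLoadSimParams(leak_true=1.2).validate()
        with pytest.raises(ConfigurationError):
            LeakLoadSimParams(load_true=0.0).validate()
        with pytest.raises(ConfigurationError):
            LeakLoadSimParams(pacing_duration_s=5.0).validate()
        with pytest.raises(ConfigurationError):
            LeakLoadSimParams(phase_durations=(0.0, 10.0, 10.0)).validate()


class TestFieldPotential:
    def test_zero_jitter_gives_equal_intervals(self):
        p = FieldPotentialSimParams(bp_jitter_cv=0.0, noise_sd=0.0, seed=0)
        _, truth = generate_field_potential(p)
        np.testing.assert_allclose(np.diff(truth.spike_times_s), 1.0)

    def test_no_dads_when_probability_zero(self):
        p = FieldPotentialSimParams(dad_probability=0.0, seed=1)
        _, truth = generate_field_potential(p)
        assert not truth.dad_beats.any()
        assert truth.dad_times_s.size == 0

    def test_exact_beat_count(self):
        p = FieldPotentialSimParams(n_beats=60, seed=2)
        _, truth = generate_field_potential(p)
        assert truth.spike_times_s.size == 60

    def test_realized_cv_matches_target(self):
        # realized beat-period CV over replicates brackets the target
        target = 10.0
        cvs = []
        for seed in range(50):
            p = FieldPotentialSimParams(bp_jitter_cv=target, n_beats=60,
                                        noise_sd=0.0, seed=seed)
            _, truth = generate_field_potential(p)
            bp = truth.beat_periods_s
            cvs.append(100.0 * bp.std(ddof=1) / bp.mean())
        cvs = np.array(cvs)
        se = cvs.std(ddof=1) / math.sqrt(cvs.size)
        assert abs(cvs.mean() - target) < 3 * se + 0.1

    def test_dad_amplitude_below_spike(self):
        p = FieldPotentialSimParams(dad_probability=1.0,
                                    dad_amplitude_fraction=0.3, noise_sd=0.0,
                                    seed=4)
        fp, truth = generate_field_potential(p)
        for td in truth.dad_times_s:
            i = np.argmin(np.abs(fp.time_s - td))
            assert abs(fp.voltage[i]) < 0.5 * p.spike_amplitude


class TestCtTable:
    GENES = ["GAPDH", "RYR2", "CACNA1C", "MYH6"]
    SAMPLES = ["ctrl_1", "ctrl_2", "cpvt_1"]

    def test_planted_offsets(self):
        df = generate_ct_table(self.GENES, self.SAMPLES, "GAPDH",
                               {"RYR2": -5.0, "MYH6": 2.0}, seed=0)
        wide = df.pivot(index="sample", columns="gene", values="ct")
        np.testing.assert_allclose(wide["RYR2"] - wide["GAPDH"], 5.0)
        np.testing.assert_allclose(wide["MYH6"] - wide["GAPDH"], -2.0)
        np.testing.assert_allclose(wide["GAPDH"] - wide["GAPDH"], 0.0)

    def test_seeded_rerun_identical(self):
        a = generate_ct_table(self.GENES, self.SAMPLES, "GAPDH", {}, seed=9)
        b = generate_ct_table(self.GENES, self.SAMPLES, "GAPDH", {}, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_reference_must_be_listed(self):
        with pytest.raises(ConfigurationError):
            generate_ct_table(["RYR2"], self.SAMPLES, "GAPDH", {}, seed=0)
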