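import numpy as np
import pytest

from calcimetry.simulate import (LeakLoadSimParams, LineScanSimConfig,
                                 generate_leakload_trace, generate_linescan,
                                 spark_spatial_profile, spark_temporal_profile)
from calcimetry.sparks import LineScanImage, normalize_linescan


@pytest.fixture
def quiet_config():
    """Noise-free, event-free line-scan configuration."""
    return LineScanSimConfig(scan_length_um=20.0, duration_s=1.0,
                             noise_sd=0.0, seed=0)


def make_single_spark_image(amplitude=0.8, fwhm_um=2.0, fdhm_ms=30.0,
                            center_um=10.0, peak_ms=200.0,
                            scan_length_um=20.0, duration_s=1.0,
                            pixel_size_um=0.155, line_rate_hz=500.0,
                            rise_ms=5.0, baseline=100.0,
                            temporal_profile=None):
    """Noise-free separable spark rendered directly from the closed-form
    kernel (independent of the simulator's event machinery)."""
    ns = int(round(scan_length_um / pixel_size_um))
    nt = int(round(duration_s * line_rate_hz))
    x = np.arange(ns) * pixel_size_um
    t = np.arange(nt) * 1000.0 / line_rate_hz
    if temporal_profile is None:
        temporal = spark_temporal_profile(t, peak_ms - rise_ms, fdhm_ms,
                                          rise_ms)
    else:
        temporal = temporal_profile(t)
    dff0 = amplitude * np.outer(spark_spatial_profile(x, center_um, fwhm_um),
                                temporal)
    return LineScanImage(values=baseline * (1.0 + dff0),
                         pixel_size_um=pixel_size_um,
                         line_rate_hz=line_rate_hz)


@pytest.fixture
def single_spark_norm():
    img = make_single_spark_image()
    return normalize_linescan(img, baseline_window=(0, 50))


@pytest.fixture
def leakload_noise_free():
    p = LeakLoadSimParams(transient_amplitude_true=2.0, leak_true=0.2,
                          load_true=3.0, noise_sd=0.0, seed=1)
    return (p,) + generate_leakload_trace(p)


def phase_annotations(seg):
    """Simulator phase intervals -> switch-time annotations."""
    return {k: v[0] for k, v in seg.intervals.items() if k != "paced_nt"}
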