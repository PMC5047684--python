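"""Extracellular field-potential annotation and rhythm metrics.

Multielectrode-array recordings of spontaneously beating cardiomyocyte
aggregates show sharp depolarization spikes followed by a repolarization
T-wave.  Per beat: beat period (BP, seconds between successive spikes),
field-potential duration (FPD, ms from spike to T-wave) and its Fridericia
rate-corrected value FPDcF = FPD / BP^(1/3) (BP in seconds).  Delayed
afterdepolarizations (DADs) are low-amplitude deflections after
repolarization completes, i.e. in the diastolic window between T-wave and
next spike.  Beat-to-beat variability is summarized by modified Poincaré
pairs (value at beat n-1 vs beat n) and the coefficient of variation
CV = 100 * s.d. / mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "FPTrace",
    "SpikeDetectConfig",
    "FpdConfig",
    "DadConfig",
    "BeatSeries",
    "RhythmSummary",
    "detect_spikes",
    "measure_fpd",
    "fridericia_correct",
    "detect_dads",
    "poincare_pairs",
    "coefficient_of_variation",
    "analyze_field_potential",
]


@dataclass
class FPTrace:
    time_s: np.ndarray
    voltage: np.ndarray          # uV
    sampling_hz: float

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time_s.shape != self.voltage.shape or self.time_s.ndim != 1:
            raise ValueError("time and voltage must be 1-D of equal length")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage must be finite")
        if self.time_s.size >= 2:
            dt = np.median(np.diff(self.time_s))
            if abs(dt * self.sampling_hz - 1.0) > 0.01:
                raise ValueError("sampling_hz inconsistent with time grid")


@dataclass(frozen=True)
class SpikeDetectConfig:
    k_noise_sd: float = 8.0          # threshold in robust-noise-SD units
    refractory_ms: float = 200.0
    relative_floor: float = 0.5      # of the largest |v| peak


@dataclass(frozen=True)
class FpdConfig:
    search_start_ms: float = 100.0   # after the spike
    search_end_bp_fraction: float = 0.8
    smooth_ms: float = 5.0
    # floor for the T-wave extremum, in smoothed-noise SDs; the maximum of
    # |noise| over a ~0.5 s search window reaches ~3.5 SD, so the floor must
    # sit above that to flag truly T-wave-free beats
    min_twave_sd: float = 5.0


@dataclass(frozen=True)
class DadConfig:
    a_min: float = 0.05              # amplitude band, fraction of spike amp
    a_max: float = 0.5
    margin_ms: float = 50.0
    smooth_ms: float = 5.0


@dataclass
class BeatSeries:
    """Per-beat annotations; arrays share beat order, NaN where undefined."""

    spike_times_s: np.ndarray
    beat_periods_s: np.ndarray       # n-1 entries: BP_i = spike_{i+1} - spike_i
    twave_times_s: np.ndarray        # NaN where no T-wave found
    fpd_ms: np.ndarray
    fpdcf_ms: np.ndarray             # NaN for the first beat (no preceding BP)
    dad_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    dad_scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dad_times_s: list = field(default_factory=list)
    spike_amplitude: float = math.nan

    @property
    def n_beats(self) -> int:
        return int(self.spike_times_s.size)


@dataclass
class RhythmSummary:
    cv_bp_percent: Optional[float]
    cv_fpdcf_percent: Optional[float]
    poincare_bp: list                # [(bp_{n-1}, bp_n), ...] seconds
    poincare_fpdcf: list             # pairs in seconds
    dad_present: bool
    dad_count: int


def _robust_sd(v: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(v - np.median(v))))


def detect_spikes(fp: FPTrace,
                  cfg: SpikeDetectConfig = SpikeDetectConfig()) -> np.ndarray:
    """Depolarization spike times.

    Spikes are local extrema of |voltage| above ``k_noise_sd`` robust noise
    SDs, separated by the refractory period; an additional relative floor
    (fraction of the largest extremum) rejects T-waves and DADs, which can
    exceed the noise criterion but are fractions of the spike amplitude.
    """
    av = np.abs(fp.voltage)
    sd = _robust_sd(fp.voltage)
    height = cfg.k_noise_sd * sd
    if av.max() <= 0 or (height > 0 and av.max() < height):
        logger.info("detect_spikes: no spikes found")
        return np.zeros(0)
    height = max(height, cfg.relative_floor * float(av.max()))
    dist = max(1, int(round(cfg.refractory_ms / 1000.0 * fp.sampling_hz)))
    pk, _ = find_peaks(av, height=height, distance=dist)
    return fp.time_s[pk]


def measure_fpd(fp: FPTrace, spike_times: np.ndarray,
                cfg: FpdConfig = FpdConfig()
                ) -> tuple[np.ndarray, np.ndarray]:
    """T-wave times and FPD (ms) per beat.

    The T-wave is the largest extremum of the smoothed trace in a search
    window from ``search_start_ms`` after the spike to
    ``search_end_bp_fraction`` of the beat period (median BP for the last
    beat).  Beats with no extremum above the noise floor are flagged with
    NaN and excluded from FPD summaries.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n = spike_times.size
    if n < 1:
        raise ValueError("need at least one spike")
    k = max(1, int(round(cfg.smooth_ms / 1000.0 * fp.sampling_hz)))
    sm = uniform_filter1d(fp.voltage, k)
    floor = cfg.min_twave_sd * _robust_sd(sm)
    bps = np.diff(spike_times)
    med_bp = float(np.median(bps)) if bps.size else \
        float(fp.time_s[-1] - spike_times[-1])
    twave = np.full(n, math.nan)
    fpd = np.full(n, math.nan)
    for i, s in enumerate(spike_times):
        bp = bps[i] if i < bps.size else med_bp
        a = s + cfg.search_start_ms / 1000.0
        b = s + cfg.search_end_bp_fraction * bp
        w = (fp.time_s >= a) & (fp.time_s < b)
        if not w.any():
            continue
        seg = np.abs(sm[w])
        j = int(np.argmax(seg))
        if seg[j] <= floor:
            continue
        twave[i] = fp.time_s[w][j]
        fpd[i] = (twave[i] - s) * 1000.0
    return twave, fpd


def fridericia_correct(fpd_ms, bp_s):
    """Fridericia rate correction FPDcF = FPD / BP^(1/3), BP in seconds.

    Accepts scalars or arrays; NaN propagates (e.g. the first beat, which
    has no terminating beat period)."""
    fpd_ms = np.asarray(fpd_ms, dtype=float)
    bp_s = np.asarray(bp_s, dtype=float)
    if np.any(bp_s[np.isfinite(bp_s)] <= 0):
        raise ValueError("beat periods must be positive")
    out = fpd_ms / np.cbrt(bp_s)
    return float(out) if out.ndim == 0 else out


def detect_dads(fp: FPTrace, spike_times: np.ndarray, twave_times: np.ndarray,
                spike_amplitude: float, cfg: DadConfig = DadConfig()
                ) -> tuple[np.ndarray, np.ndarray, list]:
    """Flag beats with a delayed afterdepolarization.

    Within each diastolic window (T-wave + margin to next spike - margin),
    the largest smoothed |deflection| is scored as a fraction of the spike
    amplitude; beats with a score inside [a_min, a_max] are flagged (larger
    deflections are candidate ectopic spikes, not DADs).  Returns
    (flags, scores, dad_times).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n = spike_times.size
    k = max(1, int(round(cfg.smooth_ms / 1000.0 * fp.sampling_hz)))
    sm = uniform_filter1d(fp.voltage, k)
    flags = np.zeros(n, dtype=bool)
    scores = np.zeros(n)
    times: list[float] = []
    m = cfg.margin_ms / 1000.0
    for i in range(n):
        tw = twave_times[i]
        if not math.isfinite(tw):
            continue
        a = tw + m
        b = (spike_times[i + 1] - m) if i + 1 < n else fp.time_s[-1]
        w = (fp.time_s >= a) & (fp.time_s < b)
        if not w.any():
            continue
        seg = np.abs(sm[w])
        j = int(np.argmax(seg))
        scores[i] = seg[j] / spike_amplitude
        if cfg.a_min <= scores[i] <= cfg.a_max:
            flags[i] = True
            times.append(float(fp.time_s[w][j]))
    return flags, scores, times


def poincare_pairs(series: Sequence[float]) -> list[tuple[float, float]]:
    """Modified Poincaré pairs (x_{n-1}, x_n) for n = 2..N."""
    x = list(series)
    if len(x) < 2:
        raise ValueError("need at least 2 values for Poincaré pairs")
    return list(zip(x[:-1], x[1:]))


def coefficient_of_variation(series) -> Optional[float]:
    """CV in percent: 100 * sample s.d. (n-1 denominator) / mean.

    ``None`` when fewer than 2 finite values or the mean is zero."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return None
    m = float(np.mean(x))
    if m == 0:
        return None
    return 100.0 * float(np.std(x, ddof=1)) / m


def analyze_field_potential(fp: FPTrace,
                            spike_cfg: SpikeDetectConfig = SpikeDetectConfig(),
                            fpd_cfg: FpdConfig = FpdConfig(),
                            dad_cfg: DadConfig = DadConfig()
                            ) -> tuple[BeatSeries, RhythmSummary]:
    """Full annotation of one recording: spikes, T-waves, FPD/FPDcF, DADs,
    Poincaré pairs and CVs."""
    spikes = detect_spikes(fp, spike_cfg)
    if spikes.size == 0:
        empty = BeatSeries(spike_times_s=spikes,
                           beat_periods_s=np.zeros(0),
                           twave_times_s=np.zeros(0), fpd_ms=np.zeros(0),
                           fpdcf_ms=np.zeros(0))
        return empty, RhythmSummary(None, None, [], [], False, 0)
    idx = np.searchsorted(fp.time_s, spikes)
    spike_amp = float(np.median(np.abs(fp.voltage[idx])))
    twave, fpd = measure_fpd(fp, spikes, fpd_cfg)
    bps = np.diff(spikes)
    # per-beat FPDcF uses the beat period terminating at that beat
    bp_term = np.concatenate([[math.nan], bps])
    fpdcf = fridericia_correct(fpd, bp_term)
    flags, scores, dad_times = detect_dads(fp, spikes, twave, spike_amp,
                                           dad_cfg)
    beats = BeatSeries(spike_times_s=spikes, beat_periods_s=bps,
                       twave_times_s=twave, fpd_ms=fpd, fpdcf_ms=fpdcf,
                       dad_flags=flags, dad_scores=scores,
                       dad_times_s=dad_times, spike_amplitude=spike_amp)
    fpdcf_ok = fpdcf[np.isfinite(fpdcf)]
    summary = RhythmSummary(
        cv_bp_percent=coefficient_of_variation(bps),
        cv_fpdcf_percent=coefficient_of_variation(fpdcf_ok),
        poincare_bp=poincare_pairs(bps) if bps.size >= 2 else [],
        poincare_fpdcf=(poincare_pairs(fpdcf_ok / 1000.0)
                        if fpdcf_ok.size >= 2 else []),
        dad_present=bool(flags.any()), dad_count=int(flags.sum()))
    return beats, summary
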