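"""Transient segmentation, spontaneous Ca2+ wave detection and scan triage.

A line-scan from a spontaneously beating cardiomyocyte shows whole-line Ca2+
transients (the paced/spontaneous beats) separated by diastolic intervals.
Spontaneous Ca2+ waves (SCW) are diastolic supra-threshold release events
that traverse a substantial fraction of the scanned line: regional events
are "wavelets", whole-cell events "waves".  Each scan is triaged as
``normal`` (consistent transient amplitudes and beat periods, no waves),
``scw`` (at least one wave/wavelet) or ``other`` (irregular transients,
alternans, double peaks, plateau decay, or too few beats to judge).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .sparks import NormalizedLineScan, detection_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "Transient",
    "TransientSegmentation",
    "TransientSegConfig",
    "WaveDetectConfig",
    "WaveEvent",
    "ClassifyConfig",
    "ScanClassification",
    "segment_transients",
    "detect_waves",
    "classify_linescan",
    "wave_stats",
]


@dataclass
class Transient:
    onset_s: float
    peak_s: float
    amplitude: float                    # dF/F0 of the spatially averaged trace
    beat_period_s: Optional[float]      # to the next onset; None for the last
    n_subpeaks: int = 1
    duration_s: float = math.nan        # above-onset-level interval length


@dataclass
class TransientSegmentation:
    transients: list[Transient]
    diastolic_intervals: list[tuple[float, float]]
    trace: np.ndarray                   # spatially averaged dF/F0
    line_rate_hz: float

    @property
    def beat_periods(self) -> np.ndarray:
        return np.array([t.beat_period_s for t in self.transients
                         if t.beat_period_s is not None])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([t.amplitude for t in self.transients])

    @property
    def diastolic_duration_s(self) -> float:
        return float(sum(b - a for a, b in self.diastolic_intervals))


@dataclass(frozen=True)
class TransientSegConfig:
    peak_fraction: float = 0.5        # of the max whole-line amplitude
    min_separation_ms: float = 200.0
    onset_fraction: float = 0.05      # transient bounds at this fraction of peak
    margin_ms: float = 50.0           # pad around each transient
    min_amplitude_sd: float = 3.8     # absolute floor in background-SD units
    prominence_fraction: float = 0.25  # rejects shoulder bumps on decays
    subpeak_prominence_fraction: float = 0.3
    # a paced/spontaneous transient rises near-simultaneously along the whole
    # line; a propagating wave does not.  Candidates whose per-position peak
    # times disperse more than this are left to the wave detector.
    max_row_peak_spread_ms: float = 60.0


def _row_peak_spread_ms(norm: NormalizedLineScan, pk: int,
                        peaks: np.ndarray, dt_s: float,
                        halfwidth_s: float = 0.5) -> float:
    """Robust SD (1.4826*MAD, ms) of the per-row peak time around one
    whole-line candidate peak."""
    j = int(np.searchsorted(peaks, pk))
    lo = int(max(0, pk - halfwidth_s / dt_s))
    hi = int(min(norm.n_time, pk + halfwidth_s / dt_s))
    if j > 0:
        lo = max(lo, (peaks[j - 1] + pk) // 2)
    if j < peaks.size - 1:
        hi = min(hi, (pk + peaks[j + 1]) // 2)
    seg = norm.dff0[:, lo:hi]
    row_t = np.argmax(seg, axis=1).astype(float)
    med = np.median(row_t)
    return 1.4826 * float(np.median(np.abs(row_t - med))) * dt_s * 1000.0


def segment_transients(norm: NormalizedLineScan,
                       cfg: TransientSegConfig = TransientSegConfig()
                       ) -> TransientSegmentation:
    """Segment whole-line transients on the spatially averaged dF/F0 trace.

    Peaks must exceed both ``peak_fraction`` of the trace maximum and an
    absolute floor of ``min_amplitude_sd`` background SDs, carry a minimum
    prominence, and be separated by ``min_separation_ms``; a quiescent scan
    yields an empty segmentation.  Candidates whose per-position peak times
    spread more than ``max_row_peak_spread_ms`` (robust SD across rows) are
    propagating events, not whole-line transients, and are excluded here so
    the wave detector sees them.  Transient intervals extend to where the
    trace falls to ``onset_fraction`` of the peak, padded by ``margin_ms``;
    diastolic intervals are the complement.
    """
    trace = norm.dff0.mean(axis=0)
    dt_s = 1.0 / norm.line_rate_hz
    floor = norm.background_mean + cfg.min_amplitude_sd * norm.background_sd
    height = max(cfg.peak_fraction * float(trace.max()), floor)
    dist = max(1, int(round(cfg.min_separation_ms / 1000.0 / dt_s)))
    peaks, props = find_peaks(trace, height=height, distance=dist,
                              prominence=cfg.prominence_fraction
                              * max(float(trace.max()), 1e-12))
    if peaks.size:
        keep = np.array([
            _row_peak_spread_ms(norm, pk, peaks, dt_s) <=
            cfg.max_row_peak_spread_ms
            for pk in peaks])
        peaks = peaks[keep]
    if peaks.size == 0:
        logger.info("segment_transients: no transients found (quiescent scan)")
        return TransientSegmentation([], [(0.0, norm.n_time * dt_s)],
                                     trace, norm.line_rate_hz)

    transients: list[Transient] = []
    bounds: list[tuple[int, int]] = []
    for j, pk in enumerate(peaks):
        amp = float(trace[pk])
        lvl = cfg.onset_fraction * amp
        lo_lim = 0 if j == 0 else (peaks[j - 1] + pk) // 2
        hi_lim = norm.n_time - 1 if j == len(peaks) - 1 \
            else (pk + peaks[j + 1]) // 2
        lo = pk
        while lo > lo_lim and trace[lo - 1] > lvl:
            lo -= 1
        hi = pk
        while hi < hi_lim and trace[hi + 1] > lvl:
            hi += 1
        # double-peak check within the transient's own interval
        sub, _ = find_peaks(trace[lo:hi + 1],
                            prominence=cfg.subpeak_prominence_fraction * amp)
        bounds.append((lo, hi))
        transients.append(Transient(onset_s=lo * dt_s, peak_s=pk * dt_s,
                                    amplitude=amp, beat_period_s=None,
                                    n_subpeaks=max(1, int(sub.size)),
                                    duration_s=(hi - lo + 1) * dt_s))
    for j in range(len(transients) - 1):
        transients[j].beat_period_s = (transients[j + 1].onset_s
                                       - transients[j].onset_s)

    pad = cfg.margin_ms / 1000.0
    occupied = [(max(0.0, lo * dt_s - pad),
                 min(norm.n_time * dt_s, (hi + 1) * dt_s + pad))
                for lo, hi in bounds]
    diastole: list[tuple[float, float]] = []
    prev = 0.0
    for a, b in occupied:
        if a > prev:
            diastole.append((prev, a))
        prev = max(prev, b)
    if prev < norm.n_time * dt_s:
        diastole.append((prev, norm.n_time * dt_s))
    return TransientSegmentation(transients, diastole, trace,
                                 norm.line_rate_hz)


@dataclass(frozen=True)
class WaveDetectConfig:
    wave_criteria: float = 3.8          # threshold in background-SD units
    min_extent_fraction: float = 0.2    # below this, events are spark territory
    whole_cell_fraction: float = 0.9    # at/above: wave; below: wavelet
    smooth_px: int = 3
    min_area_px: int = 8


@dataclass
class WaveEvent:
    onset_s: float
    amplitude: float                    # peak dF/F0 within the event
    spatial_extent_fraction: float
    kind: str                           # "wave" | "wavelet"


def detect_waves(norm: NormalizedLineScan, seg: TransientSegmentation,
                 cfg: WaveDetectConfig = WaveDetectConfig()
                 ) -> list[WaveEvent]:
    """Detect diastolic waves/wavelets as supra-threshold connected regions
    whose spatial extent exceeds ``min_extent_fraction`` of the scan length.

    Only diastolic columns are searched, so no event overlaps a transient
    interval.  Extent is the fraction of scanned positions the region spans;
    at or above ``whole_cell_fraction`` the event is a whole-cell wave.
    """
    dt_s = 1.0 / norm.line_rate_hz
    col_mask = np.zeros(norm.n_time, dtype=bool)
    for a, b in seg.diastolic_intervals:
        col_mask[int(math.ceil(a / dt_s)):int(math.floor(b / dt_s)) + 1] = True
    sm = ndimage.uniform_filter(norm.dff0, size=cfg.smooth_px, mode="nearest")
    thr = detection_threshold(norm, cfg.wave_criteria)
    binary = (sm > thr) & norm.analyzed_mask & col_mask[None, :]
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=bool))
    out: list[WaveEvent] = []
    for k in range(1, n + 1):
        ix, it = np.nonzero(labels == k)
        if ix.size < cfg.min_area_px:
            continue
        extent = (ix.max() - ix.min() + 1) / norm.n_space
        if extent < cfg.min_extent_fraction:
            continue        # left to spark analysis
        kind = "wave" if extent >= cfg.whole_cell_fraction else "wavelet"
        out.append(WaveEvent(onset_s=float(it.min()) * dt_s,
                             amplitude=float(norm.dff0[ix, it].max()),
                             spatial_extent_fraction=float(extent), kind=kind))
    out.sort(key=lambda w: w.onset_s)
    return out


@dataclass(frozen=True)
class ClassifyConfig:
    amp_cv_tol: float = 0.25
    bp_cv_tol: float = 0.25
    alternans_depth: float = 0.15       # min fractional alternation to flag
    max_transient_duration_s: float = 1.2   # plateau-decay flag


@dataclass
class ScanClassification:
    label: str                          # "normal" | "scw" | "other"
    evidence: dict


def _cv(x: np.ndarray) -> float:
    if x.size < 2 or np.mean(x) == 0:
        return math.nan
    return float(np.std(x, ddof=1) / np.mean(x))


def _alternans_flag(amps: np.ndarray, depth: float) -> bool:
    """True when successive amplitudes alternate in sign of change with a
    mean fractional swing above ``depth``."""
    if amps.size < 4:
        return False
    d = np.diff(amps)
    if np.any(d == 0):
        return False
    signs = np.sign(d)
    alternating = np.all(signs[1:] != signs[:-1])
    swing = float(np.mean(np.abs(d)) / np.mean(amps))
    return bool(alternating and swing > depth)


def classify_linescan(seg: TransientSegmentation, waves: Sequence[WaveEvent],
                      cfg: ClassifyConfig = ClassifyConfig()
                      ) -> ScanClassification:
    """Triage one scan: SCW > other > normal.

    Any detected wave makes the scan SCW.  Otherwise the scan is ``other``
    when there are fewer than two transients, when the amplitude or
    beat-period CV exceeds its tolerance, or when a morphology flag fires
    (alternans, double-peaked transients, plateau decay); else ``normal``.
    """
    if len(waves) > 0:
        return ScanClassification("scw", {
            "n_waves": len(waves),
            "wave_kinds": sorted({w.kind for w in waves}),
        })
    amps = seg.amplitudes
    if len(seg.transients) < 2:
        return ScanClassification("other", {"reason": "insufficient beats",
                                            "n_transients": len(seg.transients)})
    bps = seg.beat_periods
    amp_cv = _cv(amps)
    bp_cv = _cv(bps) if bps.size >= 2 else 0.0
    flags = {
        "amplitude_cv": amp_cv,
        "beat_period_cv": bp_cv,
        "alternans": _alternans_flag(amps, cfg.alternans_depth),
        "double_peak": any(t.n_subpeaks > 1 for t in seg.transients),
        "plateau_decay": any(
            math.isfinite(t.duration_s)
            and t.duration_s > cfg.max_transient_duration_s
            for t in seg.transients),
    }
    abnormal = (amp_cv > cfg.amp_cv_tol
                or (not math.isnan(bp_cv) and bp_cv > cfg.bp_cv_tol)
                or flags["alternans"] or flags["double_peak"]
                or flags["plateau_decay"])
    return ScanClassification("other" if abnormal else "normal", flags)


def wave_stats(waves: Sequence[WaveEvent], analyzed_duration_s: float
               ) -> tuple[Optional[float], Optional[float]]:
    """(mean wave amplitude dF/F0, frequency in waves per second of analyzed
    diastolic time); both ``None`` when no waves were detected."""
    if analyzed_duration_s <= 0:
        raise ValueError("analyzed duration must be positive")
    if not waves:
        return None, None
    amps = [w.amplitude for w in waves]
    return float(np.mean(amps)), len(waves) / analyzed_duration_s
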