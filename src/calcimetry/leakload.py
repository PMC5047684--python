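"""Shannon-Bers SR Ca2+ leak/load quantification from whole-cell traces.

The protocol: pace at 1 Hz in normal Tyrode (NT) to steady state, switch to
0 Na+/0 Ca2+ Tyrode (transsarcolemmal fluxes abolished; spontaneous
oscillations may appear in leaky cells), add 1 mM tetracaine (RyR2 block;
the fluorescence drop estimates diastolic SR leak), then 30 mM caffeine
(SR store dumped; the evoked amplitude estimates SR load), then back to NT.

Defining ratios on the fluo-4 trace F(t):

* transient amplitude = dF_trans / F0,diastolic, dF_trans being peak minus
  diastolic minimum of the paced beats;
* leak = dF_tet / F0,diastolic, dF_tet being the drop from the diastolic
  level preceding tetracaine to the tetracaine minimum F0,leak;
* load = dF_caff / F0,leak, dF_caff being the caffeine peak minus F0,leak;
* fractional release = transient amplitude / load.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.ndimage import median_filter, uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceTrace",
    "PhaseSegmentation",
    "LeakLoadResult",
    "LeakWarning",
    "PHASE_ORDER",
    "segment_phases",
    "transient_amplitude",
    "sr_leak",
    "sr_load",
    "fractional_release",
    "detect_oscillations",
    "analyze_leakload",
]

PHASE_ORDER = ("paced_nt", "zero_na_ca", "tetracaine", "caffeine",
               "recovery_nt")


class LeakWarning(UserWarning):
    """Non-fatal protocol anomaly (e.g. no tetracaine drop)."""


@dataclass
class FluorescenceTrace:
    time_s: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.value.shape:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("trace values must be finite")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def window(self, a: float, b: float) -> np.ndarray:
        return (self.time_s >= a) & (self.time_s < b)


@dataclass
class PhaseSegmentation:
    """Half-open phase intervals keyed by phase name (paced_nt, zero_na_ca,
    tetracaine, caffeine, recovery_nt)."""

    intervals: dict

    def __post_init__(self):
        prev_end = None
        for name in PHASE_ORDER:
            if name not in self.intervals:
                continue
            a, b = self.intervals[name]
            if b <= a:
                raise ValueError(f"phase {name} has non-positive duration")
            if prev_end is not None and a < prev_end - 1e-9:
                raise ValueError("phase intervals overlap or are out of order")
            prev_end = b

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.intervals[name]

    def __contains__(self, name: str) -> bool:
        return name in self.intervals


@dataclass
class LeakLoadResult:
    """The four protocol statistics of one cell plus oscillation events."""

    transient_amplitude: float
    leak: float
    load: float
    fractional_release: float          # NaN when load == 0
    f0_diastolic: float
    f0_leak: float
    oscillations: list = field(default_factory=list)  # (time_s, dF/F0)
    leak_clamped: bool = False

    @property
    def n_oscillations(self) -> int:
        return len(self.oscillations)


def segment_phases(trace: FluorescenceTrace,
                   annotations: Optional[dict] = None) -> PhaseSegmentation:
    """Build the phase segmentation from switch-time annotations, or detect
    the phase boundaries from the trace when annotations are absent.

    ``annotations`` maps phase name to onset time for the four switches
    (zero_na_ca, tetracaine, caffeine, recovery_nt); paced_nt starts at the
    trace start.  Times must be strictly increasing and inside the trace.
    """
    t0, t1 = float(trace.time_s[0]), float(trace.time_s[-1])
    if annotations is not None:
        names = [n for n in PHASE_ORDER[1:] if n in annotations]
        times = [float(annotations[n]) for n in names]
        if names != list(PHASE_ORDER[1:]):
            raise ValueError(f"annotations must provide onsets for "
                             f"{PHASE_ORDER[1:]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("annotation times out of order")
        if times[0] <= t0 or times[-1] >= t1:
            raise ValueError("annotation times outside the trace")
        edges = [t0] + times + [t1]
        return PhaseSegmentation(intervals={
            name: (edges[i], edges[i + 1])
            for i, name in enumerate(PHASE_ORDER)})
    return _detect_phases(trace)


def _detect_phases(trace: FluorescenceTrace) -> PhaseSegmentation:
    """Fallback boundary detector.

    The tetracaine phase is located from the sustained negative deflection
    (trace minimum); its onset is the last departure from the pre-drop
    plateau.  The caffeine peak is the global maximum after the drop; the
    recovery onset is the first sustained rise after the caffeine transient
    has decayed.
    """
    t, v = trace.time_s, trace.value
    k = max(3, int(round(0.25 / trace.dt)) | 1)
    sm = median_filter(v, size=k, mode="nearest")
    i_min = int(np.argmin(sm))
    f_min = sm[i_min]

    # pre-drop diastolic plateau level: median over the second preceding the
    # departure; estimated iteratively from a coarse guess
    i_drop = i_min
    f0_guess = float(np.median(sm[max(0, i_min - int(5 / trace.dt)):i_min]
                               [:int(1 / trace.dt)])) if i_min > 10 else f_min
    lvl = f0_guess - 0.05 * (f0_guess - f_min)
    while i_drop > 0 and sm[i_drop] < lvl:
        i_drop -= 1
    t_tet = t[i_drop]

    after = slice(i_min, len(v))
    i_caff_pk = i_min + int(np.argmax(sm[after]))
    # caffeine onset: last time before the peak at ~the leak plateau
    lvl_c = f_min + 0.05 * (sm[i_caff_pk] - f_min)
    i_caff = i_caff_pk
    while i_caff > i_min and sm[i_caff - 1] > lvl_c:
        i_caff -= 1
    t_caff = t[i_caff]

    # recovery: first sustained rise after the caffeine decay
    d = np.diff(sm[i_caff_pk:])
    rise = np.flatnonzero(uniform_filter1d((d > 0).astype(float),
                                           max(3, int(0.2 / trace.dt))) > 0.9)
    # skip the caffeine upstroke itself: require the trace to have decayed
    t_rec = None
    for j in rise:
        idx = i_caff_pk + j
        if sm[idx] < f_min + 0.5 * (sm[i_caff_pk] - f_min):
            t_rec = t[idx]
            break
    if t_rec is None or t_rec >= t[-1]:
        t_rec = t[-1] - trace.dt

    # end of pacing: last paced peak + ~one beat period
    pre = trace.window(t[0], t_tet - 1.0)
    vp = v[pre]
    prom = max(3.0 * _noise_sd(vp), 0.05 * (vp.max() - vp.min())) \
        if vp.size else 1.0
    pk, _ = find_peaks(vp, prominence=prom,
                       distance=max(1, int(0.3 / trace.dt)))
    if pk.size:
        # ignore low-amplitude peaks (e.g. 0 Na+/0 Ca2+ oscillations) when
        # locating the end of pacing: paced transients dominate in height
        base = float(np.median(vp))
        keep = vp[pk] >= base + 0.6 * (vp[pk].max() - base)
        pk = pk[keep]
    if pk.size >= 2:
        bp = float(np.median(np.diff(t[pre][pk])))
        t_zero = float(t[pre][pk[-1]]) + 0.95 * bp
    elif pk.size == 1:
        t_zero = float(t[pre][pk[-1]]) + 1.0
    else:
        t_zero = t[0] + (t_tet - t[0]) / 2.0
    t_zero = min(t_zero, t_tet - trace.dt)

    return PhaseSegmentation(intervals={
        "paced_nt": (t[0], t_zero),
        "zero_na_ca": (t_zero, t_tet),
        "tetracaine": (t_tet, t_caff),
        "caffeine": (t_caff, t_rec),
        "recovery_nt": (t_rec, t[-1] + trace.dt),
    })


def _refined_extremum(v: np.ndarray, dt: float, mode: str,
                      smooth_s: float = 0.25, refine_s: float = 0.05
                      ) -> float:
    """Extremum of a noisy segment without order-statistic bias.

    Locates the extremum on a median-filtered copy, then reads the median of
    the raw samples within ``refine_s`` of that location — unbiased on the
    plateau-shaped extrema the protocol trace has, and exact without noise.
    """
    if v.size == 0:
        raise ValueError("empty segment")
    k = max(1, int(round(smooth_s / dt)) | 1)
    sm = median_filter(v, size=k, mode="nearest") if v.size > k else v
    i = int(np.argmin(sm) if mode == "min" else np.argmax(sm))
    r = max(1, int(round(refine_s / dt)))
    return float(np.median(v[max(0, i - r):i + r + 1]))


def _noise_sd(v: np.ndarray) -> float:
    """Robust noise SD from first differences (insensitive to slow trends)."""
    if v.size < 3:
        return 0.0
    d = np.diff(v)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2)


def transient_amplitude(trace: FluorescenceTrace, seg: PhaseSegmentation,
                        n_beats: int = 5, min_separation_s: float = 0.3
                        ) -> float:
    """Paced Ca2+ transient amplitude dF_trans / F0,diastolic.

    F0,diastolic is the mean of the per-beat diastolic minima over the last
    ``n_beats`` steady-state beats; the peak is the mean of the matching
    per-beat maxima.  Raises when fewer than ``n_beats`` beats are found.
    """
    a, b = seg["paced_nt"]
    w = trace.window(a, b)
    t, v = trace.time_s[w], trace.value[w]
    if v.size < 10:
        raise ValueError("paced phase too short")
    prom = max(3.0 * _noise_sd(v), 0.05 * (v.max() - v.min()))
    if prom <= 0:
        raise ValueError("steady state not reached: no beats detected")
    pk, _ = find_peaks(v, prominence=prom,
                       distance=max(1, int(min_separation_s / trace.dt)))
    if pk.size < n_beats + 1:
        raise ValueError(
            f"steady state not reached: {pk.size} beats < {n_beats + 1}")
    minima = np.array([
        _refined_extremum(v[pk[i]:pk[i + 1]], trace.dt, "min",
                          smooth_s=0.15, refine_s=0.05)
        for i in range(pk.size - 1)])
    peaks = v[pk[1:]]
    f0 = float(np.mean(minima[-n_beats:]))
    peak = float(np.mean(peaks[-n_beats:]))
    if f0 <= 0:
        raise ValueError("non-positive diastolic baseline")
    return (peak - f0) / f0


def _diastolic_pre_tet(trace: FluorescenceTrace, seg: PhaseSegmentation,
                       window_s: float = 1.0) -> float:
    """Diastolic fluorescence immediately preceding tetracaine: median of the
    last ``window_s`` of the 0 Na+/0 Ca2+ phase (robust to oscillations)."""
    a, b = seg["zero_na_ca"]
    w = trace.window(max(a, b - window_s), b)
    if not w.any():
        raise ValueError("empty pre-tetracaine window")
    return float(np.median(trace.value[w]))


def sr_leak(trace: FluorescenceTrace, seg: PhaseSegmentation,
            smooth_s: float = 0.25) -> tuple[float, float, float, bool]:
    """Tetracaine-induced SR leak dF_tet / F0,diastolic.

    Returns (leak, f0_diastolic, f0_leak, clamped).  F0,diastolic is the
    diastolic level immediately preceding tetracaine; F0,leak the minimum of
    the median-filtered trace during tetracaine.  A negative computed drop
    (dye drift) is clamped to 0 with a warning, and F0,leak is then reported
    at the pre-tetracaine level.
    """
    if "tetracaine" not in seg:
        raise ValueError("tetracaine phase absent")
    f0d = _diastolic_pre_tet(trace, seg)
    a, b = seg["tetracaine"]
    w = trace.window(a, b)
    v = trace.value[w]
    if v.size == 0:
        raise ValueError("empty tetracaine phase")
    # the post-drop plateau is several seconds long, so a wide refinement
    # window is safe and keeps F0,leak tight at small drops
    f0_leak = _refined_extremum(v, trace.dt, "min", smooth_s=smooth_s,
                                refine_s=0.5)
    if f0_leak >= f0d:
        warnings.warn("no tetracaine-induced drop; leak clamped to 0",
                      LeakWarning)
        return 0.0, f0d, f0d, True
    return (f0d - f0_leak) / f0d, f0d, f0_leak, False


def sr_load(trace: FluorescenceTrace, seg: PhaseSegmentation,
            f0_leak: float, smooth_s: float = 0.05) -> float:
    """Caffeine-induced SR load dF_caff / F0,leak.

    The caffeine peak is the maximum of the lightly smoothed caffeine
    interval.  Requires F0,leak from :func:`sr_leak` (protocol order).
    """
    if "caffeine" not in seg:
        raise ValueError("caffeine phase absent")
    if not (math.isfinite(f0_leak) and f0_leak > 0):
        raise ValueError("F0,leak unavailable: protocol order violated")
    a, b = seg["caffeine"]
    v = trace.value[trace.window(a, b)]
    if v.size == 0:
        raise ValueError("empty caffeine phase")
    peak = _refined_extremum(v, trace.dt, "max", smooth_s=smooth_s)
    return max(0.0, (peak - f0_leak) / f0_leak)


def fractional_release(result: LeakLoadResult) -> float:
    """Ratio of paced transient amplitude to caffeine transient amplitude;
    NaN (missing) when the load is zero."""
    if result.load <= 0:
        return math.nan
    return result.transient_amplitude / result.load


def detect_oscillations(trace: FluorescenceTrace, seg: PhaseSegmentation,
                        k_sd: float = 3.8, min_separation_s: float = 0.3
                        ) -> list[tuple[float, float]]:
    """Spontaneous Ca2+ oscillations in the 0 Na+/0 Ca2+ window preceding
    tetracaine: peaks above baseline + ``k_sd`` robust SDs, as (time,
    amplitude dF/F0) with amplitude relative to the window's baseline."""
    if "zero_na_ca" not in seg:
        raise ValueError("0 Na+/0 Ca2+ phase absent")
    a, b = seg["zero_na_ca"]
    w = trace.window(a, b)
    t, v = trace.time_s[w], trace.value[w]
    if v.size < 5:
        return []
    base = float(np.median(v))
    sd = 1.4826 * float(np.median(np.abs(v - base)))
    height = base + k_sd * sd
    prom = max(k_sd * sd, 1e-9 * max(base, 1.0))
    pk, _ = find_peaks(v, height=height, prominence=prom,
                       distance=max(1, int(min_separation_s / trace.dt)))
    return [(float(t[i]), float((v[i] - base) / base)) for i in pk]


def analyze_leakload(trace: FluorescenceTrace,
                     annotations: Optional[dict] = None) -> LeakLoadResult:
    """Run the full protocol quantification on one trace."""
    seg = segment_phases(trace, annotations)
    amp = transient_amplitude(trace, seg)
    leak, f0d, f0l, clamped = sr_leak(trace, seg)
    load = sr_load(trace, seg, f0l)
    osc = detect_oscillations(trace, seg)
    res = LeakLoadResult(transient_amplitude=amp, leak=leak, load=load,
                         fractional_release=math.nan, f0_diastolic=f0d,
                         f0_leak=f0l, oscillations=osc, leak_clamped=clamped)
    res.fractional_release = fractional_release(res)
    return res
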