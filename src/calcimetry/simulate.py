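"""Synthetic cardiomyocyte recordings with known ground truth.

Generators for the four recording modalities the analysis pipeline consumes:

* confocal line-scan (X-T) fluorescence images containing Ca2+ sparks,
  wavelets/waves, and spontaneous whole-cell transients;
* whole-cell fluorescence traces following the Shannon-Bers SR leak/load
  protocol (1 Hz pacing -> 0 Na+/0 Ca2+ -> tetracaine -> caffeine -> recovery);
* extracellular field-potential recordings with depolarization spikes,
  T-waves, beat-period jitter and optional delayed afterdepolarizations;
* qPCR C_T tables with planted -dCt expression offsets.

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs, and each returns a ground-truth record of every
planted event so detection and measurement code can be scored against it.
Drug conditions (isoproterenol / nadolol / flecainide) are parameter presets
over event rates and morphologies, not pharmacological mechanisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LineScanSimConfig",
    "LeakLoadSimParams",
    "FieldPotentialSimParams",
    "GroundTruth",
    "PlantedEvent",
    "BeatTruth",
    "generate_linescan",
    "generate_leakload_trace",
    "generate_field_potential",
    "generate_ct_table",
    "spark_spatial_profile",
    "spark_temporal_profile",
    "spark_decay_tau",
    "CONDITION_PRESETS",
]


class ConfigurationError(ValueError):
    """Raised when a simulator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configs and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineScanSimConfig:
    """Geometry, noise and event statistics of one simulated line-scan.

    Rates are expectations: spark counts are Poisson with mean
    ``spark_rate * (scan_length_um / 100) * duration_s`` (sparks per
    100 um per second, the convention spark frequency is reported in).
    """

    scan_length_um: float = 40.0
    pixel_size_um: float = 0.155
    line_rate_hz: float = 500.0
    duration_s: float = 2.0
    baseline_f0: float = 100.0
    noise_sd: float = 0.02           # additive Gaussian, fraction of F0
    spark_rate: float = 0.0          # per 100 um per s
    spark_amplitude_mean: float = 0.6
    spark_amplitude_sd: float = 0.1
    spark_amplitude_min: float = 0.2
    spark_fwhm_um_mean: float = 2.0
    spark_fwhm_um_sd: float = 0.3
    spark_fdhm_ms_mean: float = 30.0
    spark_fdhm_ms_sd: float = 5.0
    spark_rise_ms: float = 5.0
    transient_rate_hz: float = 0.0   # spontaneous beating rate
    transient_amplitude: float = 2.0
    transient_fdhm_ms: float = 250.0
    transient_rise_ms: float = 30.0
    transient_alternans: float = 0.0  # fractional alternation of amplitudes
    wave_rate_per_s: float = 0.0      # diastolic waves per second
    wave_extent_fraction: float = 1.0
    wave_amplitude: float = 1.5
    wave_fdhm_ms: float = 200.0
    wave_velocity_um_s: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.line_rate_hz <= 0:
            raise ConfigurationError("pixel_size_um and line_rate_hz must be > 0")
        if self.scan_length_um <= 0 or self.duration_s <= 0:
            raise ConfigurationError("scan_length_um and duration_s must be > 0")
        if self.baseline_f0 <= 0:
            raise ConfigurationError("baseline_f0 must be > 0")
        for name in ("noise_sd", "spark_rate", "transient_rate_hz", "wave_rate_per_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 < self.wave_extent_fraction <= 1.0):
            raise ConfigurationError("wave_extent_fraction must be in (0, 1]")
        if self.spark_fdhm_ms_mean <= self.spark_rise_ms / 2:
            raise ConfigurationError("spark FDHM must exceed half the rise time")

    @property
    def n_space(self) -> int:
        return int(round(self.scan_length_um / self.pixel_size_um))

    @property
    def n_time(self) -> int:
        return int(round(self.duration_s * self.line_rate_hz))


@dataclass(frozen=True)
class PlantedEvent:
    """One planted event in a simulated recording.

    ``kind`` is one of spark / wavelet / wave / transient / oscillation / dad.
    Spatial fields are NaN where they do not apply (e.g. whole-line transients).
    """

    kind: str
    time_s: float                    # onset time
    position_um: float = math.nan    # center position (sparks) / start (waves)
    amplitude: float = math.nan      # dF/F0 (or fraction of spike amp for DADs)
    fwhm_um: float = math.nan
    fdhm_ms: float = math.nan
    extent_fraction: float = math.nan
    peak_time_s: float = math.nan


@dataclass
class GroundTruth:
    """Planted-event record accompanying one simulated recording."""

    events: list[PlantedEvent]
    config_echo: dict
    seed: int

    def of_kind(self, *kinds: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.kind in kinds]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config_echo,
            "events": [asdict(e) for e in self.events],
        }


# Drug-condition presets: labels from the study design (isoproterenol 100 nM,
# nadolol 10 uM, flecainide 10 uM); the numbers encode the qualitative contrast
# exercised end-to-end (beta-adrenergic stress raises spark/wave activity and
# broadens morphology; flecainide restores it; nadolol does not), not dose-
# response pharmacology.
CONDITION_PRESETS: dict[str, dict] = {
    "baseline": dict(spark_rate=4.0, spark_fdhm_ms_mean=28.0, spark_fwhm_um_mean=1.9,
                     wave_rate_per_s=0.0),
    "iso": dict(spark_rate=9.0, spark_fdhm_ms_mean=40.0, spark_fwhm_um_mean=2.5,
                wave_rate_per_s=0.35),
    "nad": dict(spark_rate=8.0, spark_fdhm_ms_mean=38.0, spark_fwhm_um_mean=2.4,
                wave_rate_per_s=0.30),
    "flec": dict(spark_rate=4.5, spark_fdhm_ms_mean=29.0, spark_fwhm_um_mean=2.0,
                 wave_rate_per_s=0.05),
}


# ---------------------------------------------------------------------------
# spark kernel (separable; closed form used by truth-consistency checks)
# ---------------------------------------------------------------------------

def spark_decay_tau(fdhm_ms: float, rise_ms: float = 5.0) -> float:
    """Decay constant (ms) giving a temporal half-maximum width of ``fdhm_ms``.

    The temporal kernel rises linearly over ``rise_ms`` then decays as
    exp(-t/tau).  The half-maximum crossings sit at rise_ms/2 (on the ramp)
    and rise_ms + tau*ln2 (on the decay), so FDHM = rise_ms/2 + tau*ln2.
    """
    if fdhm_ms <= rise_ms / 2:
        raise ConfigurationError("FDHM must exceed half the rise time")
    return (fdhm_ms - rise_ms / 2) / math.log(2.0)


def spark_temporal_profile(t_ms: np.ndarray, onset_ms: float, fdhm_ms: float,
                           rise_ms: float = 5.0) -> np.ndarray:
    """Unit-amplitude temporal kernel: linear rise then exponential decay."""
    tau = spark_decay_tau(fdhm_ms, rise_ms)
    dt = np.asarray(t_ms, dtype=float) - onset_ms
    out = np.zeros_like(dt)
    rising = (dt >= 0) & (dt < rise_ms)
    out[rising] = dt[rising] / rise_ms
    decaying = dt >= rise_ms
    out[decaying] = np.exp(-(dt[decaying] - rise_ms) / tau)
    return out


def spark_spatial_profile(x_um: np.ndarray, center_um: float,
                          fwhm_um: float) -> np.ndarray:
    """Unit-amplitude spatial Gaussian with the given full width at half max."""
    sigma = fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((np.asarray(x_um, dtype=float) - center_um) / sigma) ** 2)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    """Normal draws redrawn until >= low (sd may be 0)."""
    if sd <= 0:
        return np.full(size, max(mean, low))
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out < low
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.maximum(out, low)


# ---------------------------------------------------------------------------
# line-scan generator
# ---------------------------------------------------------------------------

def generate_linescan(cfg: LineScanSimConfig) -> tuple["LineScanImage", GroundTruth]:
    """Render a line-scan image and the record of every planted event.

    Returns the raw-fluorescence image ``F = F0 * (1 + sum of dF/F0 kernels)
    + Gaussian noise`` and a :class:`GroundTruth` sorted by onset time.
    Spark centers and peak times are snapped to the pixel/line grid so the
    rendered noise-free peak equals the planted amplitude up to discretization.
    """
    from .sparks import LineScanImage  # local import to avoid a cycle

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ns, nt = cfg.n_space, cfg.n_time
    x_um = np.arange(ns) * cfg.pixel_size_um
    t_ms = np.arange(nt) * 1000.0 / cfg.line_rate_hz
    dt_ms = 1000.0 / cfg.line_rate_hz

    dff0 = np.zeros((ns, nt))
    events: list[PlantedEvent] = []

    # --- spontaneous whole-line transients -------------------------------
    transient_windows: list[tuple[float, float]] = []  # (onset_s, end_s)
    if cfg.transient_rate_hz > 0:
        period_s = 1.0 / cfg.transient_rate_hz
        onset = 0.25 * period_s
        i_beat = 0
        while onset < cfg.duration_s - 0.05:
            amp = cfg.transient_amplitude * (
                1.0 + cfg.transient_alternans * (1 if i_beat % 2 == 0 else -1))
            onset_ms = round(onset * 1000.0 / dt_ms) * dt_ms
            prof = spark_temporal_profile(t_ms, onset_ms, cfg.transient_fdhm_ms,
                                          cfg.transient_rise_ms)
            dff0 += amp * prof[None, :]
            end_s = (onset_ms + cfg.transient_rise_ms
                     + 3.0 * spark_decay_tau(cfg.transient_fdhm_ms,
                                             cfg.transient_rise_ms)) / 1000.0
            transient_windows.append((onset_ms / 1000.0, min(end_s, cfg.duration_s)))
            events.append(PlantedEvent(
                kind="transient", time_s=onset_ms / 1000.0, amplitude=amp,
                fdhm_ms=cfg.transient_fdhm_ms, extent_fraction=1.0,
                peak_time_s=(onset_ms + cfg.transient_rise_ms) / 1000.0))
            onset += period_s
            i_beat += 1

    # --- sparks ----------------------------------------------------------
    n_sparks = rng.poisson(cfg.spark_rate * (cfg.scan_length_um / 100.0)
                           * cfg.duration_s)
    if n_sparks > 0:
        amps = _truncated_normal(rng, cfg.spark_amplitude_mean,
                                 cfg.spark_amplitude_sd,
                                 cfg.spark_amplitude_min, n_sparks)
        fwhms = _truncated_normal(rng, cfg.spark_fwhm_um_mean,
                                  cfg.spark_fwhm_um_sd, 0.5, n_sparks)
        fdhms = _truncated_normal(rng, cfg.spark_fdhm_ms_mean,
                                  cfg.spark_fdhm_ms_sd,
                                  cfg.spark_rise_ms / 2 + 2.0, n_sparks)
        # keep events far enough from edges that half-max crossings stay inside
        for k in range(n_sparks):
            mx = 1.5 * fwhms[k]
            mt = (cfg.spark_rise_ms + 3.0 * spark_decay_tau(fdhms[k],
                                                            cfg.spark_rise_ms))
            x_lo, x_hi = mx, cfg.scan_length_um - mx
            t_lo, t_hi = 2 * dt_ms, cfg.duration_s * 1000.0 - mt
            if x_hi <= x_lo or t_hi <= t_lo:
                continue
            center = rng.uniform(x_lo, x_hi)
            onset = rng.uniform(t_lo, t_hi)
            # snap center to the pixel grid and peak time to the line grid
            center = round(center / cfg.pixel_size_um) * cfg.pixel_size_um
            peak_ms = round((onset + cfg.spark_rise_ms) / dt_ms) * dt_ms
            onset_ms = peak_ms - cfg.spark_rise_ms
            prof_t = spark_temporal_profile(t_ms, onset_ms, fdhms[k],
                                            cfg.spark_rise_ms)
            prof_x = spark_spatial_profile(x_um, center, fwhms[k])
            dff0 += amps[k] * prof_x[:, None] * prof_t[None, :]
            events.append(PlantedEvent(
                kind="spark", time_s=onset_ms / 1000.0, position_um=center,
                amplitude=amps[k], fwhm_um=fwhms[k], fdhm_ms=fdhms[k],
                peak_time_s=peak_ms / 1000.0))

    # --- diastolic waves / wavelets --------------------------------------
    n_waves = rng.poisson(cfg.wave_rate_per_s * cfg.duration_s)
    if n_waves > 0:
        windows = _diastolic_windows(transient_windows, cfg.duration_s)
        for _ in range(n_waves):
            extent_um = cfg.wave_extent_fraction * cfg.scan_length_um
            travel_s = extent_um / cfg.wave_velocity_um_s
            dur_s = travel_s + (cfg.spark_rise_ms
                                + 3.0 * spark_decay_tau(cfg.wave_fdhm_ms,
                                                        cfg.spark_rise_ms)) / 1000.0
            fits = [w for w in windows if (w[1] - w[0]) > dur_s + 0.1]
            if not fits:
                continue
            w = fits[rng.integers(len(fits))]
            onset = rng.uniform(w[0] + 0.05, w[1] - dur_s - 0.05)
            start_px = 0
            if cfg.wave_extent_fraction < 1.0:
                start_px = int(rng.integers(0, cfg.n_space
                                            - int(extent_um / cfg.pixel_size_um)))
            rows = np.arange(start_px,
                             min(ns, start_px + int(round(extent_um
                                                          / cfg.pixel_size_um))))
            for i in rows:
                row_onset_ms = (onset + (i - start_px) * cfg.pixel_size_um
                                / cfg.wave_velocity_um_s) * 1000.0
                dff0[i] += cfg.wave_amplitude * spark_temporal_profile(
                    t_ms, row_onset_ms, cfg.wave_fdhm_ms, cfg.spark_rise_ms)
            kind = "wave" if cfg.wave_extent_fraction >= 0.999 else "wavelet"
            events.append(PlantedEvent(
                kind=kind, time_s=onset, position_um=start_px * cfg.pixel_size_um,
                amplitude=cfg.wave_amplitude, fdhm_ms=cfg.wave_fdhm_ms,
                extent_fraction=cfg.wave_extent_fraction))

    image = cfg.baseline_f0 * (1.0 + dff0)
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd * cfg.baseline_f0,
                                   size=image.shape)
    events.sort(key=lambda e: (e.time_s, e.kind))
    truth = GroundTruth(events=events, config_echo=asdict(cfg), seed=cfg.seed)
    return (LineScanImage(values=image.astype(np.float32),
                          pixel_size_um=cfg.pixel_size_um,
                          line_rate_hz=cfg.line_rate_hz), truth)


def _diastolic_windows(transient_windows, duration_s):
    """Complement of the transient windows within [0, duration]."""
    if not transient_windows:
        return [(0.0, duration_s)]
    out = []
    prev = 0.0
    for a, b in sorted(transient_windows):
        if a > prev:
            out.append((prev, a))
        prev = max(prev, b)
    if prev < duration_s:
        out.append((prev, duration_s))
    return out


# ---------------------------------------------------------------------------
# SR leak/load protocol trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeakLoadSimParams:
    """Planted truth and geometry of one Shannon-Bers protocol recording.

    Phases follow the bench protocol: field stimulation at 1 Hz in normal
    Tyrode for >= 20 s, switch to 0 Na+/0 Ca2+ (~10 s, where spontaneous
    oscillations may appear), 1 mM tetracaine (~10 s, fluorescence drops to
    the leak baseline), 30 mM caffeine (~10 s, SR store dumped), recovery.
    ``leak_true`` is the fractional tetracaine drop dF_tet/F0,diastolic;
    ``load_true`` is the caffeine amplitude dF_caff/F0,leak.
    """

    pacing_rate_hz: float = 1.0
    pacing_duration_s: float = 20.0
    f0_diastolic: float = 1.0
    transient_amplitude_true: float = 2.0
    leak_true: float = 0.2
    load_true: float = 3.0
    oscillation_rate: float = 0.0       # per s, 0 Na+/0 Ca2+ phase only
    oscillation_amplitude: float = 0.5  # dF/F0
    phase_durations: tuple[float, float, float] = (10.0, 10.0, 10.0)
    recovery_duration_s: float = 5.0
    sample_hz: float = 100.0
    noise_sd: float = 0.0               # fraction of f0_diastolic
    drop_duration_s: float = 1.0        # tetracaine smoothstep duration
    caffeine_rise_s: float = 0.5
    caffeine_hold_s: float = 0.2
    caffeine_decay_tau_s: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.leak_true < 1.0):
            raise ConfigurationError("leak_true must be in [0, 1)")
        if self.load_true <= 0:
            raise ConfigurationError("load_true must be > 0")
        if any(d <= 0 for d in self.phase_durations) or self.pacing_duration_s <= 0:
            raise ConfigurationError("phase durations must be > 0")
        if self.pacing_duration_s < 20.0:
            raise ConfigurationError(
                "protocol requires >= 20 s of pacing to reach steady state")
        if self.f0_diastolic <= 0 or self.sample_hz <= 0:
            raise ConfigurationError("f0_diastolic and sample_hz must be > 0")


def generate_leakload_trace(p: LeakLoadSimParams):
    """Render the protocol trace; returns (trace, segmentation, truth).

    The planted truth satisfies the defining ratios exactly before noise:
    paced peaks at F0*(1+A), tetracaine minimum at F0*(1-leak), caffeine
    peak at F0_leak*(1+load).  Oscillations are planted only in the
    0 Na+/0 Ca2+ window before tetracaine (tetracaine abolishes them).
    """
    from .leakload import FluorescenceTrace, PhaseSegmentation, LeakLoadResult

    p.validate()
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / p.sample_hz
    zero_s, tet_s, caff_s = p.phase_durations
    t_pace_end = p.pacing_duration_s
    t_tet = t_pace_end + zero_s
    t_caff = t_tet + tet_s
    t_rec = t_caff + caff_s
    t_end = t_rec + p.recovery_duration_s
    t = np.arange(0.0, t_end, dt)
    f0 = p.f0_diastolic
    f0_leak = f0 * (1.0 - p.leak_true)
    v = np.full_like(t, f0)

    # paced transients: ramp to peak, exponential decay, truncated per beat
    bp = 1.0 / p.pacing_rate_hz
    rise_s = 0.05
    tau = 0.15
    n_beats = int(math.floor(p.pacing_duration_s / bp))
    events: list[PlantedEvent] = []
    for i in range(n_beats):
        t0 = i * bp
        dtb = t - t0
        in_rise = (dtb >= 0) & (dtb <= rise_s)
        in_decay = (dtb > rise_s) & (dtb <= 0.9 * bp) & (t < t_pace_end)
        v[in_rise] = f0 + f0 * p.transient_amplitude_true * dtb[in_rise] / rise_s
        v[in_decay] = f0 + f0 * p.transient_amplitude_true * np.exp(
            -(dtb[in_decay] - rise_s) / tau)
        events.append(PlantedEvent(kind="transient", time_s=t0,
                                   amplitude=p.transient_amplitude_true,
                                   peak_time_s=t0 + rise_s))

    # 0 Na+/0 Ca2+ oscillations, strictly before tetracaine; onsets are
    # thinned to at least one kernel length apart so events stay resolvable
    n_osc = rng.poisson(p.oscillation_rate * zero_s)
    osc_rise, osc_tau = 0.05, 0.15
    onsets = np.sort(rng.uniform(t_pace_end + 0.5, t_tet - 1.5, n_osc))
    keep = []
    for t0 in onsets:
        if not keep or t0 - keep[-1] >= 1.0:
            keep.append(t0)
    for t0 in keep:
        t0 = round(t0 / dt) * dt  # snap so the sampled peak equals truth
        dtb = t - t0
        seg = (dtb >= 0) & (dtb <= 1.0)
        prof = np.zeros_like(t)
        r = (dtb >= 0) & (dtb <= osc_rise)
        d = (dtb > osc_rise) & (dtb <= 1.0)
        prof[r] = dtb[r] / osc_rise
        prof[d] = np.exp(-(dtb[d] - osc_rise) / osc_tau)
        v[seg] += f0 * p.oscillation_amplitude * prof[seg]
        events.append(PlantedEvent(kind="oscillation", time_s=t0,
                                   amplitude=p.oscillation_amplitude,
                                   peak_time_s=t0 + osc_rise))

    # tetracaine smoothstep drop to the leak baseline
    in_tet = (t >= t_tet) & (t < t_caff)
    u = np.clip((t[in_tet] - t_tet) / p.drop_duration_s, 0.0, 1.0)
    v[in_tet] = f0 - (f0 - f0_leak) * (3 * u ** 2 - 2 * u ** 3)

    # caffeine transient: ramp, short plateau, decay back toward F0,leak
    caff_peak = f0_leak * (1.0 + p.load_true)
    in_caff = (t >= t_caff) & (t < t_rec)
    dtc = t[in_caff] - t_caff
    seg = np.full(dtc.shape, f0_leak)
    r = dtc <= p.caffeine_rise_s
    seg[r] = f0_leak + (caff_peak - f0_leak) * dtc[r] / p.caffeine_rise_s
    h = (dtc > p.caffeine_rise_s) & (dtc <= p.caffeine_rise_s + p.caffeine_hold_s)
    seg[h] = caff_peak
    dcy = dtc > p.caffeine_rise_s + p.caffeine_hold_s
    seg[dcy] = f0_leak + (caff_peak - f0_leak) * np.exp(
        -(dtc[dcy] - p.caffeine_rise_s - p.caffeine_hold_s) / p.caffeine_decay_tau_s)
    v[in_caff] = seg
    caff_end_value = seg[-1] if seg.size else f0_leak

    # recovery: linear return to F0 over 1 s then flat
    in_rec = t >= t_rec
    dtr = t[in_rec] - t_rec
    v[in_rec] = np.where(dtr < 1.0,
                         caff_end_value + (f0 - caff_end_value) * dtr,
                         f0)

    if p.noise_sd > 0:
        v = v + rng.normal(0.0, p.noise_sd * f0, size=v.shape)

    seg_map = PhaseSegmentation(intervals={
        "paced_nt": (0.0, t_pace_end),
        "zero_na_ca": (t_pace_end, t_tet),
        "tetracaine": (t_tet, t_caff),
        "caffeine": (t_caff, t_rec),
        "recovery_nt": (t_rec, t_end),
    })
    frac = (p.transient_amplitude_true / p.load_true) if p.load_true > 0 else math.nan
    truth = LeakLoadResult(
        transient_amplitude=p.transient_amplitude_true,
        leak=p.leak_true, load=p.load_true, fractional_release=frac,
        f0_diastolic=f0, f0_leak=f0_leak,
        oscillations=[(e.time_s, e.amplitude) for e in events
                      if e.kind == "oscillation"])
    events.sort(key=lambda e: e.time_s)
    trace = FluorescenceTrace(time_s=t, value=v)
    return trace, seg_map, truth


# ---------------------------------------------------------------------------
# field potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldPotentialSimParams:
    """One simulated multielectrode-array field-potential recording.

    ``bp_jitter_cv`` is the target beat-period coefficient of variation in
    percent; realized periods are i.i.d. normal draws at that CV.  DADs are
    inserted after the T-wave of beats flagged with ``dad_probability``, at
    ``dad_amplitude_fraction`` of the spike amplitude.
    """

    sampling_hz: float = 12500.0
    n_beats: int = 60
    mean_bp_s: float = 1.0
    bp_jitter_cv: float = 5.0        # percent
    fpd_ms_mean: float = 300.0
    spike_amplitude: float = 1000.0  # uV
    twave_amplitude: float = 300.0   # uV
    spike_sigma_ms: float = 1.5
    twave_sigma_ms: float = 15.0
    dad_probability: float = 0.0
    dad_amplitude_fraction: float = 0.2
    dad_sigma_ms: float = 20.0
    noise_sd: float = 10.0           # uV
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_hz <= 0 or self.n_beats < 2:
            raise ConfigurationError("need sampling_hz > 0 and n_beats >= 2")
        if not (0.0 < self.dad_amplitude_fraction < 1.0):
            raise ConfigurationError("dad_amplitude_fraction must be in (0, 1)")
        if self.mean_bp_s <= self.fpd_ms_mean / 1000.0:
            raise ConfigurationError("mean_bp_s must exceed the FPD")
        if not (0.0 <= self.dad_probability <= 1.0):
            raise ConfigurationError("dad_probability must be a probability")


@dataclass
class BeatTruth:
    """Planted beat annotations for one field-potential recording."""

    spike_times_s: np.ndarray
    twave_times_s: np.ndarray
    beat_periods_s: np.ndarray
    dad_beats: np.ndarray          # bool, per beat
    dad_times_s: np.ndarray
    seed: int


def generate_field_potential(p: FieldPotentialSimParams):
    """Render an extracellular field-potential trace; returns (trace, truth)."""
    from .fieldpotential import FPTrace

    p.validate()
    rng = np.random.default_rng(p.seed)
    sd_bp = p.bp_jitter_cv / 100.0 * p.mean_bp_s
    bps = rng.normal(p.mean_bp_s, sd_bp, p.n_beats - 1) if sd_bp > 0 \
        else np.full(p.n_beats - 1, p.mean_bp_s)
    bps = np.maximum(bps, 0.3 * p.mean_bp_s)
    spikes = np.concatenate([[0.5], 0.5 + np.cumsum(bps)])
    dur = spikes[-1] + p.mean_bp_s
    n = int(round(dur * p.sampling_hz))
    t = np.arange(n) / p.sampling_hz
    v = np.zeros(n)

    sig_s = p.spike_sigma_ms / 1000.0
    sig_t = p.twave_sigma_ms / 1000.0
    sig_d = p.dad_sigma_ms / 1000.0
    dad_flags = rng.random(p.n_beats) < p.dad_probability
    twaves = spikes + p.fpd_ms_mean / 1000.0
    dad_times = []

    def _add(center, sigma, amp, biphasic=False):
        span = 10 * sigma
        lo = max(0, int((center - span) * p.sampling_hz))
        hi = min(n, int((center + span) * p.sampling_hz) + 1)
        dtw = t[lo:hi] - center
        if biphasic:
            # sharp positive lobe peaking exactly at `center`, followed by a
            # smaller, slower negative repolarization lobe
            w = (np.exp(-0.5 * (dtw / sigma) ** 2)
                 - 0.5 * np.exp(-0.5 * ((dtw - 4 * sigma) / (2 * sigma)) ** 2))
        else:
            w = np.exp(-0.5 * (dtw / sigma) ** 2)
        v[lo:hi] += amp * w

    for i, s in enumerate(spikes):
        _add(s, sig_s, p.spike_amplitude, biphasic=True)
        _add(twaves[i], sig_t, p.twave_amplitude)
        if dad_flags[i]:
            gap = (bps[i] if i < len(bps) else p.mean_bp_s) \
                - p.fpd_ms_mean / 1000.0
            td = twaves[i] + 0.5 * gap
            _add(td, sig_d, p.dad_amplitude_fraction * p.spike_amplitude)
            dad_times.append(td)

    if p.noise_sd > 0:
        v = v + rng.normal(0.0, p.noise_sd, size=n)

    truth = BeatTruth(spike_times_s=spikes, twave_times_s=twaves,
                      beat_periods_s=bps, dad_beats=dad_flags,
                      dad_times_s=np.asarray(dad_times), seed=p.seed)
    return FPTrace(time_s=t, voltage=v, sampling_hz=p.sampling_hz), truth


# ---------------------------------------------------------------------------
# qPCR C_T tables
# ---------------------------------------------------------------------------

def generate_ct_table(genes: list[str], samples: list[str], reference_gene: str,
                      effect_map: dict, seed: int = 0, base_ct: float = 20.0,
                      noise_sd: float = 0.0) -> pd.DataFrame:
    """Long-format C_T table with planted -dCt offsets.

    ``effect_map`` maps gene -> -dCt (relative to the reference gene); genes
    absent from the map get -dCt = 0.  Each sample receives a random overall
    C_T shift (plate effect), which -dCt is invariant to by construction.
    """
    if reference_gene not in genes:
        raise ConfigurationError("reference_gene must be among genes")
    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        shift = rng.normal(0.0, 1.0)
        ct_ref = base_ct + shift
        for g in genes:
            neg_dct = 0.0 if g == reference_gene else float(
                effect_map.get(g, 0.0))
            ct = ct_ref - neg_dct
            if noise_sd > 0 and g != reference_gene:
                ct += rng.normal(0.0, noise_sd)
            rows.append((s, g, ct))
    df = pd.DataFrame(rows, columns=["sample", "gene", "ct"])
    if df.duplicated(["sample", "gene"]).any():
        raise ConfigurationError("duplicate (sample, gene) rows")
    return df
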