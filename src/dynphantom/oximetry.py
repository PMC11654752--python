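"""Pulse-oximetry estimator: beat segmentation, R-ratio and SpO2 calibration.

A pulse oximeter compares the pulsatile attenuation at a red (660 nm)
and a near-infrared (940 nm) wavelength. For each pulse the "ratio of
ratios" is

    R = ln(Imax_660 / Imin_660) / ln(Imax_940 / Imin_940)

where Imax/Imin are the intensity extremes over the pulse. In the
86–100% range, oxygen saturation follows the empirical linear
calibration

    SpO2 = -24.87 * R + 113.8        (and inversely R = (113.8 - SpO2)/24.87)

Because the 940 nm extinction of blood barely changes over this range,
a phantom emulates a saturation level by holding the 940 nm modulation
depth fixed and choosing the 660 nm depth so the pair produces exactly
the calibrated R; :func:`depth_for_spo2` is that design calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .waveforms import SignalTrace

__all__ = [
    "PulseFeature",
    "OximetryEstimate",
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
    "detect_troughs",
    "trough_times",
    "segment_pulses",
    "pulse_r",
    "spo2_from_r",
    "r_from_spo2",
    "depth_for_spo2",
    "estimate_spo2",
]

#: Empirical linear calibration SpO2 = slope * R + intercept, valid 86-100%.
CALIBRATION_SLOPE = -24.87
CALIBRATION_INTERCEPT = 113.8


@dataclass(frozen=True)
class PulseFeature:
    """Intensity extremes of one pulse (trough-to-trough segment)."""

    i_max: float
    i_min: float
    t_max: float
    t_min: float
    pulse_index: int

    def __post_init__(self) -> None:
        if not self.i_max > self.i_min > 0:
            raise ValueError("pulse requires i_max > i_min > 0")


@dataclass(frozen=True)
class OximetryEstimate:
    """Per-pulse R values, their window average and the mapped SpO2."""

    per_pulse_r: np.ndarray
    r_mean: float
    spo2: float
    window_s: float
    n_pulses: int
    calibration_range_spo2: tuple = (86.0, 100.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.per_pulse_r, float)
        if r.size < 1:
            raise ValueError("need at least one pulse")
        if not np.isclose(self.r_mean, r.mean(), rtol=0, atol=1e-9):
            raise ValueError("r_mean must equal the mean of per_pulse_r")
        object.__setattr__(self, "per_pulse_r", r)


def _dominant_period_samples(
    v: np.ndarray, fs: float, hr_min_bpm: float, hr_max_bpm: float
) -> int | None:
    """Beat period in samples from the autocorrelation peak.

    Searches lags between one period at ``hr_max_bpm`` and one at
    ``hr_min_bpm``. Robust to detector noise and to secondary waveform
    features (dicrotic notch, diastolic wave), which only add weak
    sub-period correlation. Returns ``None`` if the trace is too short
    to contain one full period at ``hr_max_bpm``.
    """
    x = v - v.mean()
    lo = max(1, int(round(fs * 60.0 / hr_max_bpm)))
    hi = min(int(round(fs * 60.0 / hr_min_bpm)), x.size - 2)
    if hi <= lo:
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    return lo + int(np.argmax(ac[lo : hi + 1]))


def detect_troughs(
    trace: SignalTrace,
    hr_min_bpm: float = 40.0,
    hr_max_bpm: float = 220.0,
    prominence_frac: float = 0.25,
    smooth_hz: float | None = 8.0,
) -> np.ndarray:
    """Indices of pulse onsets (local intensity minima).

    Trough localization runs on a zero-phase low-pass copy of the trace
    (4th-order Butterworth at ``smooth_hz``; pass ``None`` to disable) —
    beat timing lives at the pulse fundamental (1–4 Hz), so this
    suppresses detector noise without shifting beat timing. The beat
    period is then estimated from the autocorrelation peak, and minima
    are required to be at least 70% of that period apart (never less
    than one period at ``hr_max_bpm``) with prominence at least
    ``prominence_frac`` of the smoothed trace's range. Anchoring the
    separation to the measured period lets the deepest minimum win
    within each beat, so dicrotic-notch dips and noise wiggles on the
    diastolic plateau are rejected.
    """
    if not 0 < hr_min_bpm < hr_max_bpm:
        raise ValueError("need 0 < hr_min_bpm < hr_max_bpm")
    v = trace.values
    nyquist = trace.sampling_rate / 2.0
    if smooth_hz is not None and smooth_hz < nyquist and v.size > 15:
        b, a = butter(4, smooth_hz / nyquist)
        v = filtfilt(b, a, v)
    span = float(v.max() - v.min())
    if span <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(trace.sampling_rate * 60.0 / hr_max_bpm)))
    period = _dominant_period_samples(v, trace.sampling_rate, hr_min_bpm, hr_max_bpm)
    if period is not None:
        distance = max(distance, int(round(0.7 * period)))

    # Anchor on systolic peaks: they are sharp and high-prominence, so
    # their count is noise-robust, unlike minima on the flat diastolic
    # valley floor. One trough is then located between consecutive peaks
    # (the deepest point), plus one in each sufficiently long partial
    # segment before the first / after the last peak.
    peaks, _ = find_peaks(v, distance=distance, prominence=prominence_frac * span)
    if peaks.size < 2:
        idx, _ = find_peaks(-v, distance=distance, prominence=prominence_frac * span)
        return idx
    p_est = period if period is not None else int(np.median(np.diff(peaks)))
    troughs = [a + int(np.argmin(v[a : b + 1])) for a, b in zip(peaks[:-1], peaks[1:])]
    # Partial segments only contribute a trough when their minimum lies
    # strictly inside the record — a minimum on the first/last sample
    # means the valley is truncated and its true bottom lies outside.
    if peaks[0] >= 0.5 * p_est:
        lead = int(np.argmin(v[: peaks[0] + 1]))
        if lead > 0:
            troughs.insert(0, lead)
    tail = v.size - 1 - peaks[-1]
    if tail >= 0.5 * p_est:
        trail = peaks[-1] + int(np.argmin(v[peaks[-1] :]))
        if trail < v.size - 1:
            troughs.append(trail)
    return np.asarray(troughs, dtype=int)


def trough_times(
    trace: SignalTrace,
    hr_min_bpm: float = 40.0,
    hr_max_bpm: float = 220.0,
    smooth_hz: float | None = 8.0,
) -> np.ndarray:
    """Sub-sample trough times in seconds.

    Starting from :func:`detect_troughs`, each trough's time is refined
    as the weighted centroid of the valley floor (samples within 30% of
    the local valley range, on the smoothed trace). The valley bottom of
    a PPG pulse is nearly flat, so a single argmin jitters under noise
    by several samples; the centroid pools the whole floor and is far
    more stable, which matters for rate estimates that hinge on the
    first and last trough of a record.
    """
    idx = detect_troughs(trace, hr_min_bpm, hr_max_bpm, smooth_hz=smooth_hz)
    if idx.size == 0:
        return np.array([])
    v = trace.values
    nyquist = trace.sampling_rate / 2.0
    if smooth_hz is not None and smooth_hz < nyquist and v.size > 15:
        b, a = butter(4, smooth_hz / nyquist)
        v = filtfilt(b, a, v)
    period = (
        float(np.median(np.diff(idx)))
        if idx.size >= 3
        else trace.sampling_rate * 60.0 / hr_max_bpm
    )
    half = max(2, int(round(0.3 * period)))
    times = []
    for i0 in idx:
        a_, b_ = max(0, i0 - half), min(v.size, i0 + half + 1)
        seg = v[a_:b_]
        local = float(seg.max() - seg.min())
        w = np.clip(seg.min() + 0.3 * local - seg, 0.0, None)
        if w.sum() > 0 and local > 0:
            center = a_ + float((w * np.arange(seg.size)).sum() / w.sum())
        else:
            center = float(i0)
        times.append(trace.start_time + center / trace.sampling_rate)
    return np.asarray(times)


def segment_pulses(
    trace: SignalTrace, hr_min_bpm: float = 40.0, hr_max_bpm: float = 220.0
) -> list[PulseFeature]:
    """Split a positive intensity trace into trough-to-trough pulses.

    Each :class:`PulseFeature` records the maximum and minimum intensity
    (and their times) within its segment. Partial leading and trailing
    segments — before the first and after the last trough — are dropped.

    Raises
    ------
    ValueError
        If the trace is not strictly positive, is shorter than one period
        at ``hr_min_bpm``, or contains fewer than one complete pulse.
    """
    if (trace.values <= 0).any():
        raise ValueError("pulse segmentation requires strictly positive samples")
    if trace.duration_s < 60.0 / hr_min_bpm:
        raise ValueError("trace shorter than one period at hr_min_bpm")
    troughs = detect_troughs(trace, hr_min_bpm, hr_max_bpm)
    if troughs.size < 2:
        raise ValueError("fewer than one complete pulse found")

    t0 = trace.start_time
    fs = trace.sampling_rate
    features = []
    for k, (a, b) in enumerate(zip(troughs[:-1], troughs[1:])):
        seg = trace.values[a : b + 1]
        imax = int(np.argmax(seg))
        imin = int(np.argmin(seg))
        features.append(
            PulseFeature(
                i_max=float(seg[imax]),
                i_min=float(seg[imin]),
                t_max=t0 + (a + imax) / fs,
                t_min=t0 + (a + imin) / fs,
                pulse_index=k,
            )
        )
    return features


def pulse_r(p660: PulseFeature, p940: PulseFeature) -> float:
    """Per-pulse ratio of ratios R = ln(Imax/Imin)@660 / ln(Imax/Imin)@940."""
    denom = np.log(p940.i_max / p940.i_min)
    if denom == 0:
        raise ZeroDivisionError("940 nm pulse has no pulsatility (i_max == i_min)")
    return float(np.log(p660.i_max / p660.i_min) / denom)


def spo2_from_r(r: float) -> float:
    """Linear calibration SpO2 = -24.87 R + 113.8 (percent, unclipped).

    Stated for the 86–100% saturation range; values outside that range
    are extrapolations and returned unclipped for the caller to judge.
    """
    if r < 0:
        raise ValueError("R must be non-negative")
    return CALIBRATION_SLOPE * r + CALIBRATION_INTERCEPT


def r_from_spo2(spo2_percent: float) -> float:
    """Exact inverse of :func:`spo2_from_r`: R = (113.8 - SpO2)/24.87."""
    if spo2_percent > CALIBRATION_INTERCEPT:
        raise ValueError("SpO2 above the calibration intercept has no valid R")
    return (CALIBRATION_INTERCEPT - spo2_percent) / (-CALIBRATION_SLOPE)


def depth_for_spo2(spo2_percent: float, depth_940: float) -> float:
    """660 nm modulation depth that emulates a saturation level.

    With per-channel depths d = 1 - Imin/Imax, the per-pulse ratio is
    R = ln(1 - d660) / ln(1 - d940), so the 660 nm depth that realises
    R = r_from_spo2(spo2) at a fixed 940 nm depth is

        d660 = 1 - (1 - d940) ** R.

    Raises
    ------
    ValueError
        If the required depth reaches 1 (unreachable contrast).
    """
    if not 0 < depth_940 < 1:
        raise ValueError("depth_940 must lie in (0, 1)")
    r = r_from_spo2(spo2_percent)
    d660 = 1.0 - (1.0 - depth_940) ** r
    if d660 >= 1.0:
        raise ValueError("required 660 nm depth >= 1 is unreachable")
    return float(d660)


def estimate_spo2(
    trace660: SignalTrace,
    trace940: SignalTrace,
    window_s: float = 6.0,
    hr_band: tuple[float, float] = (40.0, 220.0),
) -> OximetryEstimate:
    """Estimate SpO2 from paired red / near-infrared intensity traces.

    Both channels are segmented independently; pulses are paired by
    index (a single unpaired terminal pulse is dropped). R is computed
    per pulse, averaged arithmetically over pulses starting within the
    first ``window_s`` seconds, and mapped through the linear
    calibration.

    Raises
    ------
    ValueError
        On sampling-rate mismatch or a pulse-count discrepancy beyond 1.
    """
    if not np.isclose(trace660.sampling_rate, trace940.sampling_rate, rtol=0, atol=1e-9):
        raise ValueError("traces must share one sampling rate")
    if abs(trace660.duration_s - trace940.duration_s) > 1.0 / trace660.sampling_rate:
        raise ValueError("traces must share one duration")
    hr_min, hr_max = hr_band
    p660 = segment_pulses(trace660, hr_min, hr_max)
    p940 = segment_pulses(trace940, hr_min, hr_max)
    if abs(len(p660) - len(p940)) > 1:
        raise ValueError(
            f"pulse-count mismatch beyond 1 ({len(p660)} vs {len(p940)})"
        )
    n = min(len(p660), len(p940))
    pairs = [
        (a, b)
        for a, b in zip(p660[:n], p940[:n])
        if min(a.t_min, b.t_min) < trace660.start_time + window_s
    ]
    if not pairs:
        raise ValueError("no complete pulse inside the averaging window")
    r_values = np.array([pulse_r(a, b) for a, b in pairs])
    r_mean = float(r_values.mean())
    return OximetryEstimate(
        per_pulse_r=r_values,
        r_mean=r_mean,
        spo2=spo2_from_r(r_mean),
        window_s=window_s,
        n_pulses=len(pairs),
    )
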