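"""Synthesis and manipulation of PPG-like signal traces.

A photoplethysmogram (PPG) records blood-volume pulsations as a periodic
intensity waveform: a steep systolic upstroke, a dicrotic notch, and a
smaller diastolic wave, repeating at the heart rate. This module provides
a self-contained parametric generator (each beat is the sum of two
Gaussian bumps, whose overlap produces the notch), plus the normalization,
resampling and noise-injection primitives the rest of the pipeline uses.

All randomness is drawn from :func:`numpy.random.default_rng` seeded
explicitly, so every operation is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignalTrace",
    "BeatMorphology",
    "DEFAULT_MORPHOLOGY",
    "synth_ppg",
    "max_normalize",
    "resample",
    "add_noise",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled time series.

    Parameters
    ----------
    values
        Sample values (arbitrary intensity units, normalized units, or
        volts; the unit convention is carried in ``label``).
    sampling_rate
        Sampling rate in Hz; must be positive.
    start_time
        Time of the first sample in seconds.
    label
        Free-text tag, e.g. the wavelength channel or unit.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.isfinite(v).all():
            raise ValueError("values must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def replace(self, **kwargs) -> "SignalTrace":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class BeatMorphology:
    """Pulse-shape parameters for one cardiac beat.

    Each beat is modelled as two positive Gaussian bumps on a baseline:
    the systolic wave and the smaller, later diastolic wave. Centers and
    widths are expressed as fractions of the beat period, so the shape is
    heart-rate invariant. The dicrotic notch is the local dip where the
    two bumps overlap; ``notch_depth`` can deepen it by subtracting a
    narrow bump centred between the two waves.
    """

    systolic_amplitude: float = 1.0
    systolic_center: float = 0.22
    systolic_width: float = 0.07
    diastolic_amplitude: float = 0.35
    diastolic_center: float = 0.55
    diastolic_width: float = 0.12
    notch_depth: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.systolic_amplitude < 0 or self.diastolic_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (self.diastolic_amplitude < self.systolic_amplitude):
            raise ValueError("diastolic amplitude must be below systolic")
        for c in (self.systolic_center, self.diastolic_center):
            if not 0 <= c < 1:
                raise ValueError("bump centers must lie in [0, 1)")
        if self.systolic_width <= 0 or self.diastolic_width <= 0:
            raise ValueError("bump widths must be positive")
        if self.notch_depth < 0:
            raise ValueError("notch_depth must be non-negative")


DEFAULT_MORPHOLOGY = BeatMorphology()


def synth_ppg(
    heart_rate_bpm: float,
    duration_s: float,
    sampling_rate_hz: float,
    morphology: BeatMorphology = DEFAULT_MORPHOLOGY,
    hr_jitter_frac: float = 0.0,
    seed: int = 0,
) -> SignalTrace:
    """Generate a synthetic PPG trace.

    With ``hr_jitter_frac = 0`` the signal is exactly periodic with period
    ``60 / heart_rate_bpm`` seconds. With jitter, each beat period is
    independently perturbed by a Gaussian factor ``1 + jitter * N(0, 1)``.

    Raises
    ------
    ValueError
        If the heart rate is outside [30, 240] bpm, the duration is not
        positive, or the sampling rate is below four samples per beat
        (too slow to resolve the pulse shape).
    """
    if not 30 <= heart_rate_bpm <= 240:
        raise ValueError("heart_rate_bpm must lie in [30, 240]")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sampling_rate_hz < 4 * heart_rate_bpm / 60:
        raise ValueError("sampling rate below pulse bandwidth (< 4 samples/beat)")
    if hr_jitter_frac < 0:
        raise ValueError("hr_jitter_frac must be non-negative")

    rng = np.random.default_rng(seed)
    period = 60.0 / heart_rate_bpm
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz

    # Beat onsets cover [-2T, duration + 2T] so edge samples receive the
    # same neighbouring-beat contributions as interior ones (Gaussian
    # tails beyond 2 periods are < 1e-100 for the default widths).
    starts = []
    periods = []
    s = -2.0 * period
    while s < duration_s + 2.0 * period:
        T = period * max(1e-3, 1.0 + hr_jitter_frac * rng.standard_normal())
        starts.append(s)
        periods.append(T)
        s += T

    m = morphology
    out = np.full(n, float(m.baseline))
    for s, T in zip(starts, periods):
        out += m.systolic_amplitude * np.exp(
            -0.5 * ((t - (s + m.systolic_center * T)) / (m.systolic_width * T)) ** 2
        )
        out += m.diastolic_amplitude * np.exp(
            -0.5 * ((t - (s + m.diastolic_center * T)) / (m.diastolic_width * T)) ** 2
        )
        if m.notch_depth > 0:
            c = 0.5 * (m.systolic_center + m.diastolic_center)
            w = 0.25 * (m.diastolic_center - m.systolic_center)
            out -= m.notch_depth * np.exp(-0.5 * ((t - (s + c * T)) / (w * T)) ** 2)

    return SignalTrace(out, sampling_rate_hz, label=f"ppg_{heart_rate_bpm:g}bpm")


def max_normalize(trace: SignalTrace) -> SignalTrace:
    """Divide a trace by its global maximum so the output peaks at 1.

    Raises
    ------
    ValueError
        If the maximum is not positive (the trace cannot be meaningfully
        max-normalized).
    """
    peak = float(np.max(trace.values))
    if peak <= 0:
        raise ValueError("trace maximum must be positive for max-normalization")
    return trace.replace(values=trace.values / peak)


def resample(trace: SignalTrace, new_rate_hz: float) -> SignalTrace:
    """Resample to a new rate by linear interpolation.

    Duration is preserved to within one sample period. No anti-alias
    filter is applied; intended for smooth, pulse-band-limited signals
    going to rates of 50 Hz and above.
    """
    if new_rate_hz <= 0:
        raise ValueError("new_rate_hz must be positive")
    if np.isclose(new_rate_hz, trace.sampling_rate, rtol=0, atol=1e-12):
        return trace.replace()
    n_new = int(round(trace.duration_s * new_rate_hz))
    if n_new < 1:
        raise ValueError("resampled trace would be empty")
    t_new = np.arange(n_new) / new_rate_hz
    t_old = np.arange(trace.n_samples) / trace.sampling_rate
    return trace.replace(
        values=np.interp(t_new, t_old, trace.values), sampling_rate=new_rate_hz
    )


_NOISE_KINDS = ("white", "drift", "spikes")


def add_noise(
    trace: SignalTrace,
    noise_kind: str,
    magnitude: float,
    seed: int = 0,
    spike_rate_hz: float = 0.5,
) -> SignalTrace:
    """Inject noise emulating detector noise or motion artifacts.

    ``white``: additive zero-mean Gaussian with standard deviation
    ``magnitude`` (trace units). ``drift``: one low-frequency (< 0.5 Hz)
    sinusoid of amplitude ``magnitude`` with random frequency and phase.
    ``spikes``: sparse impulses of height ``magnitude`` at
    Poisson-distributed times (``spike_rate_hz`` expected events per
    second). Deterministic for a fixed seed; ``magnitude = 0`` returns
    the input unchanged.
    """
    if noise_kind not in _NOISE_KINDS:
        raise ValueError(f"unknown noise_kind {noise_kind!r}; expected {_NOISE_KINDS}")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return trace.replace()

    rng = np.random.default_rng(seed)
    t = np.arange(trace.n_samples) / trace.sampling_rate
    if noise_kind == "white":
        noise = rng.normal(0.0, magnitude, trace.n_samples)
    elif noise_kind == "drift":
        freq = rng.uniform(0.05, 0.5)
        phase = rng.uniform(0.0, 2 * np.pi)
        noise = magnitude * np.sin(2 * np.pi * freq * t + phase)
    else:  # spikes
        noise = np.zeros(trace.n_samples)
        n_spikes = rng.poisson(spike_rate_hz * trace.duration_s)
        if n_spikes > 0:
            idx = rng.integers(0, trace.n_samples, n_spikes)
            noise[idx] += magnitude
    return trace.replace(values=trace.values + noise)


def write_trace_csv(trace: SignalTrace, path) -> None:
    """Write a trace as two-column CSV with header ``time_s,value``."""
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False
    )


def read_trace_csv(path, label: str = "") -> SignalTrace:
    """Read a ``time_s,value`` CSV; the time grid must be uniform to 1 µs."""
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"CSV missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV needs at least two samples")
    dt = np.diff(t)
    if dt.min() <= 0 or (np.abs(dt - dt.mean()) > 1e-6).any():
        raise ValueError("time_s must increase with a uniform step (tolerance 1e-6 s)")
    return SignalTrace(
        df["value"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt.mean(),
        start_time=float(t[0]),
        label=label,
    )
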