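"""Phantom characterization: voltage sweep → functional range → lookup table.

The characterization protocol sweeps the LCD drive voltage from 0.5 to
3 V in 0.05 V steps while recording detected intensity. The *functional
range* is the voltage interval over which intensity is negatively
correlated with voltage; restricting the sweep to that band and
max-normalizing it yields the *lookup table* (LUT) that downstream
synthesis inverts to turn target signal levels into drive voltages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .phantom_model import PhantomConfig, measure_intensity
from .waveforms import SignalTrace

__all__ = [
    "TransferCurve",
    "LookupTable",
    "sweep",
    "find_functional_range",
    "build_lut",
    "lut_invert",
    "characterize_channel",
    "read_lut_csv",
    "write_lut_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransferCurve:
    """Raw voltage sweep: detected intensity versus drive voltage."""

    voltages_v: np.ndarray
    intensities: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_v, float)
        i = np.asarray(self.intensities, float)
        if v.size != i.size or v.size < 3:
            raise ValueError("curve needs >= 3 equal-length points")
        if (np.diff(v) <= 0).any():
            raise ValueError("voltages must be strictly increasing")
        object.__setattr__(self, "voltages_v", v)
        object.__setattr__(self, "intensities", i)


@dataclass(frozen=True)
class LookupTable:
    """Max-normalized, strictly decreasing transfer curve on the functional band.

    ``depth`` is the modulation depth the table spans:
    ``1 - normalized_intensities[-1]``.
    """

    voltages_v: np.ndarray
    normalized_intensities: np.ndarray
    v_lo: float
    v_hi: float
    channel: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_v, float)
        y = np.asarray(self.normalized_intensities, float)
        if v.size != y.size or v.size < 3:
            raise ValueError("LUT needs >= 3 equal-length points")
        if (np.diff(v) <= 0).any():
            raise ValueError("LUT voltages must be strictly increasing")
        if not np.isclose(y[0], 1.0, rtol=0, atol=1e-12):
            raise ValueError("first normalized intensity must be 1")
        if (np.diff(y) >= 0).any():
            raise ValueError("normalized intensities must be strictly decreasing")
        if y[-1] <= 0:
            raise ValueError("normalized intensities must stay positive")
        object.__setattr__(self, "voltages_v", v)
        object.__setattr__(self, "normalized_intensities", y)

    @property
    def depth(self) -> float:
        return 1.0 - float(self.normalized_intensities[-1])


def sweep(
    phantom: PhantomConfig,
    channel_nm: int,
    v_start: float = 0.5,
    v_stop: float = 3.0,
    v_step: float = 0.05,
    n_repeats: int = 1,
    seed: int = 0,
) -> TransferCurve:
    """Sweep the drive voltage and record mean detected intensity per point.

    The grid is arithmetic and inclusive of both ends (the last point is
    clipped to ``v_stop``). Each grid point is measured ``n_repeats``
    times through the (possibly noisy) detection chain and averaged.
    """
    if not v_start < v_stop:
        raise ValueError("v_start must be below v_stop")
    if v_step <= 0:
        raise ValueError("v_step must be positive")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    channel = phantom.channel(channel_nm)

    n_steps = int(np.floor((v_stop - v_start) / v_step + 1e-9))
    grid = v_start + v_step * np.arange(n_steps + 1)
    if grid[-1] < v_stop - 1e-9:
        grid = np.append(grid, v_stop)
    grid[-1] = min(grid[-1], v_stop)

    # One long constant-per-point drive record: n_repeats samples per grid
    # point, averaged after detection.
    drive = SignalTrace(np.repeat(grid, n_repeats), sampling_rate=1.0, label="sweep_v")
    detected = measure_intensity(drive, channel, phantom, seed=seed)
    means = detected.values.reshape(grid.size, n_repeats).mean(axis=1)
    return TransferCurve(grid, means, channel=f"{channel_nm}nm")


def find_functional_range(
    curve: TransferCurve, drop_tolerance: float = 0.002
) -> tuple[float, float]:
    """Locate the voltage band over which intensity decreases with voltage.

    A grid step counts as decreasing if intensity falls by more than
    ``drop_tolerance`` times the curve's global intensity range (this
    absorbs detector noise on flat stretches). The longest contiguous
    decreasing run wins; ties go to the lower-voltage run. Endpoints snap
    to grid points.

    Raises
    ------
    ValueError
        If no decreasing run spans at least 3 grid points.
    """
    if drop_tolerance < 0:
        raise ValueError("drop_tolerance must be non-negative")
    y = curve.intensities
    span = float(y.max() - y.min())
    if span <= 0:
        raise ValueError("flat curve: no functional range")
    falling = np.diff(y) < -drop_tolerance * span

    best_start, best_len = -1, 0
    run_start = None
    for i, f in enumerate(np.append(falling, False)):
        if f and run_start is None:
            run_start = i
        elif not f and run_start is not None:
            length = i - run_start
            if length > best_len:  # strict: ties keep the earlier (lower-V) run
                best_start, best_len = run_start, length
            run_start = None
    if best_len < 2:  # < 3 grid points
        raise ValueError("no decreasing run of >= 3 grid points: no functional range")
    return float(curve.voltages_v[best_start]), float(
        curve.voltages_v[best_start + best_len]
    )


def build_lut(curve: TransferCurve, v_lo: float, v_hi: float) -> LookupTable:
    """Restrict a sweep to the functional band and max-normalize it.

    Noisy curves are monotonized with isotonic (pool-adjacent-violators)
    regression before use — inversion requires strict monotonicity — and
    flat runs left by pooling are tilted by a negligible (1e-12 per
    point) ramp to make the decrease strict.
    """
    v = curve.voltages_v
    mask = (v >= v_lo - 1e-9) & (v <= v_hi + 1e-9)
    if mask.sum() < 3:
        raise ValueError("functional band contains fewer than 3 grid points")
    vb = v[mask]
    yb = curve.intensities[mask].astype(float)

    if (np.diff(yb) >= 0).any():
        iso = IsotonicRegression(increasing=False)
        yb = iso.fit_transform(vb, yb)
        yb = yb - 1e-12 * np.arange(yb.size)  # break pooled ties
    yb = yb / yb[0]
    # after normalization the head is exactly 1 and the max is at index 0
    return LookupTable(vb, yb, v_lo=float(vb[0]), v_hi=float(vb[-1]), channel=curve.channel)


def lut_invert(lut: LookupTable, target):
    """Map normalized-intensity target(s) to drive voltage(s).

    Piecewise-linear interpolation of voltage as a function of normalized
    intensity. Targets above 1 clamp to ``v_lo`` and targets below
    ``1 - depth`` clamp to ``v_hi``; both clamps log a warning rather
    than raising, since isolated out-of-band samples are expected on
    noisy inputs.
    """
    t = np.asarray(target, dtype=float)
    y = lut.normalized_intensities
    lo, hi = float(y[-1]), float(y[0])
    n_low = int((t < lo - 1e-12).sum())
    n_high = int((t > hi + 1e-12).sum())
    if n_low or n_high:
        logger.warning(
            "lut_invert: clamped %d target(s) above 1 to v_lo and %d below "
            "1-depth=%.4g to v_hi",
            n_high,
            lo,
            n_low,
        )
    v = np.interp(np.clip(t, lo, hi), y[::-1], lut.voltages_v[::-1])
    return v if v.ndim else float(v)


def characterize_channel(
    phantom: PhantomConfig,
    channel_nm: int,
    v_start: float = 0.5,
    v_stop: float = 3.0,
    v_step: float = 0.05,
    n_repeats: int = 1,
    drop_tolerance: float = 0.002,
    seed: int = 0,
) -> LookupTable:
    """Full characterization pass: sweep → functional range → LUT."""
    curve = sweep(phantom, channel_nm, v_start, v_stop, v_step, n_repeats, seed)
    v_lo, v_hi = find_functional_range(curve, drop_tolerance)
    return build_lut(curve, v_lo, v_hi)


def write_lut_csv(lut: LookupTable, path) -> None:
    """Write ``voltage_v,normalized_intensity`` CSV plus a JSON sidecar."""
    pd.DataFrame(
        {"voltage_v": lut.voltages_v, "normalized_intensity": lut.normalized_intensities}
    ).to_csv(path, index=False)
    sidecar = {
        "channel": lut.channel,
        "v_lo": lut.v_lo,
        "v_hi": lut.v_hi,
        "depth": lut.depth,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_lut_csv(path) -> LookupTable:
    df = pd.read_csv(path)
    try:
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
    except FileNotFoundError:
        sidecar = {}
    v = df["voltage_v"].to_numpy(float)
    return LookupTable(
        v,
        df["normalized_intensity"].to_numpy(float),
        v_lo=sidecar.get("v_lo", float(v[0])),
        v_hi=sidecar.get("v_hi", float(v[-1])),
        channel=sidecar.get("channel", ""),
    )
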