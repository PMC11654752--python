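"""Parametric forward model of the dynamic-phantom optical channel.

The physical device routes LED light through a tissue-mimicking silicone
layer and a light guide onto a liquid-crystal display (LCD); the voltage
applied to the LCD sets its transmittance, so the detected intensity can
be modulated electronically. This module abstracts that whole chain into
a per-wavelength voltage→transmittance transfer curve plus a source
intensity, a DAC quantization step and additive detector noise. It is
the fixture the characterization pipeline (:mod:`dynphantom.calibration`)
sweeps and inverts.

Transfer-curve shape
--------------------
Inside the functional band ``[v_lo, v_hi]`` the transmittance falls
smoothly and strictly monotonically from the open-state value ``t_open``
to ``t_open * (1 - depth_max)`` along a raised-cosine ramp::

    T(v) = t_open * (1 - depth_max * (1 - cos(pi * (v - v_lo) / (v_hi - v_lo))) / 2)

Outside the band it continues with a gentle positive slope
(``tail_slope``), so a full 0.5–3 V sweep is non-monotone, as real LCD
response curves are. Any smooth strictly-decreasing in-band shape would
serve; a channel may instead carry a user-supplied tabulated curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .waveforms import SignalTrace

__all__ = [
    "ChannelConfig",
    "PhantomConfig",
    "lcd_response",
    "measure_intensity",
    "default_phantom",
]


@dataclass(frozen=True)
class ChannelConfig:
    """Per-wavelength LCD transfer-curve parameters.

    ``depth_max`` is the maximal modulation depth, i.e. the relative
    intensity contrast (max − min)/max achievable inside the functional
    band. ``curve_v``/``curve_t`` optionally replace the parametric
    raised-cosine shape with a tabulated transmittance curve.
    """

    wavelength_nm: int
    depth_max: float
    v_lo: float = 1.2
    v_hi: float = 2.4
    t_open: float = 0.9
    tail_slope: float = 0.02  # fraction/V outside the band; >0 → non-monotone sweep
    curve_v: tuple | None = None
    curve_t: tuple | None = None

    def __post_init__(self) -> None:
        if not 0 < self.depth_max < 1:
            raise ValueError("depth_max must lie in (0, 1)")
        if not self.v_lo < self.v_hi:
            raise ValueError("v_lo must be below v_hi")
        if not 0 < self.t_open <= 1:
            raise ValueError("t_open must lie in (0, 1]")
        if (self.curve_v is None) != (self.curve_t is None):
            raise ValueError("curve_v and curve_t must be given together")
        if self.curve_v is not None:
            v = np.asarray(self.curve_v, float)
            tt = np.asarray(self.curve_t, float)
            if v.size != tt.size or v.size < 3 or (np.diff(v) <= 0).any():
                raise ValueError("tabulated curve needs >=3 strictly increasing voltages")


@dataclass(frozen=True)
class PhantomConfig:
    """Global phantom fixture: channels plus DAC/detector settings.

    ``metadata`` carries the static top layer's diffuse optical
    properties (absorption ``mu_a_cm1``, reduced scattering
    ``mu_s_prime_cm1``, thickness) purely descriptively; the transfer
    curves already subsume their effect on the detected signal.
    """

    channels: Mapping[int, ChannelConfig]
    source_intensity: float = 1000.0  # arbitrary units; results are invariant to it
    dac_step_v: float = 1.526e-4  # 16-bit DAC over a 10 V span
    detector_noise_sd: float = 0.0  # fraction of source_intensity
    metadata: Mapping[str, float] = field(
        default_factory=lambda: {
            "mu_a_cm1": 0.1,
            "mu_s_prime_cm1": 10.0,
            "thickness_mm": 0.5,
        }
    )

    def __post_init__(self) -> None:
        if self.dac_step_v < 0:
            raise ValueError("dac_step_v must be non-negative")
        if self.detector_noise_sd < 0:
            raise ValueError("detector_noise_sd must be non-negative")
        if self.source_intensity <= 0:
            raise ValueError("source_intensity must be positive")
        object.__setattr__(self, "channels", dict(self.channels))

    def channel(self, wavelength_nm: int) -> ChannelConfig:
        try:
            return self.channels[wavelength_nm]
        except KeyError:
            raise KeyError(
                f"no {wavelength_nm} nm channel; available: {sorted(self.channels)}"
            ) from None

    def to_json(self, path=None) -> str:
        def enc(obj):
            if isinstance(obj, ChannelConfig):
                return {k: v for k, v in obj.__dict__.items() if v is not None}
            raise TypeError(type(obj))

        payload = {
            "channels": {str(k): v for k, v in self.channels.items()},
            "source_intensity": self.source_intensity,
            "dac_step_v": self.dac_step_v,
            "detector_noise_sd": self.detector_noise_sd,
            "metadata": dict(self.metadata),
        }
        text = json.dumps(payload, default=enc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PhantomConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        channels = {
            int(k): ChannelConfig(**{**v, "curve_v": tuple(v["curve_v"]) if "curve_v" in v else None,
                                     "curve_t": tuple(v["curve_t"]) if "curve_t" in v else None})
            for k, v in payload["channels"].items()
        }
        return cls(
            channels=channels,
            source_intensity=payload.get("source_intensity", 1000.0),
            dac_step_v=payload.get("dac_step_v", 1.526e-4),
            detector_noise_sd=payload.get("detector_noise_sd", 0.0),
            metadata=payload.get("metadata", {}),
        )


def lcd_response(voltage_v, channel: ChannelConfig):
    """Transmittance fraction of the LCD channel at the given voltage(s).

    Continuous everywhere; strictly decreasing on ``[v_lo, v_hi]``;
    rising tails outside the band (see module docstring). Accepts scalars
    or arrays and broadcasts accordingly.
    """
    v = np.asarray(voltage_v, dtype=float)
    if (v < 0).any():
        raise ValueError("voltage must be non-negative")

    if channel.curve_v is not None:
        out = np.interp(v, np.asarray(channel.curve_v), np.asarray(channel.curve_t))
        return out if out.ndim else float(out)

    c = channel
    x = (v - c.v_lo) / (c.v_hi - c.v_lo)
    band = c.t_open * (1 - c.depth_max * (1 - np.cos(np.pi * np.clip(x, 0, 1))) / 2)
    out = np.where(
        v < c.v_lo,
        c.t_open + c.tail_slope * (v - c.v_lo),
        np.where(v > c.v_hi, c.t_open * (1 - c.depth_max) + c.tail_slope * (v - c.v_hi), band),
    )
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def measure_intensity(
    voltage_trace: SignalTrace,
    channel: ChannelConfig,
    phantom: PhantomConfig,
    seed: int = 0,
) -> SignalTrace:
    """Simulate the detection chain: drive voltage in, detected intensity out.

    ``out[i] = S * T(v[i]) + N(0, detector_noise_sd * S)`` with
    ``S = phantom.source_intensity``; deterministic for a fixed seed.
    """
    clean = phantom.source_intensity * lcd_response(voltage_trace.values, channel)
    if phantom.detector_noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(
            0.0, phantom.detector_noise_sd * phantom.source_intensity, clean.size
        )
    return voltage_trace.replace(
        values=clean, label=f"intensity_{channel.wavelength_nm}nm"
    )


#: Maximal modulation depths measured on the bench fixture, per wavelength.
_DEFAULT_DEPTHS = {940: 0.07, 660: 0.13, 530: 0.08, 455: 0.02}


def default_phantom(
    detector_noise_sd: float = 0.0, dac_step_v: float = 1.526e-4
) -> PhantomConfig:
    """The standard four-channel fixture (940/660/530/455 nm).

    Functional band 1.2–2.4 V on every channel; maximal modulation depths
    7%, 13%, 8% and 2% at 940, 660, 530 and 455 nm respectively; 16-bit
    DAC step; noiseless detector unless overridden.
    """
    channels = {
        nm: ChannelConfig(wavelength_nm=nm, depth_max=d)
        for nm, d in _DEFAULT_DEPTHS.items()
    }
    return PhantomConfig(
        channels=channels,
        dac_step_v=dac_step_v,
        detector_noise_sd=detector_noise_sd,
    )
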