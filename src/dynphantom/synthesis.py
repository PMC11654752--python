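"""Modulation-signal synthesis: target waveform → LCD drive voltage.

Mirrors the bench workflow: the target PPG is max-normalized, rescaled
to the desired modulation depth (the perfusion index of the emulated
pulse), mapped sample-by-sample through the inverted lookup table, and
quantized to the DAC's voltage resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import LookupTable, lut_invert
from .waveforms import SignalTrace

__all__ = ["ModulationTrace", "scale_to_depth", "map_signal", "quantize_dac",
           "synthesize_voltage"]


@dataclass(frozen=True)
class ModulationTrace(SignalTrace):
    """A drive-voltage trace (volts, within the generating LUT's band)."""

    provenance: Mapping[str, object] = field(default_factory=dict)


def scale_to_depth(normalized_trace: SignalTrace, depth: float) -> SignalTrace:
    """Affinely rescale a normalized waveform to a target modulation depth.

    Maps the trace maximum to 1 and the minimum to ``1 - depth``, so the
    output's (max − min)/max equals ``depth`` exactly. The non-pulsatile
    (DC) component is anchored at the top of the band, matching the
    convention of holding the baseline intensity fixed while scaling only
    the pulsatile excursion.
    """
    if not 0 <= depth < 1:
        raise ValueError("depth must lie in [0, 1)")
    x = normalized_trace.values
    lo, hi = float(x.min()), float(x.max())
    if depth == 0:
        return normalized_trace.replace(values=np.ones_like(x))
    if hi <= lo:
        raise ValueError("constant trace cannot carry a positive modulation depth")
    return normalized_trace.replace(values=1.0 - depth * (hi - x) / (hi - lo))


def map_signal(lut: LookupTable, rel_intensity_trace: SignalTrace) -> ModulationTrace:
    """Invert the LUT sample-wise to get the drive-voltage trace.

    Input values are expected in ``[1 - lut.depth, 1]``; out-of-range
    samples are clamped to the band edges with a logged warning (see
    :func:`dynphantom.calibration.lut_invert`).
    """
    volts = lut_invert(lut, rel_intensity_trace.values)
    return ModulationTrace(
        values=np.asarray(volts, float),
        sampling_rate=rel_intensity_trace.sampling_rate,
        start_time=rel_intensity_trace.start_time,
        label="modulation_v",
        provenance={
            "lut_channel": lut.channel,
            "lut_band_v": (lut.v_lo, lut.v_hi),
            "lut_depth": lut.depth,
            "target_label": rel_intensity_trace.label,
        },
    )


def quantize_dac(trace: ModulationTrace, step_v: float) -> ModulationTrace:
    """Round each voltage sample to the nearest DAC step.

    ``step_v = 0`` is the identity; otherwise the max absolute rounding
    error is ``step_v / 2``. Idempotent.
    """
    if step_v < 0:
        raise ValueError("step_v must be non-negative")
    if step_v == 0:
        return trace
    return trace.replace(values=np.round(trace.values / step_v) * step_v)


def synthesize_voltage(
    lut: LookupTable,
    normalized_ppg: SignalTrace,
    depth: float,
    dac_step_v: float = 0.0,
) -> ModulationTrace:
    """Convenience pipeline: depth scaling → LUT inversion → quantization.

    Raises
    ------
    ValueError
        If ``depth`` exceeds the LUT's own depth — the channel physically
        cannot express that contrast, and silently clamping the whole
        waveform would corrupt it.
    """
    if depth > lut.depth + 1e-9:
        raise ValueError(
            f"requested depth {depth:.4g} exceeds channel depth ceiling "
            f"{lut.depth:.4g}"
        )
    scaled = scale_to_depth(normalized_ppg, depth)
    return quantize_dac(map_signal(lut, scaled), dac_step_v)
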