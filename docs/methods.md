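# Methods

## Model overview

`dynphantom` simulates the optical channel of an LCD-modulated dynamic
phantom and closes the loop with a pulse-oximetry estimator. The chain is

    target PPG → max-normalize → depth scaling → LUT inversion →
    DAC quantization → LCD transmittance → detected intensity →
    beat segmentation → heart rate / R-ratio / SpO2

Everything upstream of the LCD (LEDs, dichroics, light guide, silicone
layer, photodiode, amplifier) is abstracted into three quantities per
wavelength channel: a voltage→transmittance transfer curve, a scalar
source intensity in arbitrary units, and additive Gaussian detector
noise. All downstream results are invariant to the source intensity
(verified by a property test), which is why arbitrary units suffice.

## The transfer curve

Real LCD response curves are non-monotone over a wide sweep but contain a
band where transmitted intensity falls strictly monotonically with
voltage. The model uses a raised-cosine ramp inside the functional band
`[v_lo, v_hi]`:

    T(v) = t_open · (1 − depth_max · (1 − cos(π (v − v_lo)/(v_hi − v_lo))) / 2)

with gently rising linear tails (`tail_slope`, default +0.02 fraction/V)
outside the band so a full sweep is non-monotone, exercising the
functional-range detector. The cosine ramp is one convenient smooth,
strictly decreasing shape; nothing downstream depends on it, and a channel
may carry a tabulated `voltage, transmittance` curve instead. Zero slope
at the band edges is deliberate — it reproduces the flat shoulders seen
in measured curves and makes the head of the lookup table the hardest
region for piecewise-linear inversion, which the round-trip tests probe.

Default fixture (four channels): maximal modulation depths 0.07, 0.13,
0.08 and 0.02 at 940, 660, 530 and 455 nm; band 1.2–2.4 V for every
channel; open-state transmittance 0.9 (arbitrary; cancels in
normalization); DAC step 1.526e-4 V (a 16-bit converter over a 10 V
span); detector noise 0 unless requested. The static top layer's diffuse
optical properties (µ_a = 0.1 cm⁻¹, µ_s′ = 10 cm⁻¹, 0.5 mm) are carried
as inert metadata only.

## Characterization

The sweep covers 0.5–3 V in 0.05 V steps (51 points), with optional
per-point repeat averaging for noisy fixtures (`sweep` defaults to one
repeat; the study drivers average 25 repeats, mirroring bench practice of
averaging the characterization measurement). "Negatively correlated"
is operationalized as the longest contiguous run of grid steps whose drop
exceeds `drop_tolerance` (default 0.002) times the curve's global range;
ties go to the lower-voltage run, and endpoints snap to grid points. The
relative tolerance absorbs detector noise on flat stretches while the
cosine ramp's smallest in-band step (the 2 % channel's first 0.05 V cell,
a relative drop of ≈0.004) still registers.

The lookup table is the band restriction of the sweep divided by its
band maximum. Noisy curves are monotonized by isotonic
(pool-adjacent-violators) regression before use, with pooled flat runs
tilted by 1e-12 per point to make the decrease strict — inversion
requires strict monotonicity and the measurement protocol itself says
nothing about noise handling, so this is the twin's choice. Inversion is
piecewise-linear in both directions (`numpy.interp` on the reversed
table). On the 0.05 V grid this leaves a worst-case normalized-intensity
round-trip error of ≈1.4e-4 near the flat band head (660 nm channel),
measured against a dense-grid brute-force oracle in the tests — small
enough that the noiseless closed loop stays below 0.01 % average error,
so no higher-order interpolant is needed. Out-of-range inversion targets
clamp to the band edges and emit a logging warning rather than raising:
isolated clipped samples are expected on noisy inputs, whereas a
*requested depth* exceeding the channel's ceiling raises, because that
error corrupts the whole waveform.

## PPG synthesis

Each beat is the sum of two positive Gaussian bumps on a baseline —
systolic (center 0.22 of the period, width 0.07, amplitude 1.0) and
diastolic (center 0.55, width 0.12, amplitude 0.35) — whose overlap
produces the dicrotic notch. Centers and widths are period fractions, so
the shape is rate-invariant. With zero heart-rate jitter the signal is
exactly periodic (beat onsets extend two periods beyond the record so
edge samples receive full neighbour contributions); jitter perturbs each
period by an i.i.d. Gaussian factor and defaults to 0 for
reproducibility. This generator emulates the gross morphology and exact
rate/length properties of a resting PPG; it does not reproduce
physiological beat-to-beat amplitude variability, respiratory
modulation, baseline wander, or any validated clinical waveform shape,
so passing tests demonstrate pipeline correctness, not clinical
equivalence. Synthesis runs at 1000 Hz and is linearly resampled to the
50 Hz measurement rate (no anti-alias filter; adequate for a signal
whose energy sits below a few hertz — a documented limitation for
aggressive downsampling of sharper content).

## Beat segmentation and heart rate

Segmentation works on a zero-phase low-pass copy (4th-order Butterworth,
8 Hz) of the intensity trace. The beat period is first estimated from
the autocorrelation peak between the periods implied by the heart-rate
band (default 40–220 bpm). Systolic peaks are then detected with
`scipy.signal.find_peaks` using a minimum separation of 70 % of that
period and a prominence floor of 25 % of the smoothed range; troughs are
the deepest samples between consecutive peaks, plus one per partial edge
segment at least half a period long whose minimum lies strictly inside
the record. Anchoring on peaks rather than minima matters: the PPG
valley floor is nearly flat, so under noise a raw argmin jitters by
several samples and can corrupt the *count* of minima (dicrotic-notch
dips sit near typical prominence thresholds), whereas the sharp
high-prominence systolic peak pins the beat count reliably.

Heart rate is 60 divided by the mean trough-to-trough interval. For the
interval endpoints the flat valley floor again limits raw argmin
precision, so trough times are refined to sub-sample precision as the
weighted centroid of the valley floor (samples within 30 % of the local
valley range). Per-pulse intensity extremes (Imax, Imin) are taken from
the raw, unfiltered samples within each segment.

## Oximetry

R is computed per pulse as ln(Imax/Imin) at 660 nm over ln(Imax/Imin) at
940 nm, after segmenting the two channels independently and pairing
pulses by index (a single unpaired terminal pulse is dropped; a count
mismatch beyond one raises). The window average (default 6 s) is the
arithmetic mean of per-pulse R over pulses starting inside the window.
SpO2 = −24.87·R + 113.8 is reported unclipped, with the valid 86–100 %
calibration range attached to the estimate; the design inverse
R = (113.8 − SpO2)/24.87 and the depth rule d660 = 1 − (1 − d940)^R
follow in closed form.

## Study defaults and problem sizes

The heart-rate study runs 4 channels × 5 rates (80–120 bpm in 10 bpm
steps), 20 s records synthesized at 1000 Hz and measured at 50 Hz, at 1 %
modulation depth — a typical resting perfusion index, and one that even
the 2 %-ceiling 455 nm channel can express. The saturation study reuses
one synthetic 75 bpm, 6 s record (a stand-in for a volunteer trace,
which is not distributed) for levels 86/90/95/100 % with the 940 nm depth
fixed at 0.07. Headline noisy runs use white detector noise at 0.1 %
(heart-rate study) or 0.05 % (worst-channel fidelity) of source
intensity; the physical detector chain's noise is not otherwise
specified, so these are config-exposed choices, not measurements. All
study outputs are bit-identical under a fixed seed; per-stage seeds are
drawn from one `numpy.random.default_rng(seed)` stream.

## Numerical choices and edge cases

- DAC quantization rounds to the nearest step; step 0 is the identity;
  idempotent by construction.
- Depth scaling of a constant trace is only defined for depth 0 (raises
  otherwise); max-normalization requires a positive maximum.
- `find_functional_range` raises when no decreasing run spans three grid
  points (e.g. a globally increasing curve); `build_lut` raises on bands
  with fewer than three points.
- Resampling to the same rate returns the trace unchanged; duration is
  preserved to within one sample period.
- A 940 nm pulse with zero pulsatility makes R undefined and raises.

## Known limitations

The twin validates the signal-processing pipeline, not the physics: no
radiative transfer, LCD angular or temporal response, hysteresis,
temperature drift, or shot-noise scaling. The empirical SpO2 line is
taken as given, not recalibrated. Linear-interpolation resampling and
LUT inversion are adequate at the default grids but would need revisiting
for much coarser sweeps or much lower measurement rates.
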