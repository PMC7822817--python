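# Methods

This note documents the models behind `neurotactile`: what is simulated,
which parameters matter, how the defaults were calibrated, and what the
synthetic experiments can and cannot show.

## Neuron model

All 23 channels use the two-variable Izhikevich model in its power-of-two
rescaling: multiplying the classic drift `0.04v² + 5v + 140 − u` by 0.78125
yields `(1/32)v² + 4v + 109.375 − u` (the linear coefficient rounded to 4),
so every constant is a shift-friendly dyadic rational.  The Euler step is
fixed at dt = 1 ms, matching the sensor frame rate; the recovery update
uses the pre-update membrane potential, and the spike reset writes
`v ← c`, `u ← u_pre + d` exactly.

Parameters (units as in the standard model; `a` per ms, voltages mV):

| class       | dynamics        | a    | b   | c   | d | input gain |
|-------------|-----------------|------|-----|-----|---|------------|
| SA-I        | regular spiking | 0.02 | 0.2 | −65 | 8 | k₁ = 1/32  |
| RA-I        | regular spiking | 0.02 | 0.2 | −65 | 8 | k₃ = 128 (on the derivative) |
| nociceptor  | fast spiking    | 0.1  | 0.2 | −65 | 2 | k₂ = 1/8   |

With `u` at its nullcline (`u = bv`) and zero input, the rest point solves
`(1/32)v² + 3.8v + 109.375 = 0`, i.e. v* ≈ −74.82 mV; the dynamics tests
verify convergence to this root to 0.1 mV.

**Membrane floor.** The membrane is clamped at −90 mV (about the potassium
reversal potential).  Besides being biophysically sensible, the floor is
numerically load-bearing: after a strong burst the recovery variable is
large, and the unclamped 1 ms Euler map would overshoot far below rest,
where the quadratic term catapults the membrane back over threshold in a
single step — a spurious self-sustained oscillation.  The clamp removes
exactly this artifact and is inactive in every normal firing regime.

## Input conditioning and interface calibration

The ADC-to-current conversion of the sensor interface is a free calibration
of the system (the class gains k₁, k₂, k₃ are fixed by the model).  Two
power-of-two conversions are applied:

* afferent paths (SA-I, RA-I): 8 current units per count.  Chosen so that
  a blunt contact drives every touched receptive field comfortably above
  the regular-spiking rheobase (≈ 6.1 drive units for this discretization).
  Below that point a spread-out contact loses most of its force to
  sub-threshold fields and the population rate no longer grows with
  contact area, contrary to the sustained-afferent phenomenology the model
  is meant to reproduce.
* nociceptor path: 0.25 current units per count (a right shift by 2 in
  hardware terms).  The Euler-discretized fast-spiking rate–current curve
  has wide plateaus above ≈ 35 drive units; feeding raw MCV/NoT counts
  saturates every sharpness level to near-identical rates.  The 0.25
  conversion places the MCV/NoT statistic of the default stimuli (roughly
  17–31 drive units) on the steep, graded segment of the curve.

The nociceptor threshold defaults to 512 counts (half of ADC full scale):
blunt contacts stay below it everywhere, the 5 mm objects remain weakly
supra-threshold and the sharpest objects cross it on one or two taxels,
giving the graded, sharpness-monotone nociceptor recruitment the system is
designed around.  The five nociceptors share one input signal; each channel
carries a seeded ±5% input-gain perturbation so their spike trains are
correlated but not bit-identical.

RA-I rectification is full-wave (`k₃·|ΔI|`): both onset and offset
transients excite, as rapidly adapting afferents require.

## Synthetic stimuli

The generator emulates a displacement-controlled robotic indentation of a
5×5 resistive taxel array (2.8 mm pitch, 10-bit ADC, 1 kHz frames).  The
depth profile is a trapezoid — 250 ms linear onset, 2000 ms hold, 250 ms
linear offset, default depth 1.4 mm (1.0 mm also used) — sampled at 1 ms,
2501 frames per trial.

Contact mechanics are the minimal model that reproduces "sharper = fewer
taxels at higher pressure":

* The total contact force grows linearly with depth
  (2048 counts·mm⁻¹ for cones).
* It is distributed uniformly over the object's geometric footprint: a
  disc of the apex diameter for cones; a 20 mm × width rectangle for the
  cuboids, whose 20 mm-long face contacts the array as a bar (an edge at
  1 mm width).  Bars carry a 2.5× force factor: a line contact recruits
  far more material than a point under displacement control.
* The footprint is convolved with a Gaussian kernel (σ = 1.2 mm) standing
  in for the silicone dispersion layer, then integrated over each
  2.8 × 2.8 mm taxel cell and quantized to the 10-bit range.

The force gain is calibrated once, from this geometry alone, so the 1 mm
cone at 1.4 mm depth drives its peak taxel to (slightly beyond) full
scale.  The resulting ADC saturation on the sharpest contacts is a real
sensor behavior and carries part of the sharpness signature: clipping
discards some of the concentrated force, which is one reason total
mechanoreceptor activity grows with contact area.

**Trial-to-trial variability** consists of a per-trial uniform contact-
center jitter (up to ±1 mm per axis — imperfect repositioning across the
10 repeated touches) and a per-trial Gaussian force-gain factor (sd 2% —
calibration drift).  Per-frame white sensor noise is available
(`noise_sd`, in counts) but defaults to zero: with the k₃ = 128 derivative
gain, even a single 1-count flicker in one innervated taxel is a
supra-threshold impulse for the RA-I path, so any white noise ≥ 1 LSB per
frame would make RA-I fire continuously through the hold phase.  A real
resistive sensor read at 1 kHz is sub-LSB stable, which the zero default
represents; the parameter exists to study noisier front-ends.

What the generator does **not** model: elastic continuum mechanics (no
finite-element skin), sensor hysteresis and drift, crosstalk between rows
and columns, and object tilt or rotation.  Passing tests therefore show
that the encoding and decoding machinery behaves correctly on an idealized
but faithful rendering of the protocol — not that the specific accuracy
numbers transfer to any physical sensor.

## Innervation

Each afferent centers its receptive field uniformly at random on the grid
and innervates `1 + Poisson(mean − 1)` taxels (exact mean, at least one),
sampled without replacement from the center's Chebyshev-radius-1
neighborhood (radius 2 for means above nine; the radius can be overridden).
Weights are i.i.d. uniform on (0.25, 1] — every connection non-negligible —
and are deliberately not normalized per field, so drive and firing rate
grow with field size.  Fields overlap freely; coverage statistics
(unused-taxel count, mean overlap) quantify how well a population tiles the
array.

## Decoding

* **Rate code**: spike counts per channel in a cumulative window from
  contact onset (500 ms for the contribution analyses; the window sweep
  uses 50–2500 ms), reduced to 3 principal components (fitted on the
  training fold only) and classified by KNN with k = 5.
* **Temporal code**: the Victor–Purpura metric — minimal edit cost with
  insertion/deletion cost 1 and shift cost q·|Δt| — computed by exact
  dynamic programming per channel and summed over the 23 matched channels
  (a labeled-line population distance: afferents are physically distinct
  fibers).  Default q = 0.05 ms⁻¹, a 20 ms coincidence window; q is a
  config knob.  Classification uses KNN on the precomputed distances.
* Both decoders use stratified 5-fold cross-validation (seeded) as the
  headline protocol; an 80/20 stratified holdout is available.  KNN vote
  ties break to the label of the nearest tied neighbor, which makes
  predictions deterministic for fixed data.

## Fault experiments

Taxel faults zero a seeded random subset of sensor outputs at the
interface, before innervation and before the nociceptor statistic — so
damage can raise MCV/NoT for a fixed frame (fewer supra-threshold taxels,
same maximum): innocuous touch turning noxious, the damaged-skin analogue.
Channel faults empty a seeded random subset of the 23 spike trains after
encoding.  The damaged subset is drawn once per condition and persists
across all trials.  Counts are rounded half-up (50% of 25 taxels → 13).
The sweep grid is {0, 0.1, …, 0.5} with 10 damage draws per point.

## Numerical and design choices

* Fixed-point mode: Q13.18 two's complement; conversion rounds to nearest,
  multiplication truncates the low bits (arithmetic shift), additions
  saturate with an overflow flag.  109.375, 1/32, 1/8 and 128 are exact.
  Over a full 2500 ms trial the fixed-point and float spike counts agree
  within ±1 per channel.
* The MCV/NoT division uses exact division by default; the fixed-point
  path replaces it with a right shift by ⌈log₂ NoT⌉.
* Neuron initialization: v₀ = c, u₀ = b·c (standard rest initialization).
* Seed fan-out: one master seed derives independent child seeds for
  stimulus noise, innervation, nociceptor gains, CV splits and fault
  subsets through named `SeedSequence` spawn keys, so experiment tables
  are reproducible byte-for-byte from the config alone.
* Problem sizes: the statistics reported by `scripts/acceptance.py`
  average 10 dataset seeds for decoding accuracies (3 for the temporal
  code, whose distance matrices dominate runtime), 10 damage draws for the
  fault point, and 24 innervation draws per object for the rate–sharpness
  relationship; these sizes give stable means (SEMs well inside the
  effects of interest) at about a minute of runtime.

## Known limitations

* The contact model is phenomenological; absolute firing rates are higher
  than biological SA-I/RA-I rates and should be read as digital-circuit
  rates, not physiology.
* Sharpness information in the nociceptor channel comes entirely from the
  MCV/NoT statistic and its threshold; objects whose peak pressure stays
  below threshold (both 9 mm objects, and the wider bars) are
  nociceptor-silent by design.
* The strictly monotone rate–sharpness relationships hold for population
  means over innervation draws; a single unlucky innervation map need not
  be monotone.
* The 5×5 array under-innervates its rim (fields centered near an edge
  have clipped neighborhoods), which slightly depresses responses to the
  largest objects.
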