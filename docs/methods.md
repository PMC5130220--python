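# Methods

## Problem and model

`bleedcap` models the computation chain of a swallowable capsule that
detects intestinal bleeding colorimetrically.  A white adsorptive film
inside the capsule is dyed by intestinal contents; a frequency-output
color sensor reports, per red/green/blue filter channel, a square-wave
frequency `f_C` (kHz) proportional to reflected intensity.  The chain is:

1. **White balance.**  Each channel gets an integration time `t_C` (ms)
   chosen so a white reference maps to the nominal 8-bit component 255,
   i.e. `t_C = 255 / f_C(white)`.  An arbitrary reading then converts to
   components `C = f_C · t_C` (dimensionless, ~0–255).  Components are not
   clamped: super-white inputs legitimately exceed 255 and flow through
   the formulas unchanged.  The default integration times
   (81.4097, 61.5481, 54.0988 ms) are the calibration of the reference
   sensor unit.
2. **HSL features.**  With `m = max(R,G,B)`, `n = min(R,G,B)`:
   `L = (m+n)/2` on the 0–255 scale;
   `S = (m−n)/(m+n)` if `L < 128`, else `(m−n)/(510−(m+n))`;
   `H` is the standard 60°-sector formula keyed on which channel attains
   the maximum (ties resolve in R, G, B order), wrapped into [0, 360).
   If `m = n` the color is achromatic: `H = S = 0` plus a flag.  Only H
   and S carry the diagnostic signal; L is computed but ignored.
3. **Decision region.**  Bleeding iff `3 ≤ H ≤ 25` and `0.3 ≤ S ≤ 0.8`,
   all bounds inclusive.  The region was calibrated on a double-dilution
   series of whole blood (hemoglobin 152 mg/ml): dilutions `P ≤ 64`
   (hemoglobin ≥ 152/64 = 2.375 mg/ml) fall inside, juices and `P ≥ 128`
   fall outside.  The generic wedge form `[0, H0] ∪ [H1, 360]`, `S ≥ S0`
   is supported via a wraparound flag because hue is circular.  The
   `S ≤ 0.8` cap is kept as calibrated but configurable
   (`region.s_high`); real mixtures exceeding it would silently not
   alarm, so users who prefer to treat `S > 0.8` as bleeding can raise it.
4. **Severity.**  Within the region, lower hue means deeper red and more
   blood.  Default tiers (configurable via `severity.cuts = 8,15`):
   `H ≤ 8` large, `8 < H ≤ 15` small, `15 < H ≤ 25` trace — placing the
   1×/4× dilution anchors in *large*, 16×/32× in *small*, 64× in *trace*.
5. **Capsule state machine.**  Dormant for 7200 s after activation, then
   a 5.5 s duty cycle (5 s sleep + 0.5 s sampling).  The 5.5 s period is
   deliberate: it reproduces the reference average current
   (7.6 · 0.5 / 5.5 ≈ 0.691 mA → 0.7 mA), which a 5.0 s period would not.
   A processed sample that classifies as bleeding transmits one
   severity-graded alarm immediately, with no hysteresis (repeated
   bleeding samples repeat the alarm).  A non-bleeding sample below the
   capsule voltage threshold (2.4 V) transmits a low-battery alarm,
   latched to once per run (configurable) since it is a terminal
   notification.  A bleeding sample at low voltage still sends its
   bleeding alarm — bleeding takes priority — and the voltage stays in
   the event log; this is an interpretation, as the low-voltage branch of
   the reference work flow only covers the no-bleeding case.  The
   detection-module (2.7 V) and transmitter (1.9 V) thresholds are
   carried in config for documentation; gating uses only 2.4 V.
   Alarm codes are one byte (0xB1/0xB2/0xB3 for trace/small/large,
   0xE0 low battery); the receiver renders them as buzzer + 1/2/3 LEDs,
   or buzzer alone for low battery.
6. **Power model.**  Active current = sensor + LEDs + MCU
   (2 + 5 + 0.6 = 7.6 mA); sleep current is taken as exactly 0 (watchdog
   only); average = duty-cycle-weighted mean ≈ 0.691 mA; average power =
   3.0 V × average ≈ 2.07 mW; battery life = capacity / average
   (40 mAh → ≈ 57.9 h).  Transmission bursts are modelled as
   instantaneous and lossless.

## Synthetic data generator

The generator emulates the dilution-series experiment, not raw optics.
Noise-free channel frequencies at fold-dilution `P ∈ [1, 512]` are
channel-wise linear interpolations in `log2 P` between the measured
anchors — the natural axis for a double-dilution series — so anchor
dilutions reproduce their measured frequencies exactly; extrapolation is
refused.  Baseline (non-bleeding) readings come from the two juice
anchors, which are separate solutions without a dilution axis.

Noise is multiplicative, lognormal, mean-one, independent per channel,
parameterized by its coefficient of variation.  The default CV of 2% is
a stand-in: the reference measurements report only channel means, so no
empirical noise magnitude exists.  Sensor frequency noise is positive
and roughly proportional to the mean, which motivates the lognormal
form.  Noisy generation requires an explicit integer seed; noise-free
paths are seedless and deterministic.

Scenarios assemble a stream: one reading per duty cycle after dormancy,
frequencies from the active bleed episode's dilution or the baseline,
and a linear voltage decay (V/h) from the start voltage.  A ground-truth
table (`t_s, true_dilution, true_bleeding`) accompanies every stream.

What the generator does *not* emulate: film adsorption kinetics and dye
transfer time (treated as instantaneous), spatial non-uniformity of the
film, illumination drift (which would be common-mode across channels),
temperature effects, and any RF link behavior.  Passing tests therefore
demonstrate the correctness of the computation chain under the stated
statistical model, not the biological or chemical performance of a
physical capsule.

### Anchor handling

The 16-fold measurement is excluded from the interpolation anchors.  Its
frequency columns place the derived hue at ≈358.9° — on the wrong side
of red between the 32-fold (14°) and 4-fold (4°) anchors — with derived
saturation below the 32-fold value, inverting the otherwise strictly
monotone concentration trend; the same row's reported H/S are also
inconsistent with its own frequencies.  Treating that row as a
transcription artifact and interpolating P = 16 from its neighbors
(yielding H ≈ 10.2, S ≈ 0.38) preserves the two properties the series is
supposed to have: monotone H/S versus concentration, and 100% noise-free
detection for P ≤ 64.  The transparent-yellow juice row's reported S is
likewise inconsistent (derived 0.454 vs reported 0.33), but juices are
used only as baseline frequency anchors, where this does not matter.

## Numerical choices

- **Achromatic guard.**  A color is achromatic when
  `m − n ≤ 1e−9 · max(m, 1)` rather than `m = n` exactly: the
  calibration round-trip leaves `m − n ~ 1e−13` on nominally equal
  components, which would otherwise hit the `510 − (m+n)` singularity at
  pure white.  The threshold is far below any 8-bit-visible chroma.
- **Hue ties.**  When two channels tie for the maximum, sectors are
  evaluated in R, G, B order; at the only tie occurring in the reference
  data (colorless juice, R ≈ G) both candidate sectors give H = 60.
- **Presentation rounding.**  H to the nearest degree and S to two
  decimals only at the presentation layer (CLI `h_rounded`/`s_rounded`
  columns, acceptance report); full precision everywhere internally.
- **Boundary artifact at P = 1.**  From the 4-decimal printed anchor
  frequencies, the undiluted anchor's derived hue is 2.9985° — 0.0015°
  below the inclusive `H ≥ 3` bound, although its reported hue is
  exactly 3.  This is below the print resolution of the inputs; the
  region bounds are left untouched, and tests document the artifact
  instead of absorbing it.

## Known limitations

- **Call rate under noise at the detection boundary.**  The 64-fold
  anchor maps to (H, S) = (20.0, 0.330), about one noise standard
  deviation inside both region bounds when channel noise has CV 2%
  (σ_H ≈ 8°, σ_S ≈ 0.04).  The per-reading bleeding-call rate there is
  consequently ≈ 65–68%, not >90%; reliable detection of marginal
  dilutions comes from the capsule's repeated 5.5 s sampling, not from a
  single reading.  The corresponding single-reading property test states
  the >90% expectation and fails honestly; see the test docstring.
- The simulator is a discrete-event idealization: sampling is
  instantaneous at the window start, transmission is lossless, and
  voltage is an input signal rather than a battery model.
- Severity tier cut-points are a design choice anchored to the dilution
  series; no clinical calibration of trace/small/large exists here.

## Problem sizes

Property tests run on grids of a few thousand RGB triples and Monte
Carlo samples of 1000–4000 draws; full-pipeline scenario tests use
streams of tens of readings.  The whole suite completes in a few
seconds on one CPU.
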