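# Methods

This note documents the models implemented in `seatag`, the parameters that
matter, the synthetic-data generator's scope, and the numerical and design
choices made where the design was genuinely open.

## Acquisition-chain math (`seatag.chain`)

The chain is described by an end-to-end sensitivity *S* (dB re FS/μPa,
deployed −205), bit depth *B* (16), and the clock tree
oscillator → ÷4 → master clock → ÷8 → modulator clock → ÷32 → output data
rate. All count/level conversions are closed forms on these parameters;
clipping at full scale is defined behavior, not an error, because the chain
itself clips. Clock divisions must be exact — a fractional modulator clock
is a misconfiguration and raises.

Environmental conversions use published formulas chosen to reproduce the
device's documented endpoint values:

- **Sound speed** (pure water): the Marczak (1997) fifth-order polynomial
  in temperature, valid 0–95 °C; 23 °C → 1491.2 m/s. Salinity is neglected
  (order 1% effect); an explicit override field exists for seawater work.
- **Depth from pressure**: Leroy & Parthiot (1998) standard-ocean formula
  with latitude-dependent gravity. Pressure is interpreted as *gauge* bar
  (dive-sensor convention); 97.5 bar at 15.4° N → 967 m. The inverse is
  solved by bracketed root finding (scalars) or a 4096-point interpolation
  table (arrays; error ≪ 0.01 m over 0–1200 m).
- **Detection range**: the passive-sonar balance
  `L_source − 20·log10(r) − α·r/1000 = L_floor` solved by bracketed root
  finding (Brent); with α = 0 the closed spherical-spreading form is used.
  The 120 dB capture floor is a configured value, not derived from the
  chain: it does not equal full scale minus dynamic range, and no derivation
  is documented for it, so the toolkit treats it as an input.

Reporting rounds half-up at each quantity's conventional precision
(integer counts/dB/Hz, 0.1 kHz, 0.001 MHz, 0.1 m/s, nearest metre, 0.1 h);
raw operations never round.

## Bearing pipeline (`seatag.aoa`)

**Model.** Far-field plane waves in the array plane (2-D); delays
`τ_ij(θ) = u(θ)·(p_i − p_j)/c`. 3-D solving is deliberately out of scope —
the validation context for the hardware was in-plane, and the planar
three-element array cannot resolve elevation.

**Pulse isolation.** Zero-phase band-pass (Butterworth order 4, default
2–20 kHz, the dominant click band) → analytic-signal envelope (|Hilbert|)
→ 0.2 ms moving average → threshold at median + k·MAD (default k = 12).
Rationale for the robust location+scale form: a click train is a heavy
right tail on the envelope distribution; the median and MAD are essentially
noise statistics even at high click rates. k = 12 sits midway between the
noise-envelope extreme values (~k = 8–9 over a minute of audio at the
20 dB-SNR study condition) and the click level (~k = 24), giving symmetric
margin against false alarms and misses. The window attached to each event
spans 1 ms before the onset to 10 ms after, two orders of magnitude beyond
the array's maximum geometric delay (~0.12 ms).

**TDoA.** Normalized cross-correlation (FFT) over lags bounded by
`ceil(d/c·f_s) + 2` samples; ties break toward the smallest |lag|, then the
negative lag (deterministic and neutral under symmetric noise). Raw
waveforms are correlated by default; envelope correlation is a flag.
Parabolic sub-sample refinement exists but defaults off so that one-sample
quantization behavior remains observable.

**Solve.** 0.1° grid search over the delay-residual sum of squares,
golden-section refinement to 0.01°. Collinear geometries (any two-element
array) return both mirror solutions about the baseline, flagged ambiguous.
The feasibility gate on input delays matches the correlator's search bound
(geometric maximum plus two samples) so that estimator output is always
solvable; anything beyond that raises with the offending pairs named.

**Expected angular resolution.** Per pair, feasible integer lags k map to
angles `asin(k·c/(f_s·d))`; the mean adjacent spacing, averaged over pairs,
is the single-sample resolution. For the default L geometry (0.125 m arms,
1491.2 m/s, 96 kSPS) this is 9.26°. The deployed device's exact hydrophone
spacing is not published; the default arm length is a configuration value
at the scale of the tag, and device-specific published error figures are
reference context, not targets this geometry reproduces.

## Mission simulator (`seatag.mission`)

Strict threshold comparisons exactly as specified (< 3 m, > 5 m, < 6.4 V,
< 6.2 V, < 6.0 V); the 3–5 m band retains the current mode (hysteresis —
the two-threshold design's purpose). The release countdown, the burnwire
flag, and the Wi-Fi lockout after the first dive are modeled as persisted
values that survive injected restarts; the countdown is cleared once the
burnwire fires. A depth-safety release (default 1000 m, the housing depth
bound) triggers the burnwire regardless of countdown and can be disabled.

**Energy and voltage.** The pack is two cells in series, 5 Ah at 7.4 V
nominal → 37 Wh. Draw is the sum of active subsystem watts; the default
budget (compute 1.0, audio 0.55, sensors 0.25, GPS 0.15, recovery TX
0.25 W) is a placeholder decomposition summing to the documented 2.2 W
total at surface recording and is fully user-configurable — the real
per-subsystem breakdown is device documentation not reproduced here. The
voltage proxy is linear in remaining energy from 8.4 V (full) to 6.0 V
(empty), with an exhausted pack reading 0.1 V below cutoff (cell collapse)
so the strict power-off comparison can fire. The proxy is isolated in one
function for replacement by a measured discharge curve. At a constant
2.2 W the pack depletes in 16.8 h.

**Data budget.** Stored audio rate = channels × bytes/sample × rate ×
compression ratio (default 0.15, the documented lossless-compression figure
for real recordings, carried as a config default); sensor streams at a
configurable bytes/hour. Bytes accrue only in recording modes; reporting
uses MB = 10⁶ bytes.

**Recovery channel.** Message delivery is an independent Bernoulli process
(seeded), preceded by a GPS-lock Bernoulli; transmission indices increment
only on lock. No RF propagation or packet encoding is modeled.

## Synthetic data (`seatag.synth`)

**What it emulates:** clicks with a decaying multi-pulse structure
(3 pulses, 4 ms inter-pulse interval, ×0.6 per pulse — configuration values
within the plausible range for sperm whales, recorded in truth files rather
than asserted as biology); dominant spectral energy at 5–10 kHz from a
Gaussian-windowed tone burst, plus a short (~5 µs σ) broadband transient at
a quarter of the pulse amplitude so energy extends measurably past 40 kHz
as in real clicks; geometry-consistent inter-channel delays applied by
32-tap windowed-sinc fractional-delay interpolation (sub-nanosecond truth
accuracy); plane-wave (incident level specified at the array) or spherical
(1/r from 1 m) propagation; independent Gaussian noise per channel at a
stated RMS SPL; conversion to integer counts via the chain sensitivity with
clipping flagged in truth metadata. Channels are sample-synchronous by
construction, mirroring the hardware's sub-sample synchronization.

Dive profiles are piecewise descent–bottom–ascent trapezoids with
Gaussian-drawn duration (40 ± 13 min) and maximum depth (645 ± 205 m) —
the documented deployment statistics — at a 1.5 m/s vertical rate with
600 s surface intervals (generator choices at realistic scales for deep
divers; durations truncated at 300 s, depths at 20 m, and depth capped so
at least 10% of each dive is bottom time). Sensor streams: pressure is the
exact inverse of the depth conversion plus ±300 Pa-class Gaussian noise;
light decays exponentially (5% at the 50 m extinction depth); temperature
is a two-layer linear profile clamped to the deployment-experienced 4.7–
42.4 °C bounds (device-experienced extremes, not an ocean profile); IMU is
white noise plus per-axis bias around gravity at 50 Hz; battery voltage
comes from the mission proxy. Sampling rates (1 Hz sensors, 50 Hz IMU,
0.1 Hz battery) are explicit generator configuration.

**What it does not emulate** — hence what passing tests do not show about
real data: no multipath or surface reflection, no whale-body shading, no
flow-noise spectrum (noise is white), no clock drift between channels, no
coda-level click patterning, no GPS dropout correlation with sea state.
Detection and bearing accuracy on real recordings will be worse than on
these clean synthetic conditions; the pipeline's published-context field
errors are substantially larger than its tank errors for exactly such
reasons.

**Click onsets** follow a regular process at the configured rate with ±20%
uniform jitter (Poisson optional): near-regular trains make exact truth
scoring unambiguous.

## File formats (`seatag.audio`, `seatag.flacio`, `seatag.bundle`)

Audio is carried as integer counts end to end; WAV (16/24-bit PCM) and FLAC
round-trip bit-exactly. FLAC support is a compact built-in subset codec:
independent channels, fixed predictors of order 0–4 with Rice-coded
residuals, constant and verbatim fallbacks, CRC-8/CRC-16 frame integrity,
and an MD5 signature of the raw samples verified on decode. The encoder
picks the smallest representation per subframe, so smooth synthetic signals
compress well while arbitrary content remains lossless. Stereo
decorrelation and LPC subframes are not implemented; the decoder rejects
them explicitly. Because the MD5 check is computed from the raw samples
independently of the frame coding, a successful decode certifies
bit-exactness end to end.

Sensor CSVs write epoch seconds at six fractional digits (microsecond
text precision) and values at nine; timestamps must be monotone and
violations report the first offending row. Bundles are validated for
manifest/directory consistency and segment contiguity. All writes are
deterministic: identical configuration and seed regenerate a bundle byte
for byte.

## Test scale choices

Stochastic suites run at desk scale chosen for statistical adequacy: the
state-machine sweep uses 100 seeded two-dive profiles of ~20 min each; the
bearing sweeps use 360 bearings (noiseless and at 20 dB SNR); end-to-end
bundles carry 30–60 s of 3-channel 96 kSPS audio at 120 clicks/min; the
recovery-channel check uses 10⁴ Bernoulli attempts against the 99% binomial
interval.

## Known limitations

- The voltage proxy is linear; real lithium-ion discharge curves are not,
  so simulated threshold-crossing *times* are approximations even though
  threshold *ordering* and semantics are exact.
- The 2-D bearing solver degrades gracefully but untestedly for sources
  well out of the array plane.
- The built-in FLAC codec targets correctness and losslessness, not
  state-of-the-art compression ratios; real-recording compression figures
  are not reproducible on synthetic white-noise-dominated content.
- Pure-water sound speed is used by default even for `water_type: sea`
  unless an override is supplied.
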