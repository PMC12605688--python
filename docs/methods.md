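# Methods

This note documents the models, parameter choices and numerical conventions
behind `pepflow`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Signal model and preprocessing

Input is a pair of synchronized channels: an ECG (mV) and the first
derivative of thoracic impedance, dZ/dt (Ω/s), sharing one sampling rate
after harmonization (when rates differ, the higher-rate channel is
polyphase-resampled down; rational resampling avoids aliasing near the 25 Hz
ICG band edge). Preprocessing uses Butterworth band-passes — fifth-order
0.67–45 Hz for the ECG, fourth-order 0.5–25 Hz for dZ/dt — applied
forward-backward (`sosfiltfilt`). Zero-phase filtering is a deliberate
choice: a causal filter delays fiducial landmarks by several milliseconds,
which would bias every PEP downstream. The squared magnitude response of the
two passes slightly sharpens the band edges; all tests account for the
doubled attenuation.

Derivatives (d²Z/dt², d³Z/dt³) are estimated by central differences with a
short moving-average pre-smoothing on each pass (window `round(5·fs/1000)`
samples, minimum 3). Raw repeated differencing of 500–1000 Hz signals
amplifies quantization and sensor noise enough to destroy the
third-derivative extrema that two of the B-point rules search for; the
smoothing window is short relative to every search window used (≥ 50 ms).

Conventions: 0-based sample indices, half-open cycle intervals
`[start, end)`, exported times in ms, ms→samples conversions rounded half
away from zero, and "local extremum" meaning a strict three-point extremum
with plateaus resolved to the last plateau sample.

## Cycle segmentation

R-peaks anchor everything. The default detector is a Pan–Tompkins-style
chain (QRS band-pass 5–30 Hz → derivative → squaring → 150 ms
moving-window integration → adaptive signal/noise threshold with a 250 ms
refractory period), refined to the local maximum of the input ECG within
±60 ms. The detector is pluggable (`detect_r_peaks(..., method=callable)`)
so reference R-peaks or an external detector can be injected.

The cycle of beat *i* is `[rᵢ − round(0.35·RRᵢ₋₁), rᵢ − round(0.35·RRᵢ₋₁) + RRᵢ₋₁)`,
i.e. 35% of the preceding RR interval before the R-peak and the remainder
after it. Defining the end as `start + RR` (rather than independently as
`r + round(0.65·RR)`) makes consecutive cycles tile the record exactly for
constant RR; the two definitions coincide except when `0.35·RR` falls on an
exact half sample. The first R-peak yields no cycle (no preceding RR).

## Fiducial extraction

**Q-peak** (PEP start; the Q-wave *peak* is used rather than the onset, as it
is the more reliably annotated landmark):

* `van13` — fixed offset `q = r − round(t·fs/1000)`; t defaults to 40 ms and
  the benchmark grid expands t over {32, 34, 36, 38, 40, 42} ms. Never
  missing; offsets clipped to the cycle start are flagged.
* `for18` — last sample before the R-peak with amplitude below
  `−1.2·R/scaling_factor`, R read from the filtered ECG at the detected
  R-peak. The scaling factor (default 2000) replaces the sampling rate of the
  original formulation, which would otherwise couple an amplitude threshold
  to the recording rate.
* `mar04` — à-trous DWT with the quadratic-spline wavelet (detail filter
  `[2, −2]`, smoothing filter `[1,3,3,1]/8`). Detail coefficients at scale 2²
  behave like a smoothed derivative: a Q-wave produces a negative modulus
  maximum (downslope) in the window `[r − 80 ms, r)`; evidence must reach 5%
  of the QRS modulus maximum at the same scale. The Q-peak is the deepest ECG
  local minimum between that evidence and the R-peak; beats without wavelet
  evidence are missing (`NoQWaveEvidence`). The 5% evidence ratio and the
  80 ms window are documented constants validated against the generator's
  ground truth (clean beats: exact to ±1 sample; beats synthesized without a
  Q deflection: 100% missing).

**C-point**: `scipy.signal.find_peaks` on dZ/dt after the R-peak (prominence
≥ 5% of the cycle's peak-to-peak range); among multiple candidates the peak
whose R–C interval is closest to the mean R–C of up to three preceding
cycles wins, the tallest peak when no history exists. No candidate → the
cycle is missing with reason `NoC`, which propagates to every C-relative
B-point rule.

**B-point** — twelve rules, each returning an index strictly before the
C-point or exactly one reason code (`InvBWindow`, `NoC`, `NoIsoCross`,
`NoLocMin`, `NoMonIncr`, `NoZCross`; `NegPEP` is set at pipeline level).
Where the original publications leave constants unstated, the choices here
are documented approximations validated on the synthetic morphology classes:

* `pal21` search window `[c − 150 ms, c)`; slope threshold
  `θ = 0.5·(dzdt(c) − min(window))/150 ms` (scales with C-wave amplitude),
  relaxed to θ/2 in stage 2, global-minimum fallback in stage 3.
* `mil22` weight `w(k) = (k/N)²` over the 300 ms pre-C window (monotone rise
  from ~0 to 1); with a flat weight the rule reduces to the last-local-minimum
  search, which the tests verify.
* `for18` "most significant" increasing run: longest, ties broken by
  amplitude gain, then by later onset; the B-point search is confined to the
  run's first third and takes the last zero crossing of d³Z/dt³ (either
  direction), falling back to its last local maximum. A negative-to-positive-
  only reading of the zero crossing fails on every clean notch beat (the
  third derivative crosses downward at the upslope onset), so the
  any-direction reading is used.
* `loz07lr/qr` predictions `B = 0.55·RC + 4.45` and
  `B = −0.0032·RC² + 1.233·RC − 31.59` (ms) are interpreted as offsets from
  the R-peak — the R–C interval is R-anchored, so the prediction is too; the
  fixed coefficients are never refit. Predictions outside
  `[cycle start, c)` are invalid.
* All C-relative windows clip to the cycle start; fewer than 2 samples after
  clipping → `InvBWindow`. Zero crossings are sample-level (the first sample
  on the far side); no sub-sample interpolation, matching sample-level
  annotations.

## Outlier correction

The corrected quantity is the **R-anchored B-point offset** (`b − r`, ms).
Absolute B-point times grow by one RR interval per beat; detrending that ramp
with a 0.1 Hz filter leaves large edge transients, and edge interpolation
would copy absolute times across beats. The offset series is the
physiologically stationary signal. (The public API accepts and returns
absolute times; the anchoring is internal.)

Stationarization subtracts a fourth-order Butterworth 0.1 Hz low-pass
(zero-phase) computed on a uniform beat grid at `fs_beat = 1/mean(RR)`;
missing beats are filled by linear interpolation before filtering and
restored after. Fewer than 8 valid beats: the series passes through with a
flag. Outliers are beats with `|x − median| > max(3·MAD, 1 ns)` on the
stationarized series; MAD is the *raw* median absolute deviation (no 1.4826
consistency factor). The tiny floor makes the degenerate cases coherent: a
constant series yields no outliers, a constant series with one spike flags
exactly the spike, and floating-point ripple after detrending is ignored.
Note the detrending filter absorbs roughly 20% of an isolated spike
(measured for a 4th-order 0.1 Hz low-pass at 1 beat/s), and its impulse
response spreads a fraction of a large spike into neighbouring beats — both
inherent to subtract-the-low-pass stationarization.

Correctors: `linint` replaces outliers by linear interpolation between the
nearest clean neighbours (edges copy the nearest clean value); `for18-ar`
averages a forward AR(p) one-step prediction (least-squares fit on up to 30
preceding clean beats) with a backward prediction on the reversed following
beats, using one side alone when the other lacks context and falling back to
interpolation when both do. The AR order p = 4 and 30-beat context are
package choices (the originating description leaves them open); the order
adapts downward when the context is short. A dummy corrector provides the
no-correction scenario. By default the correction stage also interpolates
beats whose B-point detection failed (configurable), so correction can only
reduce the number of invalid PEPs — clean beats are never modified.

## Pipelines and evaluation

A pipeline is segmentation → C-point → (Q-peak ∥ B-point) → optional
correction → PEP. Q and B stages are independent; when the B-point lands at
or before the Q-peak the PEP is negative and becomes missing (`NegPEP`) or 0
by policy. Either fiducial stream can be replaced by a reference annotation
table (reference injection), which isolates the other stage: with reference
Q-peaks injected, the PEP error equals the B-point error exactly — the
mechanism used to attribute pipeline error to stages. The default registry
enumerates 3 × 12 × 3 = 108 pipelines, or 288 with the fixed-offset Q grid
expanded.

Evaluation matches estimated to reference cycles greedily in time order; a
pair is accepted when both the start and end borders differ by at most half
the 100 ms tolerance ("centered" tolerance = ±50 ms per border). With ±50 ms
borders and cycles ≥ 300 ms, matches cannot cross, so the greedy sweep is
optimal. Unmatched estimates are false positives and excluded; unmatched
references are reported separately (`unmatched_ref`) rather than folded into
the invalid count. Per matched cycle, `E = PEP_ref − PEP_est`, `AE = |E|`,
`ARE = AE/PEP_ref` (stored as a fraction, reported as percent). Two
aggregation levels are emitted: per *datapoint* (the mean within each
grouping-key combination — e.g. participant × condition × phase, a
configurable choice) and per *sample* (mean ± SD over all cycles, each cycle
weighted equally); with unequal datapoint sizes the two genuinely differ.
Missing estimates on matched cycles are counted invalid, bucketed by reason,
and reason counts sum to the invalid total.

Inter-rater agreement uses the two-way, absolute-agreement, average-measures
ICC for two fixed raters, computed from the ANOVA mean squares:
`ICC(A,2) = (MSR − MSE)/(MSR + (MSC − MSE)/n)`, with the F-based confidence
interval of the single-measure form (Satterthwaite denominator df) stepped up
via Spearman–Brown. Zero between-target variance is degenerate and flagged.
The implementation is cross-checked against an independent ANOVA oracle and
against `pingouin` in the tests.

## Synthetic generator

The generator emulates what the fiducial algorithms actually consume:
timing, local waveform shape around each fiducial, and noise — not
hemodynamics. ECG beats are Gaussian bumps (P, Q, R, S, T) with the Q dip
narrow (σ = 5 ms) so its trough is exact at the ground-truth sample; setting
`q_amplitude = 0` synthesizes beats without any Q deflection. dZ/dt beats
are cubic Hermite splines through knots encoding the four B-point
morphology classes annotators distinguish: an incisive **notch** (strict
local minimum exactly at B), a 15 ms zero-slope **plateau** starting at B,
an **inflection** (curvature sign change, no extremum), and a
**featureless** monotone rise. The upslope accelerates within ~12 ms after
the B-point to well above the B-to-C chord slope — that acceleration is what
makes B the "onset of the rapid rise". The featureless class anchors its
rise 40% of the preceding RR before the R-peak, just outside the 35% cycle
border, so the cycle window contains no local minimum at all (this requires
heart rates ≲ 110 bpm; the default is 60). Beat timing: per-beat RR jitter
is i.i.d. Gaussian truncated at ±20% of the mean RR (keeping the 35%/65%
segmentation valid); per-beat PEP jitter is optional and clipped to keep
B strictly between R and C. Noise (Gaussian, baseline drift, powerline) is
added after concatenation. Identical configurations produce bit-identical
output.

Defaults are a resting adult: 60 bpm, PEP 100 ms (inside the 60–170 ms
physiological range), Q–R gap 40 ms, R–C interval 150 ms, notch morphology.

**What passing on synthetic data shows — and does not.** The generator gives
exact ground truth, so it verifies each rule's *logic* (windows, fallbacks,
reason codes, arithmetic) and the pipeline identities. It does not reproduce
the morphological diversity, respiration coupling, electrode artifacts or
ectopy of real recordings; absolute error levels on synthetic beats say
nothing about error levels on clinical data, where B-point detectors are
known to disagree by tens of milliseconds. Problem sizes used in the test
suite and acceptance script (30–122 s trains, 29–121 beats) were chosen as
the smallest sizes at which every code path — filter warm-up, C-point
history, outlier screening — is exercised.

## Known limitations

* The Pan–Tompkins-style R detector targets clean-to-moderately-noisy adult
  sinus rhythm; heavy artifact or arrhythmia handling is out of scope (inject
  reference R-peaks instead).
* `mar04` thresholds are fixed constants, not the adaptive per-record
  thresholds of a full delineator; on unusual QRS morphologies the evidence
  gate may misfire.
* The featureless morphology's monotone-window guarantee holds for the
  generator's default geometry, not arbitrary parameter combinations.
* Native readers for proprietary acquisition containers (.acq, TFM .mat) and
  EDF are out of scope; recordings enter via columnar CSV.
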