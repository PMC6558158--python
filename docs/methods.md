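# Methods

`headgait` quantifies head stabilization during everyday walking from two
body-worn inertial measurement units (IMUs): one fixed to the head, one to
the trunk, each recording tri-axial specific force (in g) and angular
velocity (rad/s) at a nominal 100 Hz. This note describes the processing
model, the synthetic-data generator that stands in for real recordings, the
numerical choices, and the limits of what the test suite demonstrates.

## Processing model

### Synchronization and calibration

The two devices run on independent clocks. Knocking them against each other
at the start and end of a recording produces large synchronous acceleration
spikes; the first and last detected spike per device (acceleration magnitude
above 2.5 g, 1 s refractory) define a two-point linear clock map
`t_head = offset + (1 + drift)·t_trunk`. Knock times are refined to
sub-sample precision as the centroid of the above-baseline magnitude around
each spike — with knocks ~10 min apart, millisecond-level timing is needed
for the drift term to be meaningful. The head channels are then resampled
onto the trunk timebase with a cubic spline.

Sensor-to-body mounting is estimated from two calibration postures: a
quasi-static segment (≥ 2 s, |a| within 5 % of 1 g, RMS wobble below
0.05 g) pins the body vertical to the mean measured gravity, and a five-nod
segment pins the medial/lateral (ML) axis to the first principal axis of
the nod angular-velocity samples, signed so the initial nod is a forward
pitch. The trunk device is calibrated from the static posture alone
(vertical constrained, yaw left as identity) — a person nodding their head
does not rotate their trunk, so no trunk nod exists. Body axes are
right-handed: x anterior/posterior (AP, forward), y ML (left), z vertical
(V, up); a static upright sensor reads +1 g on z.

### Gravity filter and aligned frame

Orientation is tracked by a per-sample complementary gravity filter.
With body rates ω and low-passed specific force a (both prefiltered by
zero-phase 5th-order Butterworth filters: gyro high-passed at 0.1 Hz
against bias drift, accel low-passed at `f_lp`):

1. propagate: rotate g(t−1) by the exact Rodrigues rotation of −ω·Δt
   (a world-fixed vector seen from a rotating body frame obeys
   ġ = −ω × g);
2. blend: g ← α·g + (1 − α)·a;
3. normalize g;
4. form q(t) as the axis–angle rotation taking g(t) onto the world
   vertical, axis g(t) × g_W.

Because the axis is always horizontal, q(t) contains no yaw by
construction; heading is neither observable nor needed. Net inertial
acceleration in the aligned frame is `i_A = rot(q, a_raw − g)`; angular
velocity deliberately stays in the body frame (pitch velocity = ML
component), matching how laboratory studies report rotations.

**Defaults α = 0.98, f_lp = 0.5 Hz.** Both were set by a sweep over
synthetic validation trajectories and gait sessions. Two effects dominate.
First, the accelerometer pull must not chase gait-band inertial
acceleration: at f_lp = 0.5 Hz a 1.9 Hz component is attenuated by ~55 dB,
so the blend pulls toward clean gravity. Second, the complementary time
constant τ = α·Δt/(1 − α) must be long against the gait cycle: real gait
pitches the head a few degrees at ~1.9 Hz, and with τ ≈ 0.09 s (α = 0.9)
the blend fights that oscillation, leaving a ~1–2° oscillating tilt error
that leaks vertical inertial acceleration and gravity into the AP channel
— enough to bias the AP attenuation coefficient by ~0.02. At α = 0.98
(τ ≈ 0.5 s) the gyroscope tracks the oscillation and per-axis attenuation
recovery errors fall below 0.003, while accuracy on slow-tilt validation
trajectories remains ~1° median under default sensor noise. Filtering is
forward–backward (zero phase) since the pipeline is offline.

The filter's error metric is the geodesic distance
`d = arccos(2⟨q₁, q₂⟩² − 1)`, the angle of the shortest arc between two
orientations, invariant to quaternion sign.

### Step detection and bouts

Candidate steps are peaks of aligned vertical trunk acceleration with
minimum height 0.2 g, prominence 0.4 g, and minimum separation 0.2 s
(equivalent to a maximum detectable cadence of 5 Hz). Per candidate, a
1024-sample Blackman-windowed power spectrum per axis yields predominant
frequencies (argmax of power, DC excluded), and a 512-sample segment
yields per-axis RMS. Cycling-like periods pass the peak detector but are
excluded when vertical RMS < 0.1 g or |f_V − f_ML| > 0.5 Hz; these two
thresholds were fitted once against the synthetic cycling generator and
are exposed in the configuration. Surviving steps are grouped into bouts
wherever consecutive peaks are < 1 s apart (peak-to-peak); single-step
bouts are discarded. Analysis is finally gated to steps whose *head*
vertical predominant frequency (512-sample spectrum, grid spacing
100/512 ≈ 0.195 Hz) lies in [1, 2.6] Hz, the range in which predominant
frequency works as a proxy for walking speed.

### Stability measures (per retained step)

* **Attenuation coefficient** `AC = 1 − A_H/A_T` per axis, from
  Blackman-weighted RMS of the 512-sample head and trunk segments
  (weighting de-emphasizes non-locomotor samples at segment edges; the
  window normalization cancels in the ratio). Positive AC = head motion
  attenuated relative to the trunk.
* **Harmonic ratio.** With f_dom the axis's predominant frequency and
  stride base f_s = f_dom/2 (a stride is two steps), even-harmonic power
  E = Σₖ S(k·f_dom) and odd-harmonic power O = Σₖ S((2k−1)·f_s) are summed
  over N = 10 harmonics (truncated at Nyquist), each read from the single
  nearest grid bin. HR = E/O for AP and V (biphasic within a stride) and
  HR = O/E for ML (monophasic), so large HR always means regular gait.
  A zero denominator returns a configurable cap (default 100).
* **Coherence** `K² = |S_xy|²/(S_xx·S_yy)` between head pitch velocity and
  vertical head acceleration, and between head and trunk pitch velocity,
  via a Welch estimate over a 1024-sample window split into exactly 5
  Blackman sub-segments of 512 samples advanced by 128 samples
  (consecutive overlap 384), evaluated at the bin nearest the predominant
  frequency. A single periodogram would make K² ≡ 1; five strongly
  overlapped sub-segments keep the 100/512 Hz resolution while making the
  estimate informative (at the cost of a known positive bias under
  independence, which the tests reproduce against a Monte-Carlo oracle).
* **Phase difference** between vertical head acceleration x and pitch
  velocity y: the lag of the cross-correlation peak of mean-removed,
  Blackman-weighted 512-sample segments, searched within ±1 period of x
  (period from the first autocorrelation peak) and refined by parabolic
  interpolation — at 100 Hz an integer-sample lag quantizes phase at
  ~6.7°/sample near 1.9 Hz, too coarse for the ~±3° scale of interest.
  Phase = −2π·lag/period, then corrected by −π/2 and wrapped to (−π, π].
  The correction makes acceleration-vs-velocity phases comparable with the
  displacement-vs-angle phases of the laboratory literature: integrating a
  sinusoid shifts phase by −π/2, hence 2(−π/2) − (−π/2) = −π/2.

### Summaries

Every measure is summarized against head vertical predominant frequency,
whose values lie on the 512-sample spectral grid; the summary bins are
those grid frequencies inside the gate. Boxplot statistics use linearly
interpolated quartiles and 1.5·IQR whiskers (most extreme sample within
the fence; outliers counted, not listed). The strength of the frequency
dependence is the Kruskal–Wallis effect size η² = (H − k + 1)/(n − k)
with tie-corrected H; labels: small < 0.04, intermediate ≤ 0.11, large
above. Routine pairwise Welch and paired t-tests are written to the run
log only.

## Synthetic-data generator

No public recordings exist for this protocol, so the generator emulates
the statistical structure the analysis relies on; every downstream claim
in the test suite is made against its ground truth.

* **Cadence.** Step frequency is drawn per bout from N(1.86, 0.23) Hz
  (clipped to [0.5, 4]) with small AR(1) per-step jitter (SD 0.02 Hz,
  lag-1 correlation 0.9). The per-bout frequency-autocorrelation model is
  a free choice; nothing downstream depends on its details.
* **Waveforms.** Per axis, gait acceleration is a harmonic series in the
  stride phase θ (θ = 2πm at step peaks): even (step) harmonics k·f in
  cosine phase with geometric amplitude decay (ratio 0.4 over 10
  harmonics), odd (stride) harmonics (2k−1)·f/2 injected in quadrature.
  The quadrature trick makes odd content vanish exactly at step peaks, so
  every peak has the same height and clears the detector's height and
  prominence thresholds with margin, while the even/odd power split — and
  hence the harmonic ratio — is set freely per axis (defaults: even:odd
  4:1 vertically, 3:1 AP, 1:2.5 ML). ML keeps its largest single spectral
  line at the step frequency (so the cycling exclusion's V-vs-ML frequency
  match holds for walking, as it must for real walking data) while still
  carrying substantial stride-locked content; real ML acceleration is more
  strongly stride-fundamental than this.
* **Amplitudes.** Per-bout lognormal scaling (σ = 0.2, mode 1, clipped to
  [0.7, 2.5]) of a vertical RMS with mode 0.3 g; AP and ML at 0.8× and
  0.6× the vertical. This yields the right-skewed session RMS
  distribution with mode ≈ 0.3 g.
* **Attenuation and pitch coupling.** The head's inertial acceleration is
  the trunk's scaled by (1 − AC) per axis (defaults 0.3/0.2/0.05 for
  AP/ML/V) plus independent sensor noise. Head (and trunk) pitch velocity
  is a tone at the step frequency whose offset is chosen so the corrected
  displacement-vs-angle phase equals the target (default −50°); its
  envelope-weighted mean is removed per bout so integrated pitch returns
  to baseline (otherwise short bouts accumulate a net pitch offset over
  hours).
* **Kinematic consistency.** Body pitch is the exact integral of the
  emitted pitch velocity; the accelerometer output is the tilted gravity
  plus the designed inertial acceleration in the sensor frame, and the
  gyroscope is the body rate rotated by the mounting. The orientation
  filter therefore faces exactly the coupling it faces on real data.
* **Bouts and confounders.** Bout lengths follow a discrete power law
  (Zipf-like, exponent 1.5, truncated to [2, 2000] steps), matching the
  observed log-log-linear decay of bout-length incidence; rests are
  lognormal (median ~6 s, minimum 2.5 s). With probability 0.08 a
  cycling-like block (15–40 s) is inserted: sharp pedal spikes at 1.4 Hz
  that pass the peak detector but with vertical RMS < 0.1 g and an ML
  tone at 2.7 Hz, so both exclusion criteria fire.
* **Protocol artifacts.** Each session starts and ends with a
  synchronized 3 g, 50 ms half-sine knock; a 5 s static posture and five
  1.5 rad/s forward-pitch nods at 0.8 Hz provide the calibration
  segments; sensors are mounted with configurable rotations (defaults a
  few degrees of roll/pitch, trunk yaw 0 since a nod-free trunk
  calibration cannot observe yaw); the head clock is offset 0.3 s and
  drifts at 1e−5 s/s; accelerometer noise 0.02 g, gyro noise 0.01 rad/s
  plus a 0.01 rad/s-per-hour bias ramp.
* **Orientation-only trajectories** for filter validation are yaw-free by
  construction (horizontal rotation vector from band-limited sinusoids,
  anchored at identity) with the exact analytic body rate via the right
  Jacobian of SO(3), so the emitted gyro integrates back to the truth to
  numerical precision and is directly comparable with the yaw-free filter
  output.

### What the generator does not emulate

Soft-tissue and sensor-mounting artifacts, turning and non-level walking,
stair gait as a distinct class, translation-induced centripetal
accelerations during calibration nods, non-stationary within-step
waveform changes, magnetic or temperature effects, and any heading
dynamics. Passing tests therefore demonstrate algorithmic correctness and
parameter recovery under the stated signal model — not clinical validity
on real recordings.

## Numerical and statistical choices

* Spectra are Parseval-normalized periodograms; only ratios and argmaxes
  are consumed downstream, so the convention is free (asserted by test).
  The DC bin is excluded from argmaxes so gravity residuals cannot win.
  Segments overrunning recording edges are zero-padded symmetrically.
* RMS for the magnitude summaries is computed on unwindowed samples; the
  AC ratio uses Blackman-weighted RMS.
* Ties in peak detection break toward the earlier sample; harmonic bins
  are the single nearest grid bin (half-width configurable); coherence is
  read at the nearest bin, not interpolated.
* Short NaN runs (≤ 0.5 s) in input files are linearly interpolated and
  longer runs are fatal; non-uniform sampling is rejected, never
  resampled.
* η² may be slightly negative under the null; it is reported as computed
  and labeled "small". All-tied data raise an error rather than NaN.
* The sequential gravity-filter loop is compiled with numba when
  available (pure-Python fallback), making 10-h sessions tractable.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use 600-s sessions for
parameter-recovery checks (≈ 500–1000 steps), 60-s trajectories for
filter validation, and 2-h sessions for the frequency-distribution check.
Because cadence is drawn per bout, a single session has few effective
degrees of freedom for the frequency sample mean (the bout-length law is
heavy-tailed); the distribution check therefore pools several independent
2-h sessions — comparable to one subject-day of wear time — rather than
lengthening any single session.

## Known limitations

* The trunk's yaw mounting is unobservable without a trunk nod; a real
  deployment with a twisted trunk sensor would mix AP and ML.
* The cycling-exclusion thresholds are fitted to the synthetic cycling
  generator, not to real cycling data.
* Predominant-frequency estimates for 2-step bouts are biased low by
  ~0.25 Hz: the 5.12-s analysis window is mostly non-locomotor. This is a
  property of the short-time-spectrum method itself, not of the
  implementation; per-bout summaries for very short bouts should be read
  accordingly.
* Phase differences assume x is quasi-sinusoidal; strongly multi-harmonic
  x biases the autocorrelation period estimate slightly (the Blackman
  taper shifts the first autocorrelation peak by ≲ 1 % of a period).
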