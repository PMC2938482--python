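# Methods

This note documents the models, parameter choices and numerical decisions
behind `fbt`, and states what the synthetic generators do and do not
emulate — hence what a passing test suite does and does not demonstrate
about real recordings.

## Acoustic model and cue extraction

### Spherical-head model

The generator (`fbt.synth.HeadModel`, `simulate_head_ir`) treats the head
as a rigid sphere of effective radius $a$ in a free field. The interaural
delay follows the Woodworth formula

$$\tau(\theta) = \frac{a}{c}\,(\sin\theta + \theta), \qquad |\theta| \le 90^\circ,$$

with $c$ the speed of sound (343 m/s) and $\theta$ the source azimuth in
the head frame. The formula is frequency independent — consistent with
ear-canal measurements in small mammals, where ITDs vary little with
frequency — and peaks at $\frac{a}{c}(1 + \pi/2)$ for a source at ±90°.
Beyond ±90° the angle is mirrored ($\theta \to \pm(180^\circ - |\theta|)$)
so cues fall back toward zero directly behind the head; real pinnae break
this front/back symmetry, the sphere cannot.

Head shadow is modelled per frequency band as a first-order level
difference $\mathrm{ILD}_b(\theta) = s_b \sin\theta$ dB, split
symmetrically across the ears ($\pm s_b \sin\theta / 2$ dB). The strengths
$s_b$ default to 4.3 dB for 0.75–1.5 kHz and 10.9 dB for 4–8 kHz,
reproducing the qualitative ordering that shadow grows with frequency.
The jacket-pocket microphone site is derived from the ear-canal model by
shrinking the radius (×0.89) and the shadow strengths (×0.92), reflecting
pocket microphones that sit slightly closer together and less in the
head's shadow; both factors are configuration, not constants.

**Calibration, not anatomy.** The default radius (25.35 mm) is chosen so
the ITD half-range over a ±150° grid is 190 µs — a mid-cohort value for a
ferret-sized head. It is an arbitrary calibration of the *effective*
acoustic radius, not a measured species constant.

Impulse responses are synthesized as windowed-sinc (Blackman) fractional
delays, band-limited per shadow band by the same zero-phase Butterworth
used in analysis, so sub-sample ITDs are representable at the 80 kHz
default sample rate (sample period 12.5 µs). The construction is exactly
mirror-symmetric: negating the source angle swaps the channels, so
generated cues are odd functions of azimuth to machine precision, and
rotating the head frame (`head_orientation`) is exactly equivalent to
counter-rotating the source.

### Golay measurement

`generate_golay_pair` builds complementary codes by the doubling recursion
($a' = a \,\|\, b$, $b' = a \,\|\, {-b}$ from $a = b = [+1]$); the sum of
the two autocorrelations is $2N\delta$, verified numerically for orders
1–12. `estimate_impulse_response` correlates each recording with its own
code and averages; for a noiseless LTI system the recovery is exact, and
the test suite holds it to 1e-9 relative error on random sparse systems.
The pipeline's cue stage runs this full chain (convolve codes through the
simulated head, deconvolve, then extract cues) rather than reading cues
off the model directly.

### ITD, ILD and curve handling

* **ITD** (`compute_itd`): integer-lag cross-correlation peak within a
  ±1000 µs default search window, refined by 3-point parabolic
  interpolation. Parabolic refinement is cheap and adequate at 80 kHz;
  fractional delays of band-limited signals are recovered within 2 µs
  (validated against a 64× upsampled correlation oracle). With
  `interpolate=False` whole-sample delays are recovered exactly. Ties
  between equal peaks break toward the smaller absolute lag. Positive
  ITD/ILD mean the right ear leads / is louder; negative angles are to the
  left. The source never states cue polarity for this paradigm — this
  choice makes cue curves increase over frontal angles.
* **ILD** (`compute_ild`): zero-phase (forward–backward) order-4
  Butterworth band-pass, then $20\log_{10}$ of the RMS ratio. Zero-phase
  filtering cannot bias a delay estimate if applied before
  cross-correlation. A band covering (0, fs/2) means "unfiltered". Imposed
  broadband gains are recovered within 0.05 dB; a gain confined exactly to
  an analysis band is recovered within ~0.06 dB of the Parseval
  band-energy oracle because the filter's transition bands leak a little
  unweighted energy.
* **Half-ranges** (`summarize_ranges`): a "±X" cue range is read as half
  of (max − min) over the measured angle grid; whether published ranges
  mean this or max|cue| is ambiguous, and the half-range reading is used
  consistently. Curves are summarized across a cohort by min / median /
  max of per-curve half-ranges.
* **F0 alignment** (`align_zero_crossing`): the angle at which the cue
  crosses zero is found by linear interpolation between the bracketing
  grid points and subtracted from all angles; cue values are untouched. If
  the cue crosses zero more than once (possible on noisy curves) the
  crossing nearest 0° is taken. A curve that never changes sign has no F0
  and raises an error.
* The low analysis band is 0.75–1.5 kHz by default; reports of 0.75–1.25
  kHz exist for jacket measurements and the band edges are therefore
  plain configuration.

## ECAP analysis

### Forward-masking model

The generator emits four frames per stimulus level on a shared
post-probe time base (20 kHz, 36 samples ≈ 1.8 ms): probe alone
(artifact + neural + noise), masker+probe (masker and probe artifacts
only — complete masking), masker alone, and no stimulus (baseline). The
probe artifact decays exponentially ($A e^{-\lambda t}$, defaults 500 µV,
2 /ms); the masker artifact is a scaled copy. All artifact and baseline
terms are strictly additive and identical wherever the same stimulus
appears, so the canonical subtraction $A - (B - C) - D$ cancels them to
machine precision. Real systems use a vendor-specific "modified"
forward-masking variant whose details are not public; the canonical
four-frame arithmetic is implemented and is exact under the stated
additivity/complete-masking assumptions. Incomplete masking, amplifier
saturation and nonlinear artifacts are *not* modelled, so the
cancellation-exactness results say nothing about those failure modes.

The neural response is a fixed biphasic template (negative trough at
0.3 ms, positive peak at 0.6 ms, Gaussian lobes of width 0.06 ms)
normalized so its sampled peak-to-trough span is exactly 1, scaled by
$\max(0,\; m\,(L - L_{thr}))$ — exactly piecewise linear in level with a
hinge at threshold. Whether P1 precedes or follows N1 varies with
recording convention; the extremum windows are configurable (defaults
0.10–0.45 ms for N1, 0.45–1.0 ms for P1).

### Threshold and stability

P1–N1 is max-over-P1-window minus min-over-N1-window, clipped at zero.
Growth-function points with amplitude strictly below the 30 µV noise
floor are excluded (the boundary value is retained); an ordinary
least-squares line through the remainder gives the threshold as
$-b/m$, with errors raised for fewer than two retained points or a
non-positive slope. OLS (not a robust fit) is deliberate: the procedure
being reproduced is a plain linear regression.

Stimulus level is kept as abstract "stimulus-level units" throughout —
device current units and dB-re-threshold conventions coexist in this
field, and the unit is metadata, not arithmetic.

The default generator slope is 20 µV per level unit, typical of animal
ECAP growth functions that reach several hundred µV within tens of units
of threshold; it places the 30 µV noise floor about 1.5 units above
threshold. With 10 µV frame noise (post-sweep-averaging residual), six
levels at threshold +10…+60, the median absolute threshold error over 200
sessions is ≈ 0.8 units; noiseless recovery is exact to 1e-6 because the
normalized template makes measured amplitude exactly proportional to the
injected one, and a uniform scale does not move a line's zero crossing.

`threshold_stability` fits threshold-vs-day OLS slopes per
(electrode, ear) series and applies a two-sided one-sample t-test to the
slopes against zero. On flat series with observation noise the test
rejects at the nominal ~5% rate (validated over 500 replicates). Identical
slopes (zero variance) are handled explicitly: t = 0 / p = 1 if the common
slope is zero, else a degenerate certain rejection.

## Impedance bookkeeping

The generator rises from baseline (1.9 kΩ) to plateau (8.5 kΩ) along a
logistic in post-operative day, renormalized so day 0 equals the baseline
exactly and the plateau is the asymptote; the default midpoint (day 9)
and scale (2 days) complete the rise within the first three post-operative
weeks. Per-electrode plateau offsets (default zero; the demo pipeline uses
an apical-high / mid-array-low profile) and a common-ground / monopolar
mode pair are supported. Noise is Gaussian, truncated at 3σ, so healthy
variability cannot cross the failure boundaries — failures enter only as
explicitly planted events that force values to 25 kΩ (open) or 0.5 kΩ
(closed) from their onset day onward. The electrode list includes the
extracochlear reference (`EC`) by default, giving 8 positions per ear.

Classification: < 1 kΩ closed-circuit, > 20 kΩ open-circuit, boundaries
inclusive-functional (published failure rules are strict inequalities).
Open/closed measurements are excluded from every mean, sd and profile.
"Prior to day 5" is read as days 0–4 inclusive and "between 16 and 20
days" as 16–20 inclusive. The functional percentage is reported both at
position level (every measurement of an (animal, ear, electrode) in
range — the primary statistic) and at measurement level, since published
percentages are ambiguous between the two.

## Orienting responses

The angle series is the bearing of the per-frame displacement vector
relative to the initial heading; frames without displacement hold the
previous angle. The initial heading is the mean pre-onset displacement
direction over 5 frames; a marker that is stationary at the start spout —
the designed case — falls back to the arena's 0° axis, and an explicit
`initial_heading_deg` override supports arbitrary arena rotations
(outputs are invariant under a rigid rotation of coordinates plus
heading). Bearings use the circular (unit-vector) mean so wraparound near
±180° is harmless; for realistic bearings it coincides with the
arithmetic mean.

The latency rule needs a per-frame magnitude criterion that published
descriptions omit; the default is 1°/frame, configurable. Latency is the
*third* frame of the first run of three same-direction supra-threshold
frames after onset, so the rule reports two frames after the first moving
frame. The generator therefore treats its `latency_ms` as the
rule-defined (operational) latency and places the kinematic onset three
frame intervals earlier, with a raised-cosine angular rise (0.15 s) steep
enough that the first three frame steps exceed 1° for bearings of a few
tens of degrees. Noiseless recovery is then exact to the frame. For
configured latencies under ~50 ms the kinematic onset clamps at the
stimulus and the rule floor (3 frames) applies. The marker translates at
constant speed along its current bearing — a walking approach, not a
head rotation about a neck pivot; only the angle-versus-time course is
meant to be realistic.

## Pipeline, determinism and problem sizes

`run_pipeline` draws a child `numpy` generator per stage from
`default_rng([seed, stage_index])`, so stages are independent and a rerun
is byte-identical (verified file-by-file via SHA-256 in the manifest; the
manifest itself contains no timestamps). The demo cohort sizes — 16
ear-canal and 3 jacket cue configurations over ±150° in 10° steps, 7
electrodes × 2 ears × 13 weekly ECAP sessions, 4 animals × 2 ears × 8
electrodes × 90 days × 2 modes of impedance, 20 + 20 orienting trials, 10
ambient-level measurements — mirror the scale of a real chronic-study
dataset while keeping a full run in single-digit seconds. Cohort cue
half-ranges are drawn from triangular distributions parameterized by
[min, median, max] so the simulated spread matches reported cohorts,
which skew toward smaller heads.

## Known limitations

* The acoustic model has no pinna spectral cues, no elevation dependence,
  no room reflections and no measurement noise; cue-recovery tolerances
  reflect estimator accuracy, not robustness to real acoustics.
* The ECAP model has no refractoriness, latency-vs-level shifts, or
  masker-interval effects; the impedance model is a phenomenological time
  course, not an electrode–tissue interface model.
* Orienting trajectories are single-marker kinematics; no video
  processing, and no psychometric analysis of the behavioural task.
* Statistical routines (OLS, t-test) are scipy's; the package adds the
  domain rules around them, not new statistics.
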