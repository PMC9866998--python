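# Methods

This note records the models, conventions and numerical choices behind
`freegait`, and what the synthetic test bed does and does not establish.

## Signal model and conventions

Time is seconds from the recording start; intervals are half-open
`[start, end)`.  Unit conversion uses standard gravity 9.80665 m/s² exactly.
Recordings are assumed uniformly sampled at the nominal rate (default
100 Hz); the CSV reader interpolates small timing gaps onto the uniform grid
and logs a warning when more than 1% of intervals are oversized, because the
wavelet differentiator assumes uniform sampling.

**Vertical axis and the sign of a_v.**  Over a candidate bout, the vertical
direction is the signed device axis whose mean is closest to +1 g (an error
is raised if no axis is within 30° of gravity).  Gravity is removed by
subtracting the bout mean.  The dynamic part is signed *positive in the
direction of gravity* (down-positive).  This choice is substantive: for any
smooth pendulum-consistent CoM trajectory the height is minimal at heel
strike, so an up-positive a_v has *maxima* there; the convention that
initial contacts are *minima* of the CWT-differentiated signal is only
coherent with a down-positive a_v.  All magnitudes (excursions, lengths,
SDs) are invariant to this choice.

## Walking-bout extraction

Upright: the nominally-vertical axis low-passed below `1/upright_win_s` Hz
(default 0.5 Hz, 2nd-order zero-phase Butterworth) must exceed
`cos(45°)·g`.  Moving: the sliding 1 s standard deviation of the
acceleration magnitude must exceed 0.1 m/s².  Candidate bouts are maximal
runs of upright-and-moving with gaps ≤ 2 s merged and runs < 10 s dropped,
then confirmed by requiring ≥ 4 alternating initial contacts from the event
detector.  These four thresholds are not fixed by the underlying method and are
standard actigraphy heuristics; all live in `PipelineConfig`.  Windows are
anchored at each bout's start (default 30 s); a short tail is discarded.

The 0.1 m/s² stillness threshold implies a well-posedness condition on
noise: broadband sensor noise must stay below it for standing to be
classifiable at all.  The synthetic generator's default noise (0.05 m/s²)
respects this; modern logging accelerometers sit near 0.01 m/s².

## Event detection

The chain is: cumulative trapezoidal integration of a_v → linear detrend →
differentiation with a first-derivative-of-Gaussian kernel (a one-scale
Gaussian CWT) → minima = initial contacts; a second identical
differentiation → maxima = final contacts.  The differentiator is
implemented with `scipy.ndimage.gaussian_filter1d(order=1)`, which is
phase-exact and sign-correct (`pywt`'s `gaus1` CWT equals it up to a sign
flip and a half-sample shift; the two operators are cross-checked in the
test suite).

**Scale.**  The Gaussian sigma is set so the kernel's centre frequency
`1/(2πσ)` matches the dominant spectral peak of the integrated signal in
0.5–3 Hz (Welch periodogram); a fixed frequency can be configured.  If no
peak exists the scale falls back to 2 Hz with a logged warning.

**Peak picking.**  Extrema need prominence ≥ 0.2 × the robust signal
amplitude (√2·1.4826·MAD — the amplitude of the dominant sinusoid,
insensitive to bout-edge transients) and separation ≥ 0.25 s.  Events
within 0.5 s of the series edge are discarded, so bouts are padded with 1 s
of neighbouring recording before detection and events are then clipped back
to the bout; without the pad, contacts at the bout boundary are
undetectable in principle.  Initial-contact positions found at the
step-frequency scale are refined at half that scale within ±15% of the
median inter-event interval (coarse-to-fine), because heavy smoothing
biases minima positions next to asymmetric baselines — with alternating
0.50/0.60 s steps the single-scale positions compress the asymmetry by
~25%; refinement removes the bias while the coarse pass keeps noise
robustness.  Sub-sample positions come from a parabolic fit.

**Pairing.**  With T the median inter-IC interval, each IC is matched to
the first unused FC in `(IC + 0.1T, IC + 0.9T)`.  That FC is
physiologically the toe-off of the *previous* foot, so the temporal stage
computes same-side stance as `fc[i+1] − ic[i]` and swing as
`ic[i+2] − fc[i+1]`; stance + swing then equals the same-side stride
exactly.  More than 25% unmatched events marks the bout low-quality.  The
first side is unknowable from one lumbar sensor (default "L",
configurable); asymmetry is invariant to it.

## Spatial model

Per step, a_v is doubly integrated and the CoM excursion is
`h = max − min` of the displacement over `[IC_i, IC_{i+1})`; step length is
the inverted-pendulum chord `2·sqrt(2·l·h − h²)` with leg length `l`
(default 0.9 m — a required subject parameter, not hidden in the code), and
step velocity is length/time.  No calibration multiplier is applied to the
pendulum lengths.  Integration drift is controlled by a zero-phase
4th-order Butterworth high-pass at 0.5 Hz applied to velocity and
displacement.  A per-step linear detrend of velocity — a plausible
alternative — is *not* used: the pendulum vertical velocity is itself
nearly linear within a step, so a per-step fit subtracts the signal itself
(in simulation it destroys ~80% of the excursion).  The high-pass needs
about `2 / cutoff` s to settle, so per-step spatial estimates within ~4 s
of a series edge are less accurate; accuracy statements below refer to
settled steps.  Undefined values (too-short steps, `h ≥ l`) are NaN and are
excluded from summaries, never imputed.

## Summaries, domains, anomalies

Within a window: mean over defined values; variability = sample SD
(ddof = 1, configurable — windows hold only ~57 steps); asymmetry =
|mean(L) − mean(R)| with sides by alternation.  Windows with fewer than 10
steps are dropped with a logged reason.  The 13 quantities map one-to-one
onto the four domains (Pace: mean step velocity/length; Rhythm: mean
step/swing time; Variability: five SDs; Asymmetry: four asymmetries — step
velocity asymmetry is not part of the model).

Anomalous steps are flagged per characteristic when
`|x − median| > k · 1.4826 · MAD` (default k = 3).  When the MAD is zero
but the data are not constant, the scale falls back to 1.2533 × the mean
absolute deviation; constant data yield no flags.  No standard rule exists for what counts as an anomalous step; this
median/MAD rule is this package's own concretization and is documented as
such.
Review manifests rank windows by flag count, then maximal score, then start
time, and carry a configurable constant offset onto the video timeline
(clock synchronisation between IMU and camera is out of scope).

Context labels are attached by maximal temporal overlap; a window covered
less than 50% is "unknown", and overlap ties go to the later-starting label.

## The synthetic generator

The generator emulates the signal structure the pipeline assumes, not a
gait lab: the CoM height is a chain of circular pendulum arcs (radius = leg
length, chord = per-step length, constant horizontal speed within the
step), and the vertical acceleration is the *exact* second derivative of
that trajectory after Gaussian smoothing of the heel-strike kinks
(`transition_sigma_s`, default 0.01 s).  Two properties follow:

- the double integral of the generated a_v reproduces the constructed
  trajectory, so the analysis-side reconstruction is testable against an
  analytic truth (settled per-step error < 1%);
- the smoothed velocity reversal at each contact is a strong (~3 g peak,
  ~4 m/s² after CWT smoothing) transient phase-locked at the contact
  instants — the step-frequency power that real lumbar signals carry.  A
  bare arc chain with the reversals simply omitted has almost no power at
  the step frequency (±0.12 m/s² at default geometry) and is undetectable
  under realistic noise, which is why the reversals are retained in
  smoothed form.

The kink smoothing raises the trajectory's minimum by `V·σ·√(2/π)` (V the
boundary fall speed), so the constructed excursion is ~3 mm short of the
ideal arc height and the recovered step length sits ~3–4% below the true
chord — inside the 5% accuracy claimed for the inversion, and the reason
`transition_sigma_s` is kept at 0.01 s.  Ground-truth toe-offs are placed
0.15 s after the next contact (stance − step time in level-ground data);
they are labels, not trajectory features.  Schedules compose walking with
standing (gravity on the vertical axis) and lying (gravity horizontal)
segments; gravity reorientations are cosine-tapered over 1 s to avoid
integrator shock, while walking dynamics start at full amplitude (a first
step is a real step).  Defaults are typical impaired level-ground walking:
step time 0.524 s, step length 0.562 m, 100 Hz, ±8 g-scale signals.

What passing tests therefore show: the pipeline inverts its own generative
model accurately and robustly (event recovery verified up to 0.5 m/s² added
white noise).  What they do not show: performance on real gait, which
contains arm-swing and torso dynamics, asymmetric impact shapes,
non-stationary cadence, and sensor artefacts the generator does not model;
stair ambulation in particular violates the pendulum model, and the
package (like the method it implements) reports stair-bout spatial values
that should be treated as proxies, not measurements.

## Sizes and determinism

The test suite and acceptance checks use 30–40 s bouts (57–80 steps) and
20–50 replicate simulations per recovery claim — large enough for the
stated tolerances (SD recovery at n≈57 has ~10% sampling error; 20 seeds
bring the mean within a few percent) while keeping the whole suite under
half a minute.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); the analysis pipeline itself is
deterministic, so identical inputs and config reproduce identical outputs
byte-for-byte, and every dropped event, step or window is accounted for in
the run record.
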