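# Methods

## Signal model and radar geometry

An FMCW chirp sweeps 58–63.5 GHz (bandwidth b = 5.5 GHz) in tc = 64 µs; 32
ADC samples per chirp, 256 chirps per frame, pulse repetition time 4 ms.
Closed forms used throughout: range resolution Δr = c/(2b) ≈ 2.7 cm, centre
frequency fc = f0 + b/2 = 60.75 GHz, wavelength λ = c/fc ≈ 4.94 mm, maximum
range fs·tc·c/(2b) = n·Δr ≈ 87.3 cm, slow-time rate sps = 1/PRT = 250 Hz,
beat frequency fB = 2br/(c·tc), and the phase-to-displacement factor
t = (λ/2)/(2π)·10⁶ ≈ 392.98 µm/rad. Neither fs nor tc appears in a printed
configuration; the simulator fixes tc = 64 µs and defines fs = n/tc, which
makes the maximum range independent of the tc choice. c defaults to 3·10⁸ m/s
so the derived constants round to the conventional printed figures; the
exact value is selectable. The target defaults to the bin-1 centre range
(one Δr); a wearable actually sits ~3 mm from the skin — far below Δr — and
no attempt is made to model sub-bin leakage loss quantitatively.

## Synthetic data: what it emulates and what it does not

Each beat is the sum of three Gaussian bumps at fixed fractions of the beat
period — systolic peak (centre 0.15, width 0.095, height 1.0), dicrotic
component (0.36, 0.055, 0.42) and diastolic hump (0.52, 0.15, 0.35) — with
the peak-to-trough excursion normalised to `amplitude_um` (default 50 µm at
72 bpm). These widths were chosen so the morphology carries the standard
landmarks (fast upstroke, shallow notch trough near 29% of the beat,
diastolic shoulder, a single prominent foot) and segments into exactly one
beat per cardiac cycle between 45 and 100 bpm; narrower components produce
deep non-physiological mid-beat valleys that a foot detector cannot
distinguish from beat boundaries.

Raw frames follow the received-chirp model: sample i of chirp m at antenna k
is `a_tx·a_rx[k]·cos(2π fB i/fs + (4π/λ)(r0 + d_m) + φ_k) + clutter + noise`
with φ_k the arrival-angle phase (antennas 1 and 3 form the λ/2 uniform
linear pair, so φ₃ − φ₁ = π sin θ). Static I/Q offsets (the circle-fit "DC"
terms) are injected as a static quadrature tone at the same beat frequency —
i.e. clutter in the same range bin, carrying the same arrival-angle phase as
the pulsatile return since it reflects off the same skin patch. A constant
ADC offset would only populate the DC bin, which the per-chirp mean removal
empties. Oscillator phase noise is modelled as an optional slow random-walk
phase plus white additive sample noise (no published spectrum to match).

Not emulated: electromagnetic scattering and skin reflectivity, multi-target
clutter, breathing and motion artefacts, beat-to-beat morphology and rate
variability, and the unexplained waveform inversion seen in real recordings
(an `invert` flag reproduces the symptom without a physical model). Passing
tests therefore demonstrate the correctness of the processing chain on its
own signal model, not performance on real wrist recordings.

## Range processing

The range FFT runs per chirp along fast time with the per-chirp mean removed
first (switchable): the pipeline uses the first non-DC bin, and mean removal
keeps DC leakage out of it. No window is applied (none is specified; a
window argument exists). The spectrum is scaled by 2/n so a unit-amplitude
fast-time cosine at a bin centre gives a unit-magnitude bin value, and
non-negative-frequency bins are retained. The 32-sample FFT is not
zero-padded.

## Direction of arrival

Snapshots are all 256 chirps of one frame (the most recent by default) from
antennas 1 and 3 at bin 1. The range-FFT bin of a real cosine carries
exp(+jψ) whereas the steering model a(θ)ₖ = exp(−jπk sin θ) assumes a phase
lag across the array, so the snapshots are conjugated (the negative-frequency
image) before forming R = XXᴴ/N. The signal subspace is the eigenvector of
R's largest eigenvalue (one target; a two-element array can resolve at most
one). The minimum-variance weights use the subspace-projected steering
vector in the numerator and the *unprojected* vector in the normalisation,
`w = R⁻¹(AAᴴa)/(aᴴR⁻¹a)`: normalising by the projected vector instead
(aᴴ_proj R⁻¹ a_proj) makes the pseudospectrum of a rank-1 covariance peak
away from the source, because the projection collapses every steering vector
onto the same direction. A diagonal loading of 10⁻⁶·tr(R)/m is added before
inversion since a noiseless single-source covariance is exactly singular.
Grid: −40°…+40° in 1° steps; argmax ties break toward the smaller |angle|;
placement is accepted within ±10°.

## Displacement extraction

Per frame, Taubin's algebraic circle fit is solved by Newton–Raphson on the
characteristic polynomial of the normalised moment matrix of
(i, q, z = i² + q²), starting from root 0 with tolerance 10⁻¹² and at most
20 iterations; the circle follows from the eigen direction of the converged
root, with the data centroid restored. Fits are smoothed by a running
average over the last 30 frame circles. A fit whose RMS residual exceeds 10%
of its radius is rejected as a blob rather than an arc — fitting a circle
through a noise cloud yields a radius comparable to the cloud itself, and
dividing by it amplifies phase noise enormously; rejected frames reuse the
previous smoothed circle, or an origin-centred circle of RMS-radius before
any credible fit exists (a static return then demodulates to a constant
phase, which the band-pass removes).

Compensated points ((I − a) + j(Q − b))/r are demodulated with the
two-argument arctangent (the single-argument form cannot reach [−π, π]),
unwrapped over the full concatenated multi-frame series (preserving
continuity at frame borders), band-passed 0.75–5 Hz with a 4th-order
Butterworth applied forward-backward — zero-phase filtering preserves the
feature timings (SUT, TR) that a causal filter would delay; a causal option
exists — and scaled to micrometres.

Known limitation: when the arc subtended per frame is small relative to the
additive noise (SNR below roughly 40 dB at 50 µm amplitude), the fitted
radius biases low and recovery degrades; this is the tiny-arc pathology
inherent to the approach, mitigated but not removed by the 30-circle
average.

## Pulse-wave analysis

Segmentation (no published method): feet are local minima at least 0.33 s
apart with prominence ≥ 20% of the trace's interquartile amplitude; one wave
per consecutive foot pair; durations outside 0.4–1.5 s (40–150 bpm) are
dropped. Inversion is flagged automatically by the skewness of the first
difference (upright beats have fast upstrokes, so the derivative is
right-skewed); the series is negated when the skewness is negative.

The reference wave is the [0,1]-scaled pointwise mean of (by default five)
clean beats, each linearly interpolated to 250 samples (1 s at sps; length
unspecified in any source). Quality is the Pearson correlation of the
[0,1]-scaled, length-interpolated beat with the reference; usable means
strictly greater than the threshold.

Calibration follows the two printed equations exactly; the first usable beat
defines the scaling factor, every beat is stretched about its own minimum,
so the first good beat's span equals refSYS − refDIA to machine precision
and all minima are preserved.

Feature detectors (geometrically defined in the source, detectors ours):
systolic peak = argmax; dicrotic notch = first local minimum after the peak
and before 80% of the beat, falling back to the most negative trough of the
smoothed first derivative, then to 40% of the decay; PR = curvature zero
crossing (second difference of a moving-average-smoothed wave, window
max(3, 5% of length)) closest to the systolic peak within [25% of the
upstroke, notch], excluding the peak; AIx = +1 when PR precedes the peak,
−1 after. Width crossings use the sample index of the sign change with
zeros counted positive and no sub-sample interpolation — consequently, on a
perfectly symmetric beat the diastolic crossing sits one sample later than
the mirrored systolic one. Beats missing a crossing at any level are dropped
from the feature table. Gender is encoded female = 0, male = 1, unknown =
0.5 (configurable).

## Regression

The trainer is a compact NumPy feed-forward implementation: He-initialised
weights, ReLU on hidden and output layers (blood pressure is positive; a
linear output is switchable), MSE loss, Adam (1e-3, β = 0.9/0.999), 50
epochs at batch size 10, a 15% validation split drawn deterministically from
the init seed, and an optional L1 subgradient (coefficient 1e-3, unstated in
any source) on the first-layer weights. The output bias is initialised to
the training-target mean so the mmHg-scale ReLU outputs start active — with
zero bias and unit-scale inputs, the outputs would begin deep in the dead
regime. Features are min-max normalised column-wise (constant columns map to
0 with a warning; bounds are retained for new data); targets stay in mmHg.
The 80/20 split uses a deterministic shuffle with random state 42.

Error reporting: "mean ± SD" statistics are computed on *absolute* errors
(matching the mean-average-error usage of the AAMI rule); signed-error means
are reported alongside. The headline RMSE pools both outputs; per-output
RMSEs are also emitted. AAMI bounds are inclusive (mean ≤ 5.0, SD ≤ 8.0
mmHg); BHS grades take the best row of the cumulative-percentage table whose
three bounds are all met.

The synthetic feature benchmark draws 3000 beats whose (SBP, DBP) are smooth
functions of age, gender, height, weight, systolic upstroke time and pulse
span plus Gaussian noise of σ = 3 mmHg; the remaining columns carry
physiologically plausible correlated values. The best grid model reaches the
σ noise floor (test RMSE ≈ 3 mmHg), and the full 42-model grid trains in
about a minute on one CPU at this size — chosen so the whole benchmark runs
comfortably at desk scale while still exercising every architecture.

## Pipeline

The batch pipeline aborts before extraction when the estimated DOA falls
outside ±10° (repositioning message). When no reference wave is supplied it
is built from the first five segmented beats of the recording itself — a
single-subject stand-in for the multi-subject mean reference. Artifacts
embed a SHA-1 hash of the full configuration so reruns detect config drift,
and the wave accounting (segmented = usable + discarded) is asserted on
every run.
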