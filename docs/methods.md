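# Methods

## Signal model

The rPPG premise is that cardiac pulsation and respiratory airflow
modulate skin luminosity periodically: blood volume changes appear most
strongly in the green channel, while the warming/cooling and perfusion
cycle of breathing shifts the skin along the green–red opponent axis,
i.e. CIELAB a\*. The package therefore reduces a tracked skin region to
two series — the per-frame spatial mean of G and of a\* — and treats rate
estimation as dominant-frequency estimation in a physiological band.
Series are linearly detrended and mean-centered first; slow illumination
drift otherwise dominates the 0.2 Hz band edge. Frames lost by the
tracker are filled by linear interpolation between valid neighbours
(zero-filling would inject broadband energy) and flagged.

sRGB → Lab uses the IEC 61966-2-1 de-gamma and the D65 white point (no
illuminant is identifiable for field recordings; D65 is the sRGB
reference). Conversion goes through scikit-image; its matrix constants
place the neutral axis within a few 1e-3 of a\* = 0, which sets the
tolerance used in the tests.

## Band-pass filtering and spectral estimation

"Second-order Butterworth" is read as an order-2 low-pass prototype
mapped to a band-pass — 4 poles total, the convention of mainstream DSP
toolboxes where a band-pass doubles the stated order. The filter is
applied forward-then-backward (`filtfilt`, reflection padding over three
filter lengths), giving zero phase and an effective magnitude response
|H(f)|²; a sinusoid at a cutoff is therefore attenuated to 0.5, not
0.707. Bands (Hz): HR 0.83–3.00; RR wide 0.33–3.1; RR low/medium/high
0.2–1.2 / 1.2–2.2 / 2.2–3.2. A frequency exactly on a class boundary
belongs to the lower class (half-open convention, matched by the
generator's labels).

Spectra are magnitudes of the Hann-windowed FFT, zero-padded to the next
power of two ≥ 4n and scaled so a unit sinusoid at a bin center reads
1.0. A one-minute record has 1/60 Hz raw resolution (±1 BPM), so the
in-band argmax is refined by three-point parabolic interpolation; on the
4× padded grid this brings worst-case recovery error on the default
synthetic scenes below 0.02 Hz (1.2 per-minute units), which the
acceptance suite asserts over 200 random scenes. The spectrum is
computed on the band-filtered series — the re-analysis step genuinely
re-filters per class. A peak sitting on the first or last in-band bin
raises an `edge_peak` flag (the true rate likely lies outside the band);
the flag is carried into the vitals provenance rather than triggering
any feedback loop.

## Feature engineering

Eight parameters per analyzed signal: mean, min, max and SD of the
*luminosity changes*, read as the first differences of the detrended raw
series (the phrase contrasts with the filtered-series statistics listed
separately; a config switch `changes="raw"` exposes the alternative
reading); mean and SD of the band-filtered series; peak frequency and
amplitude. Model 2 consumes all 16 = 8 cardiac + 8 band-specific
respiratory parameters — the symmetric choice that uses every engineered
parameter. Features are min–max scaled to [−1, 1] with parameters
learned on training rows only (tan-sigmoid input convention); constant
columns map to 0 with a warning, and test rows may legitimately fall
outside [−1, 1].

## Network training

Both models are two-layer feedforward nets with 10 tanh hidden units
(a configurable count; 10 is the default working point). The classifier
is trained against one-hot targets under squared error with a linear
output — the convention of MSE-based regularized trainers — and applies
the softmax at inference; the regressor standardizes each target column
on the training rows and inverts the transform at prediction.

Training is Levenberg–Marquardt on the Gauss–Newton Hessian
H = 2β·JᵀJ + 2α·I of F(w) = β·E_D + α·E_W, with damping μ (×10 on a
rejected step, ÷10 on acceptance, abort above μ = 1e10; start 0.005).
After each accepted step the evidence framework re-estimates the
hyperparameters: γ = N_w − 2α·tr(H⁻¹) (computed from the eigenvalues of
JᵀJ so every term stays positive when ill-conditioned), α = γ/(2E_W),
β = (n_obs − γ)/(2E_D), where n_obs counts scalar observations — rows ×
outputs, so a 94-sample two-target fit has 188 observations. Two
numerical guards matter in practice:

- γ is clipped to n_obs − 1 so at least one residual degree of freedom
  remains; with more parameters than observations the raw update drives
  β to zero and the data term vanishes.
- the first five epochs run as plain LM (α frozen at 0) before evidence
  updates begin; re-estimating α from an unfitted net otherwise locks
  small noise-free problems into the trivial weights-to-zero solution.

Initialization is layer-wise uniform scaled by 1/√fan-in from a seeded
generator; every stochastic routine takes an explicit seed. The 70/30
split is a seeded uniform permutation with round(0.7n) training rows
(134 → 94/40). The test suite asserts the analytic Jacobian against
central differences, monotone decrease of F over accepted steps, and
that the regularized trainer generalizes at least as well as plain LM on
noisy tasks (median over seeds).

## Tracking

Corners are minimum-eigenvalue (Shi–Tomasi) maxima inside the box,
thresholded at max(5% of the best in-box response, an absolute floor
that rejects uniform regions). Pyramidal Lucas–Kanade uses 3 levels,
15×15 windows, ≤30 iterations per level, convergence at 0.01 px —
defaults in line with common KLT practice. The box moves by the median
displacement of features that converged with an acceptable patch
residual; the median (rather than an affine fit) is robust to partial
occlusion by cage bars. If fewer than 25% survive, the frame is flagged
invalid, the box freezes at the last valid position and features are
re-detected inside it, retrying silently while the region stays
featureless (e.g. fully covered by a uniform bar). Thermal stacks reuse
the tracker on a stack-wide min–max normalized intensity image.

## Thermal statistics

Per-frame max, mode and population SD over the ROI; recording-level
mean/max/mode/SD of the per-frame maxima. Using the per-frame maximum
makes the summary robust to cold occluders crossing a large head ROI.
Temperatures are continuous, so the mode is binned at 0.1 °C —
thermometer display precision — with bins *centred on multiples of
0.1 °C* (so a constant 38.5 °C region has mode exactly 38.5) and ties
resolved to the lower bin. Invalid tracked frames are excluded from both
the per-frame list and the aggregates.

## Temperature–humidity index

THI = T − (0.31 − 0.31·RH)(T − 14.4) with RH a fraction; the bracketed
term is plain grouping (a ceiling would make the index discontinuous and
the published sheep form uses grouping), and RH as a fraction is forced
by 0.31 − 0.31·RH needing to stay in [0, 0.31]. Percent inputs in
(1, 100] are divided by 100 with a warning. Identities THI(14.4, ·) =
14.4 and THI(·, 1) = T, plus monotonicity in RH above 14.4 °C, are
asserted on a grid.

## Evaluation conventions

Through-origin regression reports the ordinary (centred) Pearson R — the
convention under which R and R² are usually quoted together — with the
uncentered variant exposed alongside. "95% confidence" outlier flagging
is implemented as the t-based *prediction* interval of the through-origin
fit, s²(1 + x₀²/Σx²) with n − 1 degrees of freedom; intervals on the mean
would flag far more than a few percent of noisy points. Classifier
reports give accuracy/error/MSE per training/testing/overall stage (MSE
against one-hot targets), the confusion matrix, and one-vs-rest ROC
curves swept over the softmax score.

## Synthetic scenes: what they emulate, and what they do not

A scene is a smooth seeded random texture (no photorealism attempted)
whose ROI carries base + amp·sin(2πft) modulations: cardiac in green,
respiratory in red — red–green opponency is what drives a\*, and planting
in red keeps the two channels separably testable. Per-pixel Gaussian
sensor noise is added in floating point *before* 8-bit quantization,
emulating sensor dithering: without it, sub-unit amplitudes vanish in
the quantizer and realistic rPPG levels would be untestable.

Default amplitudes come from the a\* Jacobian at mid-gray
(∂a\*/∂R ≈ +0.37, ∂a\*/∂G ≈ −0.57 per digital number) and typical rPPG
pulsatile scales: amp_hr = 0.4 DN (sub-unit, as real pulse signals are
on 8-bit sensors) and amp_rr = 3.0 DN, so the cardiac leak into a\* is
about 20% of the respiratory component — separation is physically
impossible to make perfect, and the suite asserts the <25% bound rather
than pretending otherwise. Noise presets: "default" σ = 2.0 DN,
"clean" σ = 0.5 DN (the smallest level that still dithers sub-unit
amplitudes). One-minute recordings at 30 fps (the RGB stream rate is not
fixed by the hardware spec; 30 fps satisfies Nyquist for 3.2 Hz with
margin); thermal stacks default to 9 Hz. The default cohort is 134
scenes, respiration frequencies uniform within each class band
(balanced classes ±1), heart rates uniform in 1.05–2.2 Hz, random
phases, labels 60× the planted frequency.

What the generator does **not** emulate: head motion coupled to
breathing, specular/illumination changes, non-sinusoidal pulse
waveforms, heart-rate variability within a recording, wool boundary
effects, or codec compression. Passing tests therefore demonstrate that
the analysis chain is correct and self-consistent at realistic
amplitude/noise ratios — not that field recordings of animals reach the
same accuracy.

## Problem sizes and runtime choices

Unit tests use 30-second, 48×36-pixel scenes; cohort-level checks use
the full 134-scene, one-minute cohort at 64×48 pixels with a 28×20 ROI,
which keeps a complete train-and-evaluate cycle around a minute on one
CPU while preserving the spectral resolution the method relies on. The
spectral-recovery property uses 200 one-minute scenes. Scene pixel
dimensions only set how much spatial averaging reduces per-frame noise;
the temporal behaviour that drives every estimate is unaffected.

## Known limitations

- The tracker assumes mostly translational ROI motion; large rotations
  or scale changes would need an affine model.
- Respiration classes whose true frequency sits within ~0.01 Hz of a
  band boundary are intrinsically ambiguous; misclassifications
  concentrate there (visible as the testing-stage accuracy dipping below
  the training stage on noisy cohorts).
- Medium-band respiration overlaps the cardiac band; when the cardiac
  leak into a\* rivals the respiratory amplitude the re-analysis can
  lock onto the heart rate. The default amplitude ratio keeps a 5:1
  in-band margin.
- The evidence updates use the Gauss–Newton approximation of the
  Hessian; far from a minimum γ is only an estimate of the effective
  parameter count.
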