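# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `ecapkit`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model

A stimulation *event* is a train of rectangular pulses with pulse
parameters (current `I` in mA, pulse width `pw` in µs, bipolar contact
pair, polarity — which contact is the current source — and waveform,
monophasic or biphasic with alternating polarity) and train parameters
(frequency `f` in Hz, duration in s). Time is in seconds from session
start; per-pulse latencies in ms from pulse onset; all windows are
half-open `[start, end)`.

The neural channels are modelled (and, in the generator, rendered) as

```
trace(t) = Σ_pulses [ stimulation artefact
                      + Σ_fibers amplitude_f · rec_f(I, pw, contact) · w_f(t − d_eff/v_f)
                      + muscle artefact (fixed 4–8 ms latency) ]
           + Gaussian noise
```

where `v_f` is the fiber's conduction velocity, `d_eff` the
stimulation-to-recording distance (reduced for anodic pulses by the
virtual-cathode shift, linear in the supra-threshold current), and `w_f`
a compact zero-mean biphasic waveform.

## Recruitment model (generator)

Recruitment follows a clipped logistic between the strength-duration
threshold and saturation:

* Lapicque/Weiss strength-duration law: `I_th(pw) = rheobase · (1 + chronaxie/pw)`;
  the saturation current scales with the same factor.
* The logistic describes the spread of axonal thresholds across the
  population, so it is clipped to exactly 0 at `I_th` and exactly 1 at
  `I_sat` (no axon fires below the smallest axonal threshold). Between
  the anchors the curve passes 0.5 at the midpoint. This also keeps the
  sub-threshold tail from injecting unmeasurable-but-nonzero recruitment
  into the physiological ground truth.
* Recruitment depends only on pulse parameters, never on train
  parameters — the pulse/train separation every downstream analysis
  relies on.

Default fiber populations (velocity chosen in the interior of the
non-overlapping classification bins; rheobase/saturation are long-pulse
asymptotes in mA; amplitude in µV):

| fiber | v (m/s) | rheobase | saturation | amplitude | width (ms) |
|-------|--------|----------|-----------|-----------|-----------|
| Aβ    | 50     | 0.06     | 0.145     | 40        | 0.30      |
| Aγ    | 22     | 0.15     | 0.60      | 15        | 0.40      |
| Aδ    | 11     | 0.25     | 0.90      | 8         | 0.60      |
| B     | 5.5    | 0.40     | 1.10      | 20        | 1.00      |

Chronaxie is 250 µs throughout; at 260 µs this places the 15 %-of-maximum
onsets near 0.15 mA (Aβ), 0.5 mA (Aγ) and 1.1 mA (B), the ordering seen
on porcine DRCs. The B amplitude is larger than its physiological size
relative to A fibers on purpose: its latency window is roughly eight
times wider than Aβ's, so equal *relative* measurement precision across
fibers requires more absolute signal. A second, higher-threshold Aγ
population, Aα (hidden inside the stimulation artefact) and C fibers
(not recruited below 2.5 mA) are available but off by default. Noise SD
defaults to 2 µV, making the SNR of a saturated Aβ eCAP ≈ 20.

The eCAP waveform is a Ricker (Mexican-hat) wavelet — zero-mean,
biphasic-with-sidelobes, peaked exactly at the latency, and with a
compact surround. An earlier difference-of-Gaussians draft was dropped:
its wide Gaussian surround leaked measurable energy across neighbouring
latency windows (most damagingly from the muscle artefact into the B
window), which no windowed estimator could undo.

The muscle artefact is rendered at a fixed centre of 5.0 ms (width
1.2 ms, inside the observed 4–8 ms band), independent of recording
distance, with gain proportional to Aβ recruitment — it is a far-field
laryngeal EMG signature, not a propagating volley.

## Physiology model (generator)

Per event, with `rec_f` the per-pulse mean recruitment:

* `ΔHR = α(f)·rec_Aγ − β(f)·N_B`, where `N_B = Σ_pulses rec_B(polarity)`
  is the recruitment-weighted per-train B-eCAP count — recruiting both
  polarities of a biphasic train doubles it — and `β(f)` is
  non-decreasing in frequency. Defaults: α = {5 Hz: 2.4, 10: 3.2,
  20: 4.0} BPM, β = {5: 0.20, 10: 0.30, 20: 0.45} BPM per eCAP,
  interpolated between keys. The count is recruitment-weighted rather
  than hard-thresholded so that ΔHR is exactly linear in (rec_Aγ, rec_B)
  at fixed train parameters, which is the structure the per-frequency
  plane fits assume.
* `ΔBR = −min(100, k·pulse_count·rec_Aγ)` %, `k = 0.5`.
* Twitches: one EMG burst (2.5–10 ms post pulse, damped oscillation)
  per pulse with amplitude `80 µV · rec_Aβ`; the ground-truth count
  treats a pulse as twitch-evoking when `rec_Aβ ≥ 0.05`.
* Spasm score: `0.004 · f · duration · rec_Aβ`, rendered as a scaling of
  the EMG noise floor in the second after train end so the measured
  post/pre L1 ratio equals `1 + score` in expectation.

Rendering choices that make the metrics observable by their own
estimators: heart rate ramps to its new level over 2 s, holds until
3 s after train end, then decays (τ = 5 s); R-peak times integrate the
instantaneous rate with 1 ms beat-to-beat jitter. The breathing-rate dip
holds until 3 s after train end — exactly the ΔBR metric's search
window — so at least one complete slowed breath falls inside it; with the
default baseline of 30 breaths/min this holds for dips down to −50 %,
which bounds the default grid's ground truth. Deeper dips (toward apnea)
are physically renderable but not measurable by any interval-based
breathing-rate estimator within the window; that is a limitation of the
metric, not of the generator.

Baselines: 90 BPM / 30 breaths/min, in anaesthetised-porcine range.

## Feature extraction choices

* **Per-epoch filtering.** Epochs are cut from the raw trace (truncated
  at the inter-pulse interval so an epoch never contains the next
  pulse), the blanked stimulus samples (default 0–1 ms) are replaced by
  a short ramp to the boundary value, each epoch is high-passed
  independently (5th-order Butterworth, 200 Hz, zero phase via
  `sosfiltfilt`), and the blanked samples are then zeroed. Filtering the
  whole trace instead lets the acausal filter transient of each pulse's
  artefact leak several ms into the *preceding* epoch, which breaks the
  train-parameter invariance of neurograms at high frequencies. A
  trace-level `preprocess_neural` (with optional pulse excision) is
  still provided for whole-trace work.
* **Noise-debiased window energy.** Averaging `n` pulses leaves
  per-sample noise variance `pulse_sd²/n` in the mean; the squared
  window norm is reduced by this expected noise energy, and energies
  within 3 standard deviations of the pure-noise level (Gaussian energy
  statistics, `Var = 2 Σ v_i²`) are censored to zero. Without the
  debias, wide windows (B spans ~10 ms) report a noise floor of tens of
  percent of the fiber maximum; without the censor, the half-normal
  residue of the debias leaves a spurious few-percent floor that
  corrupts regression on near-zero recruitments.
* **Velocity bins.** The textbook conduction-velocity ranges overlap
  (Aδ 5–30 m/s spans both Aγ and B); classification uses disjoint
  default bins Aβ [30, 70], Aγ [15, 30), Aδ [8, 15), B [3, 8),
  C [0.6, 2.0] m/s, configurable per session.
* **Virtual cathode.** For anodic pulses the extractor widens windows
  toward shorter latencies by a configured `2 mm/mA × I` shift rather
  than estimating the shift.
* **B decontamination.** For currents above 0.5 mA the B activation is
  recomputed on the difference between that current's mean response and
  the 0.5 mA reference response (noise variances add), cancelling the
  distance-invariant muscle artefact, which saturates with Aβ well below
  the B threshold. Currents at or below 0.5 mA are left unchanged.
* **Propagation validation.** A component seen on ≥ 2 cuffs is
  *propagating* when a single fitted velocity predicts every channel's
  peak latency within 0.1 ms; with cuffs at 50.0 and 54.5 mm a
  distance-invariant artefact misses the single-velocity fit by
  ~0.17 ms, while genuine eCAP latencies land within sample quantisation
  plus noise jitter (≲ 0.05 ms each).
* **Train-invariance MAPE** compares group means over their common
  support (higher frequencies give shorter epochs), symmetrised over
  reference order, excluding samples whose reference magnitude is below
  1 % of the reference peak.

## Thresholds, models, dosing

* Onset = first upward crossing of 15 % of the (per-session, per-fiber)
  maximum by the piecewise-linear interpolant; 85 % for saturation;
  nominal 3 mA when onset is never reached over the tested range;
  left-censored flag when the first tested current is already above the
  onset fraction. Post-maximum outliers (points sagging below 0.9 of the
  maximum after the maximum is reached) are dropped before threshold
  estimation.
* Parametric fits use bounded multi-start least squares (16 starts from
  data-driven ranges, seeded per call); the step-sigmoid split point is
  scanned over interior data points. A fit no better than a constant is
  flagged degenerate.
* The GP maximises the marginal likelihood plus Gamma(2, 1) log-priors
  on length-scale and signal amplitude (a weak Gamma(1.1, 1) prior keeps
  the noise SD positive), over standardised inputs/outputs, with four
  Nelder–Mead starts. Effective degrees of freedom are
  `tr(K (K + σ²I)⁻¹)` via eigendecomposition. The approximate F-test
  uses parameter counts for parametric fits and effective df for GP
  fits.
* ΔHR segmentation is optimised by grid search (pre ∈ {2, 5, 10} s,
  gap ∈ {0, 1, 2, 5} s, post ∈ {2, 5, 10} s) on the R² of an OLS fit of
  ΔHR on the main effects of current, pulse width, frequency and
  duration; ties break toward the smallest gap, then post, then pre.
  Because a window that clips the HR ramp scales all ΔHR values by a
  common factor, R² distinguishes candidates only through their
  signal-to-noise; for parameter-recovery comparisons against ground
  truth the package uses the segmentation matched to the generator's
  response latency (pre 5 s, gap 2 s, post 5 s).
* The twitch detector calibrates its threshold per event as
  mean + 5 SD of window norms from the 2 s of EMG before onset.
* Physiological DRCs used in alignment are the rectified
  adverse-direction magnitudes (bradycardia `max(0, −ΔHR)`, bradypnea
  `max(0, −ΔBR)`, mean twitch amplitude): the onset of the *adverse*
  effect defines the threshold, so a low-current tachycardia bump cannot
  masquerade as the bradycardia onset. Alignment tolerance defaults to
  10 % of the tested current range. Alignment is a plausibility marker,
  never a causal claim.
* Activation vectors match probe currents to the nearest tested current
  within 10 % relative tolerance; PCA is centred but not variance-scaled
  (all entries share the normalised-activation unit). Response surfaces
  are evaluated only inside the tested ranges. HR-plane fits append a
  (0, 0) → 0 anchor and average normalised activations across recording
  cuffs to halve predictor variance.

## Default study conditions and problem sizes

The default (biomarker) grid is 14 currents spanning 0.05–2.5 mA at
260 µs, monophasic cathodic from one longitudinal pair, at 10 and
20 Hz × 5 s, with the protocol's 30 s minimum between stimulations
(≈ 16 min of recording at 20 kHz neural sampling). The neural-focus
preset uses two pulse widths (130, 260 µs) and 3 s, 10 Hz trains with a
10 s gap (the 30 s minimum applies to stimulations affecting
physiology); the activation-vector preset probes ten contact-pair
locations at the five vector currents with per-contact excitability
scaling. Default frequencies divide the 20 kHz sampling rate so that
noise-free epochs are sample-aligned across train parameters.

## What the generator does and does not emulate

It reproduces the mechanistic skeleton the analyses assume:
strength-duration recruitment, conduction-velocity latencies, the
distance-invariant muscle artefact, pulse/train separation, polarity
asymmetries, frequency-dependent integration into ΔHR/ΔBR/EMG. It does
not emulate fascicular anatomy, electrode-tissue impedance drift,
anaesthesia depth, heart-rate variability beyond beat jitter, baroreflex
feedback, refractory effects, or inter-subject variability beyond what
the configuration exposes. Passing recovery tests therefore demonstrates
the pipeline's correctness under the stated model, not its performance
on real recordings.

## Known limitations

* Aδ activation is structurally contaminated by the muscle artefact
  (their latency windows overlap at ~50 mm), as in the real preparation;
  recovery assertions therefore target Aβ, Aγ and B.
* Measured ΔHR lags the true plateau by the RR-interval discretisation
  during fast transitions, giving a few-percent shrink of deep
  bradycardias.
* ΔBR cannot observe dips shorter than one slowed breath interval; the
  metric saturates near −50 % at the default baseline and windows.
* The rank of the DRC at its tied zero-prefix and noisy saturation
  plateau makes whole-curve rank correlations uninformative;
  monotonicity is asserted as bounded sag plus pointwise agreement with
  the generating recruitment.
* With a single stimulation location the latent-space stage is skipped
  (it needs ≥ 3 activation vectors).
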