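# Methods

This note documents the models implemented in `stgboundary`, what the
synthetic-data generator does and does not emulate, the numerical choices
behind each stage, and known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The gyrus model

The STG is modeled as a 1-D strip: position in mm from the anterior tip
(default length 100 mm, nodes every 1 mm). This replaces cortical-surface
meshes because the length analysis is intrinsically one-dimensional (1-mm
bins anterior→posterior). Two landmarks live on the strip: the *anatomical
landmark* (proxy for the posterior margin of Heschl's gyrus, default 70 mm)
and the *planted functional boundary* (default 68 mm) where the generating
clear-minus-noisy contrast crosses zero. The affine
`y = standard_offset − position` maps the strip onto the standard-space
anterior–posterior axis; defaults place the landmark at y = −30 and the
boundary at y = −28. The "posterior third" used by boundary detection is
[2L/3, L] of the full strip length — the natural reading of the search region given
that no other reference extent is defined for the label.

## Synthetic ECoG

Each strip electrode carries an ongoing 70–110 Hz process: a deterministic
carrier line (random phase; frequencies offset across electrodes over
82–98 Hz so that no two channels carry a coherent common line — a shared
line would re-enter every channel through the common average reference with
a random per-recording phase and bias band power by several percent) plus
optionally stochastic band-limited noise. A trial multiplies the *amplitude*
of this process by `sqrt(1 + (amp%/100)·env(t))`, so the in-band power
percent change follows `amp% · env(t)` exactly — the generative identity the
tests exploit. A single carrier line is used deliberately: several in-band
lines beat at their difference frequencies and ripple the short-window power
estimate, destroying the exact identity.

The burst envelope rises from 40 ms, reaches 1 by 180 ms, holds a 200 ms
plateau and decays with τ = 120 ms (onset latency < 100 ms, peak ≈ 200 ms
after auditory onset). The plateau is as wide as the spectral-analysis
window, so the peak of the smoothed estimate equals the generating
amplitude rather than being attenuated by the window.

Condition amplitudes vary along the strip as sigmoids (width 4 mm by
default, so the contrast flips within ~10 mm). A plain per-condition blend
would put the contrast zero-crossing slightly off the planted boundary
whenever anterior and posterior contrast magnitudes differ; the auditory
contrast component is therefore re-centred so `mean(clear) − mean(noisy)`
crosses zero exactly at the boundary (one sign change, at the planted
position — a tested invariant).

Additive, unmodulated components: pink (1/f) background excluded from the
analysis band plus a 15 Hz guard margin on each side (without the margin,
spectral leakage through the ~±10 Hz smoothing of a 200 ms window dilutes
the planted percent change by several percent), and a 60 Hz line component.
Off-gyrus reference channels (default 54) carry noise only (no
deterministic in-band line); they exist so
that common average referencing behaves as with a realistic full montage —
with n channels, CAR attenuates each channel's own signal power by
(1 − 1/n)², about 3% at n = 56. Defaults: carrier RMS 5, in-band noise RMS
2, pink RMS 15, line amplitude 10 (microvolt-like units), 2 kHz sampling.

What the generator does not emulate: seizure/artifact segments, electrode
impedance drift, phase structure or cross-channel coupling of real ECoG,
spatially correlated noise. Passing tests therefore show the *estimators*
are correct and calibrated, not that they are robust to every pathology of
clinical recordings.

## Synthetic BOLD

Each trial drives a 0.6 s neural event (the duration of a single spoken
word), convolved with the generator's ground-truth HRF and scaled by the
position- and condition-dependent amplitude (anterior clear 0.37%, noisy
0.24%; posterior 0.26%/0.33%, chosen so the posterior preference reverses;
magnitudes in the anterior column are printed values, the posterior column
is a generator choice consistent with the reversed preference). Voxels sit
on a (position × depth) grid, default 1 mm spacing × 3 depths, about a raw
baseline of 1000 with: AR(1) noise (coefficient 0.3, stationary sd 0.2% —
set so the per-voxel clear-vs-noisy contrast t spans roughly +5 anterior to
negative posterior, the single-subject regime of event-related data),
per-run quadratic drift (0.5% scale), and six motion parameters (random
walks) coupled weakly (0.05%) into each voxel.

The ground-truth HRF is a double-gamma with peak 5.75 s, trough 12.75 s,
ratio 4 (sharper lobes, shape 8). It differs from the canonical kernel used
on the analysis side: the deconvolved single-trial response then peaks in
the 4–6 s window with a negative value at the 10.5 s lag — the observed
shape — which a peak-6 s/trough-16 s kernel cannot produce. The canonical
6/10/4 kernel remains the forward-model and block-design choice, giving
realistic (and quantified) model mismatch: with all noise off, predicted and
measured curves still correlate only at r ≈ 0.95, not 1, because the two
modalities deliberately share neither neural waveform nor HRF.

## ECoG analysis

* **CAR**: subtract the instantaneous cross-channel mean (including the
  channel itself).
* **Line noise**: per-channel regression of sine/cosine pairs at 60 Hz and
  harmonics — an effectively zero-bandwidth notch that leaves broadband
  70–110 Hz power intact (tested: <5% band-power change on white noise,
  >20 dB line attenuation).
* **Epochs**: −700 to +800 ms around auditory onset; events too close to a
  recording edge are dropped and counted.
* **Multitaper**: 200 ms windows, 10 ms steps, DPSS tapers with
  time–bandwidth 2 (3 tapers, ±10 Hz smoothing). A ±5 Hz target at 200 ms
  would admit only a single taper, so ±10 Hz is the narrowest choice that is
  still genuinely multitaper. Band power is the taper- and bin-averaged
  spectrum over 70–110 Hz, interpolated to a 1 ms grid and expressed per
  trial as 100·(P(t) − P̄base)/P̄base against that trial's −500…−100 ms
  baseline (so each trace has baseline mean exactly zero).
* **Inclusion**: per-trial log power ratio response (0–500 ms) vs baseline,
  one-sample two-sided t across trials, include at p < 10⁻³. The log
  stabilizes the variance of power estimates. Calibration is tested on 4000
  null electrodes at both 10⁻³ and 0.05.
* **Contrast**: Welch (unequal-variance) two-sample t of pooled clear vs
  pooled noisy per-trial response means, Welch–Satterthwaite df — printed
  per-condition SEMs differ by >2×, so a pooled-variance test would be
  miscalibrated.

## BOLD analysis

Percent-signal scaling sets each voxel's mean to exactly 100 (idempotent;
non-positive-mean voxels are masked with a log entry). The block design has
one regressor per condition — a 2-s boxcar per trial convolved with a
unit-peak gamma-variate kernel (shape 4, scale 1.1 s; single-trial peak
4.5–6 s) — plus six motion columns: 10 regressors. The tent design has 11
free knots per condition over 0–15 s at TR spacing (44 condition columns,
50 with motion); the basis is piecewise-linear, so a grid-aligned trial
contributes a unit impulse per lag. Per-run intercept and linear drift
columns are appended at fit time as baseline nuisance, not counted among
the model's regressors (standard practice for concatenated runs; they
absorb the mean-100 offset and the simulated drift). Fits are OLS;
t = w'β/√(σ̂²·w'(X'X)⁻¹w); the omnibus F covers all condition columns.
Zero-residual voxels are flagged and reported with infinite-sentinel
statistics rather than NaNs. The FIR estimate for a 15 s window of a
response whose undershoot tail extends past 15 s carries a small truncation
bias (quantified in the tests); peak timing and undershoot sign are
unaffected. Long-window (0–30 s, 21-knot) tent fits are summarized by
averaging the betas at 4.5, 6 and 7.5 s.

## Boundary detection

The contrast t-volume is sampled to surface nodes by averaging 15 equal
steps through the thickness, averaged in 1-mm bins, and scanned
anterior→posterior within the posterior third for the first sign change
relative to the nearest preceding populated bin; an exact-zero bin mean
counts as a crossing at that bin, empty bins are skipped (they never
fabricate crossings), and only the first crossing is reported. The
reference sign entering the posterior third is the sign of the *mean over
all populated anterior two-thirds bins* rather than the single preceding
bin: a transition that completes just anterior of the search region is then
reported at the first posterior-third bin instead of being missed, and a
single noise-flipped reference bin cannot suppress detection. The reported
position is the bin start of the posterior member of the sign-changing
pair, so a knife-edge planted boundary can be reported one bin posterior —
the resolution limit of the method.

ROIs relative to a boundary b: anterior [b−30, b), posterior [b, b+15],
keeping voxels with omnibus F > 5; extents are clipped at strip ends with a
warning, and empty-after-filtering ROIs are reported explicitly.

## Forward model

`make_double_gamma_hrf` solves for the two gamma-lobe scales and the mixing
coefficient so that the three printed descriptors (stationarity at the peak
and trough times, peak/|trough| ratio) are exact invariants of the realized
kernel, which is then normalized to unit peak; construction fails loudly if
the requested extrema cannot be realized (closely spaced peak/trough need
sharper lobes via `shape`). Prediction is discrete convolution of the 1 ms
condition-mean high-gamma timecourse with the kernel, read out at
stimulus-locked TR multiples (nearest sample; the convolved signal is
smooth at the seconds scale, so no anti-alias filter is needed), over the
11 samples spanning 0–15 s to match the tent grid. The scale factor
minimizes Σ(pred/s − actual)² by bounded 1-D search on log s over
(10⁻⁶, 10⁶), cross-checked against the closed form ⟨p,p⟩/⟨p,a⟩; a
non-positive inner product flags the fit unreliable. The pipeline rescales
the predicted curve to preserve the high-gamma peak before fitting, so the
reported scale factor reads directly as peak ECoG% per BOLD% (the
convention in which per-condition scales land in the several-hundreds);
the library-level predict operation itself is an unnormalized convolution.
Separate scales are fitted per region × auditory condition (four curves),
and their arithmetic mean is the summary conversion factor.

## Mixed models

The response table holds one row per unit (electrode or hemisphere) per
condition cell. Fixed effects: location × auditory-noise × visual-blur with
all interactions, treatment-coded against anterior/clear/clear. Random
structure: an intercept per participant (units within a participant are
correlated; published fractional dfs of this model family indicate grouping, and
participant is the defensible grouping for both modalities). The solver
maximizes the REML criterion directly over the two variance components
(profiled fixed effects; Woodbury identities per participant block;
Nelder-Mead on log variances). Satterthwaite dfs:
df = 2f²/Var(f) with f = [ (X'V⁻¹X)⁻¹ ]jj, Var(f) by the delta method with
the REML information of (σ²e, σ²b) (finite-difference gradient and
Hessian). Estimates, SEs and dfs were verified against statsmodels MixedLM
and R lmerTest on a frozen fixture (agreement to ~10⁻³); the statsmodels
comparison runs in the test suite. A fit whose intercept variance collapses
is flagged singular and falls back to residual dfs. The behavioral
comparison of the two noisy-auditory conditions is a paired t across
participants (the specific published test is unstated; a paired test across
participants is the conservative default).

The calibration/recovery generator (`simulate_response_table`) uses
27 units (16 anterior, 11 posterior) across 5 participants with σe = 40,
σb = 45, chosen so fitted standard errors land at the scale of the
published coefficient table (≈25 between-participant, ≈14 within); its
default effect sizes follow the published high-gamma coefficient structure,
with the posterior-location main effect set to −101 (the printed table's
−10.1 is inconsistent with its own t and SE; the text's "magnitude of 101%"
and t×SE arithmetic both give ≈ −101).

## Pipeline conditions and problem sizes

The default cohort is 5 ECoG participants (8 strip electrodes each at fixed
offsets from the landmark, 40 trials/condition — within the 32–56 range of
the emulated study — plus 54 reference channels) and 6 fMRI participants ×
2 hemispheres, each with 5 runs × 160 volumes, 48 trials/run. Behavioral
accuracies: 0.99/0.99/0.87/0.69 per condition. Per-hemisphere anatomy
varies: landmark ~ N(75 mm, 5 mm) with standard offset 45 (keeping the
y = −30/−28 anchors), functional boundary = landmark + N(−2, 4) mm, clipped
to keep the boundary inside the searchable posterior third with room for
the posterior ROI. The jitter sd is smaller than the published
functional-boundary spread (sd 9 mm in y) because on a 100 mm strip larger
jitters hit the posterior-third floor and would bias the group mean — a
limitation of the 1-D abstraction, not of the estimator. One global seed
expands into named per-stage child seeds (SHA-256 of seed:stage:index, kept
below 2³¹), so any stage re-run in isolation uses exactly the seed the full
pipeline would; reports are byte-identical across runs of the same
configuration, whose hash (output path excluded) is embedded in the report.

Test-suite problem sizes: 20 seeds for boundary recovery, 4000 null
electrodes × 24 trials for selection calibration, 500 replicates for
mixed-model type-I error, 10 replicates for effect recovery, and 6
recordings × 50 trials/condition for high-gamma amplitude recovery
(single-recording plateau estimates carry ~4–6% trial-sampling noise, so
the recovery claim is tested on their average).

## Known limitations

* The 1-D strip cannot express folding, per-hemisphere label-length
  variation, or the full anatomical spread of real boundaries (see above).
* CAR attenuation is corrected only implicitly (kept ≈3% by montage size),
  not explicitly modeled.
* The exact multitaper settings, inclusion statistic, and behavioral test
  of the emulated study are unstated; the implementations here are standard
  choices documented above, and the "p < 10⁻³ ≈ 40% power increase"
  equivalence is treated as a sanity anchor only.
* Absolute forward-model scale factors depend on the prediction's amplitude
  normalization convention (documented above); correlations do not.
* The LME supports a single random intercept per participant; nested or
  crossed random effects (e.g. hemisphere within participant) are out of
  scope.
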