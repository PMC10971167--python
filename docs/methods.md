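# Methods

## Assay and data model

The package analyses laser micro-irradiation time lapses: a 355 nm UV beam
administers 24 shots at 0.5 µm steps over a 12 µm linear cut inside a cell
nucleus; the recruitment of a GFP-tagged repair protein to the cut is imaged
as Z-stacks on a 12-bit EMCCD camera (512×512, 229.55 nm/pixel at 100×),
fast (1 fps) around the irradiation event and slow (0.2 fps) during the long
withdrawal phase. Internally every stack is carried as `[t][z][y][x]` with
continuous time in seconds (t = 0 at acquisition start) and the irradiation
event A as metadata.

Time windows: analysis uses the first 10 minutes after A by default
(configurable up to the full movie length; recordings may run 35 min). The
conventional clock in this assay places A at t = 1 s, which leaves at most
one pre-irradiation frame; several stages (noise estimation, recruitment
classification) need at least five baseline samples, so the simulator's
default timebase instead records a 10 s baseline at 1 fps before A. All
nine reported parameters are differences of time points, so the clock
origin has no effect on any result; the A = 1 s convention is available via
configuration.

## Preprocessing

Order of operations is fixed: maximum-intensity projection → drift
registration → photobleaching correction → measurement.

*Registration* is translation-only (the assay compensates lateral cell
movement; no rotation/scaling), estimated by phase cross-correlation of each
frame against the first pre-irradiation frame with 1/20-pixel upsampling.
Frames are Hann-windowed before correlation; without the window the spectral
leakage of non-periodic boundaries biases the correlation peak noticeably on
small fields. Estimated shifts above a bound (default 20 px) are clamped and
flagged. Shifted-in pixels are filled with the frame median.

*Bleaching* is estimated from nucleus pixels excluding the stripe and its
ring (per-field control mask) as `a·e^(−k t) + c` on the control-region mean
— the standard photophysics model; the correction divides each frame by
`fit(t)/fit(0)`. When the fit cannot run (fewer than 5 frames,
non-convergence) per-frame ratio factors are used instead. Whether the
original assay corrected per nucleus or per field is not documented;
per-field is the default here with the control mask excluding all detected
sites.

## Detection

Nuclei are segmented on the time-averaged pre-irradiation projection
(the tagged protein is nuclear, so nuclei are the bright objects): Gaussian
smoothing (σ = 2 px), automatic global threshold (Otsu by default; `li` and
`triangle` pluggable since thresholding generally needs adjustment across
imaging setups), 8-connected labelling, area filter (500–50 000 px) and
optional border exclusion.

The damage stripe is detected per nucleus from a difference image — mean of
the frames within 60 s after A minus mean of the pre-irradiation frames —
rather than per-frame thresholds, which makes detection robust to
inter-nucleus brightness differences. The in-nucleus difference values are
Otsu-thresholded; components must be elongated (eccentricity ≥ 0.8, the
stripe is a line), at least 10 px, and *significant*: the component's mean
difference must exceed the in-nucleus median by 3 robust standard deviations
(1.4826·MAD). The significance gate is what keeps the false-positive rate
on non-recruiting nuclei near zero — Otsu always returns a threshold, even
on pure noise. The largest qualifying component is the site (the assay cuts
once per nucleus). The background ring is the 8-connected morphological
dilation shell of the site, two pixels wide by default, clipped to the
nucleus.

Traces are per-frame arithmetic means over site and ring;
`corrected = site − ring`, and `normalized` subtracts the pre-irradiation
mean of `corrected`. A cell is classified *recruiting* when the normalized
trace exceeds 3·σ_pre for ≥ 3 consecutive post-A samples **and** the fold
change reaches 0.1. These thresholds are not from the source protocol; they
were chosen so the null false-positive rate on pure-noise simulations is
below 1%, and are configurable. In the pipeline, classification additionally
requires a detected stripe, which makes specificity on null movies
effectively total.

*Fold change.* `(Intensity_C − Intensity_A)/Intensity_A` is computed on the
raw site means (Intensity_A = pre-irradiation site mean, Intensity_C = site
maximum). A ring-corrected variant exists behind a flag but is not the
default: with spatially uniform nuclear fluorescence the ring-corrected
pre-irradiation site level is ≈ 0 and the ratio diverges. Note that the
measured fold change is diluted relative to the stripe's peak amplitude
because the site mask averages over the Gaussian cross-profile of the cut.

## Phase-point detection

Empirical points B–E are found on the normalized trace smoothed with a
5-sample centred moving average (index space, on the mixed timebase). The
noise scale σ_s of the smoothed trace is estimated from the *raw*
pre-irradiation samples divided by √window — the few smoothed baseline
samples are too correlated to give a stable estimate.

* **B (onset).** Trigger: first run of ≥ 3 consecutive post-A smoothed
  samples above 3·σ_s whose excursion also reaches 6·σ_s (noise runs hover
  near the threshold; true rises shoot far past it — without this guard an
  underestimated σ̂ occasionally triggers on baseline noise). The onset
  itself is then localized by a hinge (changepoint) fit on the raw samples
  in a short window around the trigger: zero before t₀, a non-negative
  slope after; the latest candidate within 5% of the minimal squared error
  wins (the straight hinge slightly underfits the curved rise, which would
  otherwise favour spuriously early onsets). Raw threshold crossings alone
  are first-passage biased; this combination is close to unbiased at the
  simulated noise level (≈ −0.3 s at σ = 0.05, amplitude 1).
* **Plateau level.** The smoothed maximum overestimates the plateau under
  noise (extreme-value inflation), so the level is estimated in two passes:
  maximum minus its expected inflation `σ_s·√(2 ln n_eff)`, then — when a
  broad plateau exists — the median of the later half of the
  above-95%-of-level samples, which sits nearest the asymptote.
* **C and D.** First and last crossings of 95% of the plateau level,
  each refined by a local straight-line fit (±10 samples) solved for the
  crossing — the raw first/last crossing is noise-biased early/late. If
  D − C < 10 s no plateau is declared and C = D = time of the maximum (the
  10 s minimum is an implementation choice; the original analysis scripts do
  not document one).
* **E.** First sustained drop below 5% of the plateau level after D,
  refined likewise. If the trace never drops that far, E is flagged and
  extrapolated from the fit as `D + ln(20)/k_off` — the closed-form time at
  which 95% of the dissociation has occurred under the exponential model.

With the 95%-of-plateau definition of C, a noiseless model trace gives
`C − B = ln(20)/k_on`, symmetric to the extrapolation rule for E.

## Robust regression

The model (zero baseline, exponential association from B, exponential decay
from D) is fitted to the normalized trace by bounded least squares with a
soft-L1 loss; the loss scale is 1.345 × the MAD-based robust sigma of the
pre-irradiation samples (Huber's tuning constant), so isolated outlier
frames barely move the estimates. Parameters: tB, Δmax, k_on, the span
tD − tB (keeping D ≥ B), k_off; rates bounded to [1e-5, 10] s⁻¹. Initial
values come from the empirical points (k_on ≈ 3/(C−B), k_off ≈ 3/span of
the observed dissociation); three multiplicative-jitter restarts guard
against local minima. On noiseless model traces the fit recovers all
parameters to better than 0.1%. Non-convergence is reported, not raised:
durations then come from the empirical points alone and the rate estimates
are left undefined, so cohort fractions stay unbiased.

The empirical points and the regression rates are reported independently —
both appear among the nine per-cell parameters.

## Cohort statistics

Recruiting fractions treat the independent experiment as the unit of
replication: per experiment, recruiting/irradiated × 100; per cell model,
mean ± SEM over experiments. The plateaued fraction divides by recruiting
cells only. Parameter comparisons across cell models use per-cell values
pooled over experiments: one-way ANOVA, then Tukey HSD on all pairs using
the studentized range distribution with pooled within-group variance
(Tukey–Kramer for unbalanced groups), significance tiers */**/*** at
0.05/0.01/0.001. No correction is applied across the nine parameters.
Missing parameters (non-converged fits, undefined E) are excluded pairwise
per parameter.

## Simulator

The forward model generates what the assay produces, with known truth:
disk nuclei (radius 7 µm, soft 2 px edge) of uniform nuclear fluorescence
(600 counts over a 60-count background) placed without overlap; one stripe
per recruiting nucleus — 12 µm long, Gaussian cross-profile σ = width/2
(default width 3 px), rendered as a continuous rectangle because the 0.5 µm
shot spacing (≈ 2.2 px) is below the blur scale; a discrete-24-shot mode
exists. Per-cell kinetics are drawn from truncated normals: lag
12.77 ± 3.31 s and association 65.56 ± 17.6 s (means are the assay's
cross-cell-type statistics; the spreads are the cell-to-cell SDs implied by
the reported SEMs at n = 36), plateau 120 ± 30 s and k_off 0.010 ±
0.003 s⁻¹ (plausible values for this protein; the source statistics do not
pin them down), fold change 1.0 ± 0.2 truncated to ≥ 0.1. Degradations:
global exponential bleaching (5·10⁻⁴ s⁻¹), random-walk lateral drift
(0.05 px/frame/axis), scaled-Poisson photon noise plus Gaussian read noise
(3 counts), 12-bit clipping with the clipped fraction reported. Identical
seed and configuration give bit-identical stacks.

The trace-level generator (`simulate_trace`) synthesizes consistent raw
channels (constant ring; site = ring + baseline + curve + N(0, σ)) and
recomputes corrected/normalized series with the measurement arithmetic, so
container invariants hold exactly and σ = 0 reproduces the model curve.

What the simulator does **not** emulate: optical PSF/z-blur, cell motility
beyond rigid drift, nucleoli or other intranuclear texture, dividing or
overlapping nuclei, photoconversion. Passing tests therefore demonstrate
correctness of the measurement and inference chain under the stated scene
model, not segmentation robustness on textured real nuclei.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale scenes — 96×96 single-nucleus
movies, one focal plane, 226 frames — rather than full 512×512 Z-stacks;
the geometry (nucleus and stripe size in pixels) and the full timebase are
preserved, so detection and kinetics operate at assay-realistic scales.
Recovery studies use 36 traces per condition (matching the n of the
reference statistics), 100 movies for the mixture fraction and 50 + 50 for
sensitivity/specificity. Every stochastic step takes its seed from a single
master seed via `numpy.random.SeedSequence`.

## Known limitations

* Empirical C/D/E are crossing-based; for very slow rises (k_on ≲ 0.01 s⁻¹)
  or amplitudes within a few σ of the noise, their variance grows quickly
  and the regression rates are the more reliable estimates.
* The bleaching model is mono-exponential-plus-offset; strongly
  multi-component bleaching will leave residual trend in the control trace
  (the ratio fallback can absorb it at the cost of extra noise).
* One damage site per nucleus is assumed; multi-cut protocols are out of
  scope.
* Nucleus labels are not tracked through division or large-scale
  rearrangement; registration is rigid-translation only.
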