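# stripekin

Quantification of DNA-repair-protein recruitment kinetics at laser-induced
DNA damage sites in live-cell time-lapse microscopy.

In a laser micro-irradiation assay, a focused UV beam draws a linear cut
(a "stripe") through a cell nucleus; a fluorescently tagged repair protein
(e.g. FUS-eGFP) accumulates at the damage site within seconds and later
departs again. `stripekin` turns the raw time-lapse stacks of such
experiments into per-cell kinetic parameters and cohort statistics:

1. **stack I/O** — TIFF/OME-TIFF stacks (T×Z×Y×X), the two-rate acquisition
   timebase (fast frames around irradiation, slow frames later),
   maximum-intensity projection over Z;
2. **preprocessing** — translation-only drift registration by windowed phase
   cross-correlation, photobleaching correction by a mono-exponential fit to
   a control region;
3. **detection** — nucleus segmentation (automatic thresholding), damage
   stripe detection from a post-minus-pre difference image, a two-pixel
   background ring around the stripe, background-corrected intensity traces;
4. **kinetics** — segmentation of each recruiting trace into four phases and
   a robust non-linear fit of a first-order binding model;
5. **cohort statistics** — recruiting and plateaued fractions, one-way ANOVA
   with Tukey HSD post hoc comparisons across cell models;
6. **simulation** — a forward model of the whole assay (scene geometry,
   kinetics, bleaching, drift, camera noise) with known ground truth, used
   as the test harness for every other stage.

## The kinetic model

A recruiting trace is described by five time points — **A** (irradiation),
**B** (recruitment onset), **C** (end of recruitment), **D** (dissociation
onset), **E** (return to a pre-irradiation-like level) — which delimit the
lag (I), association (II), plateau (III) and dissociation (IV) phases.
The fitted model is first-order binding kinetics on the background-corrected,
baseline-normalized intensity y(t):

```
y(t) = 0                                      t < B
y(t) = Δmax · (1 − e^(−k_on (t − B)))         B ≤ t < D
y(t) = y(D) · e^(−k_off (t − D))              t ≥ D
```

Nine parameters are reported per cell: lag time (A→B), association time
(B→C), plateau time (C→D), dissociation time (D→E), total duration
(B→E = II+III+IV), k_on, k_off, the fluorescence fold change
(Intensity_C − Intensity_A)/Intensity_A at the site, and whether a plateau
is present. C and D are the 95%-of-plateau crossings; when E is not reached
inside the imaging window it is extrapolated as the time at which 95% of the
dissociation has occurred, `E = D + ln(20)/k_off`.

## Worked example

```python
from dataclasses import replace
from stripekin import (SimulationConfig, simulate_stack, RunConfig,
                       process_stack)

sim = SimulationConfig(image_shape=(96, 96), n_z=1, n_nuclei=1, seed=5)
stack, truth = simulate_stack(sim)
records, report = process_stack(stack, RunConfig(simulation=sim))
print(report)
print(records[0].parameters)
```

prints

```
{'movie_id': 'movie1', 'n_frames': 226, 'n_nuclei': 1, 'n_sites': 1,
 'n_recruiting': 1, 'drift_flagged': 0, 'bleach_form': 'exponential'}
KineticParameters(lag_time_s=12.0, association_time_s=82.4, ...,
                  k_on=0.0336, k_off=0.0083, fold_change=0.584,
                  plateau_present=True)
```

One simulated nucleus was segmented, its stripe detected and classified as
recruiting; the onset was found 12 s after irradiation (generative value
14.2 s for this seed), and the fitted rates are close to the generative
k_on = 0.035/s and k_off = 0.0083/s. The measured fold change is lower than
the generative peak value because the site mean averages over the stripe's
Gaussian cross-profile.

The same pipeline runs from the shell:

```sh
stripekin simulate --seed 3 --out out/sim
stripekin run --config run.yaml --seed 1 --out out/run
stripekin stats --cells out/run/cells.csv --out out/stats
```

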