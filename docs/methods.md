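# Methods

This note documents the models, algorithms and numerical choices behind
`ergml`: what each stage computes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where the design was genuinely
open.

## Synthetic cohorts

### Waveform model

An averaged photopic ERG epoch is synthesised as the sum of four parts, on a
0–250 ms grid at 2 kHz (500 samples, time 0 = flash onset):

1. **a/b-wave compound.** Two opposite-signed gamma-shaped bumps,
   `g(t) = (t/t_p)^k exp(k(1 − t/t_p))`, with shape parameters
   `k_a = 22` (narrow a-wave) and `k_b = 9` (broader b-wave).  Because the
   bumps overlap, their coefficients and centres are fixed-point calibrated
   (10 iterations) so that the sampled waveform attains its minimum `−Aa`
   at `Ta` and a trough-to-peak excursion `Ab` at `Tb` — the calibration
   makes the generator's nominal parameters exactly recoverable by the
   time-domain detector on noiseless input (verified to ±0.5 ms / ±0.2%).
   Defaults (113 Td·s, skin electrodes): `Aa = 8 µV` at 14 ms, `Ab = 25 µV`
   at 30 ms; the 446 Td·s flash scales both amplitudes by 1.4.
2. **Oscillatory potentials.** Exponentially damped sinusoids at 80 and
   160 Hz (defaults 2.5 and 1.2 µV, decay 0.08 /ms), gated by a raised-sine
   window to the a→b rising limb, where OPs ride physiologically.
3. **Band textures.** Independent narrow-band Gaussian processes, one per
   40-Hz analysis band (complex white noise smoothed to ~40 Hz bandwidth and
   remodulated at the band centre).  These carry the injectable spectral
   group effects; default RMS per band falls from 0.9 µV in the OP bands to
   0.2 µV at 280–320 Hz.
4. **Measurement noise.** White Gaussian noise (default 1 µV RMS) low-passed
   at 300 Hz, mimicking the acquisition band limit.

### Group effects

A `GroupEffect` perturbs a group relative to control (which is always the
identity): a b-amplitude multiplier, a b-time shift (ms), and per-band
energy multipliers and kurtosis shifts.  Kurtosis is injected by
multiplying the band texture with a slow log-normal envelope
`exp(σu − σ²/2)`; σ is chosen from the requested shift so the modulated
texture *alone* has Pearson kurtosis `3 + shift`.  Two dilutions then act
on the extracted feature: the envelope must fluctuate below ~10 Hz to
survive band-limited demodulation (the envelope timescale is 60 ms for this
reason), and the extracted component also contains OPs and broadband noise.
A nominal shift of 12 therefore realises a group difference of only ~0.4 in
extracted band-3 kurtosis — the recovery experiment's effect size was
calibrated once against this dilution and then frozen.

### Population structure

Group sizes (137/77/43/21), male:female splits, per-group age
distributions, and medication rates mirror a realistic two-site
neurodevelopmental cohort.  Subject-level random effects make within-subject
recordings correlate: a log-normal amplitude factor (σ = 0.15), Gaussian
b-latency jitter (1.0 ms) with additional independent a-latency jitter
(0.5 ms), log-normal jitter of the gamma shapes (σ = 0.15, i.e. waveform
morphology heterogeneity) and of OP amplitudes (σ = 0.3); small
per-recording residuals (σ_amp = 0.05, 0.25 ms) sit on top.  Medicated
subjects receive a 1.15× b-amplitude multiplier.  Everything is driven by
one `numpy` generator seeded from the config, so a config determines its
cohort byte-for-byte.

### What the generator does not emulate

Pupil-size optics, electrode and blink artifacts, trace rejection upstream
of the reported average, inter-site device differences, age trends in the
waveform, and any correlation between medication and waveform beyond the
single amplitude multiplier.  Passing tests therefore demonstrate that the
*pipeline* recovers structure it is pointed at under realistic noise — not
that real ASD/ADHD cohorts carry that structure.

## Feature extraction

**Time domain.** `Ta` = time of minimum in a 5–25 ms window; `Tb` = time of
maximum after the trough within 15–70 ms; baseline = mean of 0–5 ms;
`Aa` = |baseline − trough|, `Ab` = trough-to-peak.  Peaks are located at
sample resolution (0.5 ms at 2 kHz) without sub-sample interpolation.  A
waveform whose excursion in the search region is below 0.5 µV raises
`NoDetectablePeaks` rather than returning noise-driven values.

**Haar DWT.** Orthonormal (L2) Haar analysis over a 0–100 ms window, six
levels, `periodization` mode after symmetric padding to a power of two, so
Parseval's identity holds and energies are additive.  Detail level *j*
covers fs/2^(j+1)–fs/2^j Hz; the 34-feature schema (12 high-band bins, 8
bins + sum per OP band, b-band max/time-of-max/sum, a-band sum) assigns
each coefficient to the time bin containing its temporal centre and
discards coefficients whose centre falls in the padding.  For a zero
signal the time-of-max is defined as the window start.

**VFCDM.** Pass 1 demodulates at fixed centres `f_k = (k − ½)·40 Hz`
(multiply by `exp(−i2πf_k t)`, zero-phase low-pass at 20 Hz, remodulate,
take 2·Re).  The low-pass is a 201-tap Hamming-window FIR applied once by
centred convolution with reflection padding — applying it forward-backward
would square the response and carve dips at band edges, breaking the
near-flat band sum.  Pass 2 estimates each component's instantaneous
frequency from the Hilbert phase derivative, smooths it with a 50 ms moving
average, clips it to the band interior, re-demodulates the input along that
track, and finally re-band-limits the result at the fixed centre (a track
clipped at a band edge would otherwise pull in strong neighbouring-band
content).  Band 1 is never refined: it abuts DC.  Pass 1 is linear and its
component sum reconstructs the 0–320 Hz signal content of an ERG epoch with
relative RMSE ≤ 0.1; refinement trades a little of that additivity (~0.12)
for sharper band tracking.  Statistics use the Pearson kurtosis convention
(normal = 3) and Fisher–Pearson skewness — selection thresholds depend on
this, so it is part of the contract; constant components return sd = 0 and
shape statistics of 0 with a degenerate flag.

## Fusion, selection, modelling

Fusion concatenates family blocks over the requested (eye, strength) slots;
subjects missing a required recording are dropped, and replicate recordings
of a slot are never fused (first kept).  Two-group contrasts fold the
co-occurring ASD+ADHD diagnosis into the clinical class.  The "selected"
preset removes the a-wave time, the OP160 coefficients and the statistics
of VFCDM bands 7–8 from the full fusion.

FI selection fits a seeded random forest (300 trees) and keeps features
with importance ≥ 0.25 × mean (relative mode) or ≥ 0.01 (absolute mode);
the same forest-derived importance serves kernel/distance models, which
have no native FI.  Shapley selection scores each feature as the mean over
classes of its mean |Shapley value| across instances and keeps scores
≥ 0.005; the absolute value is essential, since signed contributions
average to ≈ 0 by construction.  Features exactly at a threshold are kept;
ranking ties break by column order for determinism.

Hyperparameters are tuned by 3-fold subject-wise CV (per-fold SMOTE +
relative-FI selection, objective = balanced accuracy); evaluation uses
10-fold subject-wise CV with SMOTE on training folds only.  SMOTE
synthesises minority rows as `x + u(x_nn − x)`, `u ~ U(0,1)`, between
same-class nearest neighbours (k = 5, reduced with a warning for tiny
classes).  Specificity is computed as TN/(TN+FP) — the only definition
under which a perfect classifier attains BA = 1.  Multiclass metrics are
macro-averaged; AUC is the ROC area, macro one-vs-rest beyond two classes.
Zero-denominator ratios evaluate to 0 with a degenerate flag.  Default
hyperparameter grids are deliberately compact (2–3 values of the main
capacity knob per family); scale-sensitive models (SVM, KNN, MLP) are
wrapped in a standardising pipeline.

## Shapley attribution

Attributions are interventional: the value of coalition *S* for instance
*x* is the mean model output with features in *S* fixed at *x* and the rest
drawn from a background sample.  Two estimators share this value function:
exact enumeration of all 2^p coalitions with the Shapley kernel weights
(used up to p = 12), and antithetic permutation sampling (default 8
permutation pairs).  Both satisfy local accuracy
`f(x) = E[f(X)] + Σ φ_j` to floating-point precision — the permutation
estimator telescopes along each ordering — so the additivity tolerance in
explanations is limited only by sampling variance in the *individual* φ_j,
not in their sum.  Model calls are batched per coalition to keep tree
ensembles fast.  Summary rankings and selection default to 8 permutations
over a 16–32 row background subsample; these defaults trade rank stability
against runtime and can be raised where rankings are close.

## Group statistics

Per-feature screening uses the tie-corrected Kruskal–Wallis H with the χ²
approximation; constant features report p = 1 with a degenerate flag.  For
more than two groups, pairwise Dunn z-tests (pooled tie-corrected rank
variance) follow a rejection at 0.05, with Holm–Bonferroni adjustment.

## Experiment harness and problem sizes

`ergml.experiments` packages the two self-validation experiments.  The
null-effect experiment (identity effects, 50 subjects/group, TD+VFCDM from
one recording, RF) must score at chance: over 20 seeds the mean pooled BA
is ~0.51 (individual seeds scatter ±0.06, as expected for 10-fold CV on
100 subjects).  The recovery experiment injects a 3 ms b-wave delay plus a
nominal band-3 kurtosis shift of 12 for the clinical group (60
subjects/group) and checks that pooled BA reaches ≥ 0.80 and that both
injected markers reach the Shapley top-10.  A delayed b-wave also shifts
low-band VFCDM statistics — that is physics, not leakage — so the top-10
always contains band-1/2 companions of `Tb`.  These problem sizes (50–60
subjects/group, one recording slot, 10–20 seeds) were chosen so each
experiment completes in minutes on one CPU while keeping the Monte-Carlo
error of the checked quantities well inside their acceptance margins.

## Known limitations

- The exact Shapley path is exponential in p and is reserved for small
  models; large-p rankings rely on sampling and inherit its variance.
- The DWT schema is one defensible reading of a band/bin feature set; it is
  config-swappable, and its bin counts (12/8/8) follow the analysis-window
  geometry rather than an external standard.
- SMOTE interpolates in raw feature space; with strongly curved class
  manifolds its synthetic points can fall off-manifold.  This mirrors
  standard practice and is confined to training folds.
- The generator's group effects are low-dimensional by design; it cannot
  emulate arbitrary waveform-shape differences between diagnostic groups.
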