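# ergml

Feature engineering and machine-learning classification for light-adapted
(photopic) flash electroretinograms (ERGs), aimed at separating
neurodevelopmental phenotypes — autism spectrum disorder (ASD), attention
deficit/hyperactivity disorder (ADHD), their co-occurrence, and typically
developing controls — from the shape and spectral content of the retinal
response.

The ERG is a mass electrical response of the retina to a flash, recorded
non-invasively at the skin near the eye.  Clinically it is summarised by the
amplitude and time-to-peak of its two main deflections: the cornea-negative
a-wave (amplitude `Aa`, time `Ta`) and the cornea-positive b-wave (`Ab`
measured trough-to-peak, `Tb`).  Group differences in neurodevelopmental
conditions are subtle, so this package expands each waveform into three
feature families per recording before modelling:

| family | features | description |
|--------|---------:|-------------|
| TD     |        4 | `Ta`, `Aa`, `Tb`, `Ab` — conventional time-domain markers |
| DWT    |       34 | orthonormal Haar wavelet band energies: 12 high-band (250–1000 Hz) time bins, 8 bins + sum for each oscillatory-potential band (OP160: 125–250 Hz, OP80: 62.5–125 Hz), b-band max/time/sum, a-band sum |
| VFCDM  |       64 | variable-frequency complex demodulation into eight 40-Hz bands tiling 0–320 Hz; 8 statistics per band (mean, sd, median, iqr, skewness, kurtosis, rms, max abs) |

Features from several recordings of the same subject (right/left eye, 113 and
446 Td·s flash strengths) are concatenated into one instance per subject, so
that for example TD+VFCDM over two recordings yields 136 columns and all
three families over two recordings yield 204 (column names carry the slot
suffix, e.g. `vfcdm_kt_3_L113` — kurtosis of the 80–120 Hz band, left eye,
113 Td·s).

Models (RF, AdaBoost, gradient boosting, XGBoost, SVM, KNN, MLP) are
evaluated with subject-wise 10-fold cross-validation: folds are assigned at
the subject level so no individual contributes to both training and test;
training folds are rebalanced with SMOTE while test folds keep the raw class
distribution.  Reported metrics follow the usual confusion-matrix
definitions, with balanced accuracy

    BA = (sensitivity + specificity) / 2        (two classes)
    BA = macro-averaged recall                  (more than two classes)

Feature selection uses either random-forest feature importance (relative
threshold 0.25 × mean FI, or absolute ≥ 0.01) or Shapley scores (mean over
classes of the mean |Shapley value| across instances, threshold ≥ 0.005);
per-individual explanations are additive Shapley decompositions
`f(x) = E[f(X)] + Σ φ_j`, with the class call `f(x) > E[f(X)]`.

Because no public ERG dataset with these phenotype labels exists, the
package includes a first-class synthetic-cohort generator
(`ergml.synthetic_data`) that reproduces the structure such a study
produces: four groups with realistic sizes and sex ratios, two sites, four
recordings per subject, and injectable group effects on b-wave
timing/amplitude and on the energy/kurtosis of individual 40-Hz sub-bands.

## Worked example

Recover an injected group effect (a 3 ms b-wave delay plus a kurtosis shift
of the 80–120 Hz band for the ASD group; 60 subjects per group):

```python
from ergml.experiments import injected_effect_run

r = injected_effect_run(seed=1)
print("balanced accuracy: %.3f" % r["balanced_accuracy"])
print(r["top_features"])
```

prints

```
balanced accuracy: 0.917
['vfcdm_sk_1_R446', 'vfcdm_kt_1_R446', 'vfcdm_iqr_3_R446', 'vfcdm_mean_1_R446',
 'Tb_R446', 'vfcdm_kt_3_R446', 'vfcdm_rms_2_R446', 'vfcdm_sd_1_R446',
 'vfcdm_sd_2_R446', 'vfcdm_rms_1_R446']
```

The pooled 10-fold subject-wise balanced accuracy is 0.917, and the Shapley
ranking of the fitted model places both injected markers — the b-wave time
`Tb_R446` and the band-3 kurtosis `vfcdm_kt_3_R446` — in the top 10 of 68
features, alongside low-band statistics that shift as a mechanical
consequence of delaying the b-wave.

The same pipeline is scriptable from the shell:

```
$ ergml simulate --config cohort.yaml --out data/
$ ergml evaluate --in data/ --fusion td+vfcdm --eyes R --strengths 446 \
      --groups control,ASD --technique RF --folds 5 --out metrics.json
ergml: evaluate: BA=0.867 F1=0.867
```

where `cohort.yaml` requests 15 control and 15 ASD subjects with a 3 ms
b-wave delay for ASD.  `metrics.json` then contains the pooled metrics
(here BA = F1 = 0.867, AUC = 0.944 on 30 subjects and 68 features).

Other entry points: `ergml extract` writes a per-recording feature table,
`ergml train` tunes and fits one model, `ergml explain` writes Shapley
summary and per-individual waterfall plots.

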