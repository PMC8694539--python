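# hrca

Does the liquid being swallowed — thin-liquid barium (used in X-ray swallow
studies) versus plain water (used in bedside screening) — leave a systematic
imprint on high resolution cervical auscultation (HRCA) signals?  HRCA
records swallowing vibrations and sounds from the anterior neck with a
tri-axial accelerometer (anterior–posterior, superior–inferior,
medial–lateral axes) and a contact microphone.  If barium and water swallows
are statistically indistinguishable in HRCA feature space, algorithms
developed on imaging-study (barium) data can be carried over to water-based
bedside dysphagia screening.

This package implements that comparison as a reproducible, fully synthetic
pipeline for signal-processing and biostatistics practitioners: a cohort
generator with known ground truth at two tiers (raw 4-channel recordings, and
feature tables drawn directly from the screening model), the conditioning
chain, the 36-feature representation, the per-feature linear mixed-model
screen, and a repeated-holdout classifier battery.

## The model at the core

Each of the 36 features (9 per channel × 4 channels) is screened with a
linear mixed model

    y_ij = β₀ + β₁·I(material_ij = water) + u_i + ε_ij,
    u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ²)

for swallow *j* of participant *i*: a material fixed effect β₁
(water − barium) with a participant random intercept, REML-estimated, Wald
test at α = 0.05, no multiplicity correction.  The nine per-channel features
span four domains: time (SD, skewness, non-excess kurtosis), frequency (Welch
peak frequency, spectral centroid, RMS bandwidth), time-frequency (wavelet
entropy of discrete-Meyer subband energies), and information-theoretic
(normalized Lempel-Ziv complexity C = c(n)·log₂(n)/n of the median-binarized
signal, and a corrected-conditional-entropy regularity index ρ ∈ [0, 1],
higher = more regular).

Material prediction is evaluated with a linear SVM, Gaussian Naive Bayes, and
2-cluster K-means-as-classifier over 2000 random 70/30 swallow-level
holdouts, with and without PCA to 8 components (fit on the training split),
reporting overall accuracy, per-material sensitivity, and per-material
predictive value averaged over iterations.

See `docs/methods.md` for assumptions, defaults, numerical conventions, and
limitations.

## Worked example

```python
import dataclasses
from hrca.synthgen import study_replica_config, default_effect_spec, generate_feature_table
from hrca.screen import run_feature_screen
from hrca.classify import EvalProtocol, holdout_evaluate

# feature-tier cohort replicating the analyzed design (19 participants,
# 90 barium + 95 water swallows) with 8 planted material effects of
# 1.5 within-participant SDs
cfg = dataclasses.replace(
    study_replica_config(seed=2024),
    effect_spec=default_effect_spec(shift=1.5),
)
table = generate_feature_table(cfg)

screen = run_feature_screen(table)
print(f"rejected {screen.n_rejected} of {screen.n_total} features")
print(sorted(screen.rejected_features))

report = holdout_evaluate(table, EvalProtocol(n_iterations=200, seed=0))
acc = report.metrics["pca"]["svm_linear"]["overall_accuracy"]
print(f"SVM overall accuracy (PCA-8): {acc:.3f}")
```

Output:

```
rejected 8 of 36 features
['entropy_rate_MIC', 'entropy_rate_SI', 'lz_complexity_MIC', 'std_dev_MIC', 'wavelet_entropy_AP', 'wavelet_entropy_MIC', 'wavelet_entropy_ML', 'wavelet_entropy_SI']
SVM overall accuracy (PCA-8): 0.974
```

The screen recovers exactly the 8 planted feature×channel effects, and with
effects of this size present the classifier separates the materials almost
perfectly.  With `effect_spec=[]`
(the null) the screen rejects ≈ 5% of features and every classifier falls to
≈ 50% accuracy — the pattern that, on real data, supports carrying
barium-trained algorithms over to water screening.

The same stages run from the shell:

```bash
hrca simulate --tier feature --out run/ --seed 4
hrca screen --features run/features.csv --out run/screen.json
hrca classify --features run/features.csv --iterations 2000 --pca 8 --out run/report.json
hrca run --out fullrun/ --seed 1   # signal tier: simulate -> preprocess -> features -> screen -> classify
```

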