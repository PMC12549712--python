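# atlaspd

Functional near-infrared spectroscopy (fNIRS) measures cortical hemodynamics
through dual-wavelength light attenuation at the scalp.  During a block-design
fine-motor task, the prefrontal activation pattern of early-stage Parkinson's
disease differs from healthy aging: stage-1 (Hoehn–Yahr 1) patients tend to
*hyper*-activate frontal-polar cortex and recruit additional dorsolateral
prefrontal territory as a compensatory mechanism, while stage-2 patients show
an attenuated, delayed response.  `atlaspd` turns that observation into a
three-class staging tool: it simulates raw 22-channel prefrontal recordings
with the statistical structure the analysis assumes, runs the full
preprocessing chain from light intensity to a model-ready tensor, trains an
attention-based Transformer-LSTM hybrid classifier (ATLAS-PD) against
classical comparators, and quantifies robustness and channel-level
interpretability.

The package is aimed at methods researchers who want a fully seeded,
end-to-end testbed for fNIRS classification pipelines — no clinical
recordings are required or included.

## The model

Raw intensity `I(t)` at wavelengths 695/830 nm is converted to optical
density `OD(t) = −log₁₀(I/Ī)` and, after motion repair and filtering,
inverted through the modified Beer–Lambert law

    ΔOD_λ = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR) · d · DPF

with source–detector distance d = 3 cm and differential pathlength factor
DPF = 6.0.  The classifier stack is

    22-ch input → linear projection (d_model) → batch norm → sinusoidal
    positional encoding → Transformer encoder (multi-head self-attention,
    4·d_model feed-forward) → LSTM → dense softmax (3 classes)

trained with Adam under cross-entropy + L2 (λ = 0.001), early stopping
(patience 20 on validation loss), and best-validation-accuracy
checkpointing.  The reference configuration is d_model = 128, 4 heads,
2 encoder layers, learning rate 8e-4 (plain LSTM comparator: hidden sizes
[128, 64], lr 2e-3), dropout [0.3, 0.4].  Comparators: SVM (C = 0.8, RBF),
random forest (80 trees, depth 8), k-NN (k = 7, distance weights), and a
back-propagation MLP ((80, 40), α = 0.02).

Evaluation includes per-class one-vs-rest ROC AUC, percentile-bootstrap
confidence intervals, McNemar's paired test, a Gaussian noise-injection
robustness curve with its normalized area (AUC_robustness), permutation
channel importance aggregated over six anatomical regions, and t-SNE
embeddings of the penultimate layer.

## Worked example

```python
import atlaspd
from atlaspd.design import BlockDesign
from atlaspd.models import AtlasPDClassifier, split_dataset

# 60 subjects (20 per class), widely separated effect profiles, simulated
# at 10 Hz and decimated to 1 Hz by the preprocessing chain
cohort = atlaspd.simulate_cohort(
    20, design=BlockDesign(sampling_hz=10.0),
    effects=atlaspd.GroupEffectProfile.high_snr(),
    noise=atlaspd.NoiseProfile.low(), seed=11)
ds = atlaspd.build_dataset(cohort, chromophore="hbo", target_hz=1.0, seed=11)
train, val, test = split_dataset(ds, seed=42)

clf = AtlasPDClassifier(d_model=32, n_heads=2, n_transformer_layers=1,
                        lstm_hidden=32, crop_len=110, batch_size=6,
                        epochs=150, learning_rate=1e-3, patience=30)
clf.fit(train, validation_data=(val.data, val.labels))
print("test accuracy:", (clf.predict(test) == test.labels).mean())
```

```
test accuracy: 1.0
```

The split of the 60-subject cohort is 42/9/9 (stratified 70/15/15); on this
high-SNR cohort the hybrid classifies every held-out subject correctly.
With the discriminative signal confined to channels CH01/CH04/CH05/CH08,
permutation importance ranks exactly those four channels first:

```python
from atlaspd.explain import permutation_importance
report = permutation_importance(clf, test, repeats=10, seed=42)
print(report.ranking[:5])
```

```
('CH08', 'CH05', 'CH01', 'CH04', 'CH13')
```

A command-line interface mirrors the library
(`atlaspd simulate|preprocess|train|baselines|evaluate|explain|power|run-all`).

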