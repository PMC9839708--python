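# ieegssl

Semi-supervised classification of intracranial EEG (iEEG) segments with a
small annotation budget.

Clinical iEEG review sorts 3-second single-channel windows into four groups:
power-line noise (class 0), muscle artifact (1), pathological activity with
interictal epileptiform discharges / high-frequency oscillations (2), and
physiological background (3). Expert labels are expensive; recordings are
long. This package implements a pipeline that needs only *N* gold-standard
labels per class:

1. **Spectrogram tensor** — each segment is converted by an STFT (window 256
   samples, hop 128, Hann taper) to a magnitude spectrogram, then z-scored
   along frequency rows and along time columns; the two normalizations are
   stacked as a `[2, F, T]` tensor.
2. **Temporal autoencoder** — a GRU encoder consumes the frame sequence and
   an affine head maps its final hidden state to a *D*-dimensional embedding
   (default *D* = 128); a GRU decoder with dot-product attention over the
   encoder states reconstructs the input, trained with Adam on MSE
   (lr 10⁻³, batch 128, 10 epochs) on **unlabeled** data only. Model
   selection uses the cosine similarity between validation tensors and their
   reconstructions.
3. **KDE Naive-Bayes classifier** — for each class *c*, the density of its
   *N* labeled embeddings is estimated with an axis-aligned Gaussian product
   kernel, one Silverman bandwidth per dimension
   (`h_d = 0.9·min(σ_d, IQR_d/1.34)·N^{-1/5}`). A query *x* is assigned
   `argmax_c π_c · p̂_c(x)` with uniform priors π; posteriors are computed in
   the log domain.
4. **Evaluation protocol** — stratified k-fold cross-validation with a
   label-budget contract: per fold, the remainder splits 90/10 into an
   unlabeled training set and a validation set; only *N* labels per class are
   drawn from the validation set to fit the classifier; every label access is
   recorded in an audit log. Metrics: one-vs-rest AUROC/AUPRC (macro), macro
   and weighted F1, confusion matrix.
5. **Review projection** — UMAP to 2-D for expert inspection (never consumed
   by the pipeline).

A seeded synthetic generator emulates the four classes (pink-noise
background, 8–12 Hz rhythm, biphasic raised-cosine IEDs, Gabor-atom HFO
bursts, burst-gated high-passed EMG noise, mains sinusoid with harmonics) and
long pseudo-prospective recordings in which IED segments are rare, so the
whole pipeline is testable without clinical data. The autoencoder (with its
reverse-mode gradient tape) is implemented in NumPy.

## Worked example

```python
from ieegssl import GeneratorParams, generate_dataset, ProtocolConfig, run_split
from ieegssl.autoencoder import AEConfig
from ieegssl.spectro import SpectroConfig

params = GeneratorParams()                      # 512 Hz desk scale, 3-s segments
make = lambda n, seed: generate_dataset({c: n for c in range(4)}, params, seed=seed)

config = ProtocolConfig(
    label_budget=30,                            # gold-standard labels per class
    spectro=SpectroConfig(log_transform=False),
    ae=AEConfig(embedding_dim=64, gru_hidden=64, epochs=6,
                teacher_forcing=False, seed=0),
    seed=0,
)
result = run_split(make(150, 1), make(60, 2), make(60, 3), config)

m = result.metrics
print(f"macro AUROC : {m['macro_auroc']:.3f}")
print(f"macro AUPRC : {m['macro_auprc']:.3f}")
print(f"macro F1    : {m['macro_f1']:.3f}")
print("confusion (rows = true class 0..3):")
print(m["confusion"])
```

prints (about 15 s on one CPU):

```
macro AUROC : 0.929
macro AUPRC : 0.760
macro F1    : 0.714
confusion (rows = true class 0..3):
[[60  0  0  0]
 [ 0 60  0  0]
 [ 0 22 22 16]
 [ 0 12 14 34]]
```

Line noise and muscle artifacts are recognized perfectly even at this small
scale; separating pathological from physiological activity is the hard part
and improves with the amount of unlabeled training data (at the study scale
of 400 unlabeled segments per class, macro AUROC reaches ≈ 0.96 — see below).
`result.model` / `result.classifier` can then be deployed on a long recording
via `ieegssl.pseudo_prospective_eval`, which scores every 3-s window by the
posterior mass of the pathological class.

The same stages are available as a CLI:

```sh
ieegssl simulate --counts 0:50,1:50,2:50,3:50 --seed 1 --out-dir run/
ieegssl preprocess --manifest run/manifest.csv --arrays run/segments.npz --out-dir run/
ieegssl train --tensors run/tensors.npz --out-dir run/
ieegssl encode --model run/model.npz --tensors run/tensors.npz --out-dir run/
ieegssl fit-kde --embeddings run/embeddings.npz --manifest run/manifest.csv -n 30 --out-dir run/
ieegssl classify --classifier run/classifier.npz --embeddings run/embeddings.npz --out-dir run/
ieegssl evaluate --manifest run/manifest.csv --arrays run/segments.npz --out-dir run/eval
ieegssl project --embeddings run/embeddings.npz --manifest run/manifest.csv --out-dir run/
```

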