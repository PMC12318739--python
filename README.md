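# dcai — dual cross-attention classification of pulmonary nodules

Accurate benign-vs-malignant triage of pulmonary nodules on screening CT is
a core problem in early lung-cancer diagnosis: CT alone misses context that
radiologists encode in structured ratings (spiculation, margin, texture,
…), and the two data sources — a high-dimensional image volume and a small
ordinal table — are awkward to fuse. This package implements a multimodal
classifier that encodes both modalities with transformer encoders and fuses
them with *dual cross-attention*, together with the full surrounding
pipeline: LIDC-IDRI-style cohort construction, CT cube preprocessing, a
synthetic-data generator, five-fold cross-validation and the
confusion-matrix metric suite. It is aimed at researchers who want a
transparent, dependency-light reference implementation they can probe,
ablate and extend.

## The model

Each nodule is a pair: a rating matrix `S ∈ ℝ^{9×4}` (nine ordinal
attributes × four readers) and a CT cube `C ∈ ℝ^{32×32×32}` (1 mm isotropic,
lung-windowed to [0,1]).

```
S_emb = ReLU((S·W1 + b1)·W2 + b2)            W1: 4×32, W2: 32×256
S_enc = TransformerS(S_emb)                  9×256, six blocks
C_emb = SliceConv(C)                         32×256 (shared 32×32 kernel per axial slice)
C_enc = TransformerC(C_emb)                  32×256, six blocks

S_CA = softmax(Q_c K_s^T / √d) V_s           image queries, structured keys/values
C_CA = softmax(Q_s K_c^T / √d) V_c           structured queries, image keys/values

S_final = AvgPool(LayerNorm(S_CA))           256
C_final = AvgPool(LayerNorm(C_CA))           256
V = [S_final ⊕ C_final]                      512
loss = CE(Linear(V), y)                      y ∈ {benign=0, malignant=1}
```

Ablation switches (`structured_only`, `image_only`, `no_transformer`,
`no_cross_attention`) disable one component at a time. The network runs on
a small reverse-mode autodiff engine over float64 numpy arrays included in
the package — no GPU framework required. See `docs/methods.md` for every
modelling choice and its rationale.

## Worked example

```python
import numpy as np
from dcai import ModelConfig, SynthConfig, TrainConfig, cross_validate, gen_dataset

dataset, _ = gen_dataset(SynthConfig(n_samples=300, delta=1.0, seed=11))
report = cross_validate(
    dataset,
    ModelConfig(n_transformer_blocks=2, model_dim=64, seed=7),
    TrainConfig(epochs=10, batch_size=30, learning_rate=0.003, seed=7),
)
print({k: round(v, 3) for k, v in report.mean_metrics.items()})
```

prints

```
{'accuracy': 0.98, 'precision': 1.0, 'sensitivity': 0.959, 'specificity': 1.0, 'f1': 0.977}
```

i.e. five-fold cross-validated performance of a reduced model on 300
synthetic nodules whose class signal (δ = 1) is injected into both the cube
and the ratings: 98% of held-out nodules are classified correctly, every
nodule called malignant truly is (precision 1.0), and 95.9% of malignant
nodules are caught (sensitivity). With δ = 0 the same pipeline stays at
chance (~0.52), and each unimodal ablation on the same data lands near
0.90 — fusing the modalities recovers cases that either branch alone gets
wrong.

The same workflows are available from the shell:

```bash
dcai synthesize --out data/synth --seed 11 --n-samples 300 --delta 1.0
dcai train --data data/synth --out runs/full --seed 7 --epochs 10
dcai train --data data/synth --out runs/img  --seed 7 --ablation image_only
dcai preprocess --annotations annotations.csv --images scans/ --out data/cohort
dcai evaluate --data data/synth --checkpoint runs/full/model.npz --out runs/score
```

`preprocess` applies the cohort rules (≥ 3 mm, ≥ 3 readers, mean malignancy
rounded — 1–2 benign, 4–5 malignant, 3 excluded; missing fourth reader
imputed by rounded mean) and, given CT volumes, resamples to 1 mm,
extracts the 32³ cubes and windows them to [0,1].

## Layout

```
src/dcai/
  ingest.py      cohort rules, labels, imputation, rating matrices (CSV/XML)
  volume.py      resampling, cube extraction, HU windowing
  autodiff.py    reverse-mode autodiff on numpy arrays
  nn.py          Linear/LayerNorm/Dropout/attention/transformer blocks, AdamW
  model.py       the dual cross-attention network + ablations + checkpoints
  train.py       five-fold CV protocol, training loop
  metrics.py     confusion matrix and the five derived metrics
  synthetic.py   synthetic nodule generator (cubes + ratings)
  dataio.py      on-disk dataset layout shared by all pipelines
  cli.py         preprocess / synthesize / train / evaluate commands
```
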