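# pneumoscope

Unsupervised screening of chest radiographs for pneumonia, built on
one-class convolutional autoencoders.

Labelled medical image collections are expensive to assemble, and for
rare conditions one class may be almost absent. `pneumoscope` sidesteps
labels entirely: an autoencoder is trained to reconstruct radiographs
of a *single* class (only pneumonia-positive, or only
pneumonia-negative images). At test time each image is scored by its
reconstruction error

    e(x) = (1/u) Σᵢ (xᵢ − yᵢ)²,

where y is the model's reconstruction of the 64×64 image x and
u = 4096 pixels. Images the model has never seen the like of
reconstruct poorly, so a threshold τ on e(x) — fixed as the **maximum
validation-set error** — turns the score into a binary classifier:
x is flagged as the opposite class iff e(x) > τ.

Four autoencoder variants are provided, differing only in objective:

| variant | objective |
|---------|-----------|
| `pcae`  | squared reconstruction error |
| `dcae`  | reconstruction of the clean image from zero-masked input (corruption probability σ) |
| `scae`  | reconstruction + γ·Bernoulli-KL pulling mean latent activations to a target z |
| `bvcae` | reconstruction + β·KL(q(z\|x) ‖ N(0, I)) over a Gaussian latent code |

Classifiers are evaluated by recall, precision, f1 = 2RP/(R+P) and
f2 = 5RP/(R+4P); f2 is the headline metric because it weights recall —
missed pneumonia — four times as heavily as precision.

A seed-deterministic synthetic radiograph generator (smooth lung-field
backgrounds, planted bright opacity blobs) stands in for clinical data
in all tests and benchmarks. See `docs/methods.md` for the models,
the threshold rule, and what the generator does and does not emulate.

## Worked example

Generate a synthetic dataset and train a plain autoencoder on the
normal class (scenario `train_neg`; the whole pneumonia class plus the
held-out 20% of normals form the test set):

```sh
pneumoscope simulate --n-normal 150 --n-anomalous 60 --seed 1 --out data/synth
pneumoscope train --data-root data/synth --scenario train_neg \
    --variant pcae --seed 7 --out runs/pcae
```

which prints

```
Model  Recall  Precision  f1-Score  f2-Score
-----  ------  ---------  --------  --------
pcae   75.00%  100.00%    85.71%    78.95%
```

Reading the row: 45 of the 60 pneumonia-like test images exceeded the
threshold and were flagged (recall 75%), and no held-out normal image
did (precision 100%, zero false alarms). The max-validation-error rule
is deliberately conservative, and at this small training size (90
normals after the 60/20/20 split) the model's error spread is still
wide, so recall — and with it the recall-weighted f2 — suffers first.
At the benchmark size (300 training normals; see below) the same
pipeline reaches f2 ≈ 98%. The run directory contains the fitted
checkpoint, the per-epoch training log, the per-image decisions CSV
(error, threshold, call), the rendered report, and the fully-resolved
config for provenance.

Score a single image against the fitted model, using the threshold from
`runs/pcae/decisions.csv`:

```sh
pneumoscope predict --ckpt runs/pcae/model.ckpt.npz \
    --image data/synth/PNEUMONIA/pneumonia_00000.png \
    --threshold 0.023564 --scenario train_neg
```

```json
{"source_id": "data/synth/PNEUMONIA/pneumonia_00000.png",
 "error": 0.033272, "threshold": 0.023564,
 "is_anomaly": true, "predicted_label": "positive"}
```

The library mirrors the CLI one-to-one (`pneumoscope.run_experiment`,
`build_model`, `train`, `fit_threshold`, `classify`, `evaluate`), and
`pneumoscope.experiment.run_synthetic_benchmark` runs the full
train-on-normals recovery protocol in one call.

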