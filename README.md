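# echoflow

Continuous-time video segmentation of echocardiogram-like clips with a
latent-ODE encoder/decoder network, evaluated end-to-end on a synthetic
beating-heart phantom.

The model treats a clip as observations of a dynamical system: a shared
convolutional encoder embeds each frame, a backward-in-time ODE-RNN
(ConvGRU updates between adaptive Dormand–Prince integrations) compresses
the clip into a dynamics code `D` and an initial latent state, and a single
forward solve with **dense output** produces latent states at arbitrary
target times — 4 sparse input frames yield 7 temporally consistent
predictions in one pass. Each latent state is decoded by a self-supervised
reconstruction decoder and a task decoder (segmentation softmax or keypoint
heatmaps) that receives skip connections from the reconstruction path.

Everything — including a small reverse-mode autodiff engine and the
differentiable dopri5 solver — is implemented on numpy (no GPU framework
required); the DTW inner loop of the consistency metric is numba-compiled.

## Components

| Module | Contents |
| --- | --- |
| `echoflow.phantom` | synthetic beating-heart videos with dense labels, ED/ES ground truth, measurement keypoints, speckle noise, arrhythmia mode; clip sampler (4 frames, stride 2 → 7 dense targets) |
| `echoflow.autodiff` | minimal reverse-mode engine: conv2d, pooling, upsampling, fused losses, SGD |
| `echoflow.ode` | ConvGRU cell, dynamics-conditioned derivative net, adaptive dopri5 with dense-output interpolant, backward latent-ODE encoder |
| `echoflow.networks` | encoder, reconstruction/target decoders with skips, full video model, per-frame baseline segmenter |
| `echoflow.training` | MSE + (CE + dice) losses with `loss = seg + λ·recon` (λ = 10), clip-consistent augmentation, SGD training loop, checkpoints |
| `echoflow.metrics` | Dice/IoU and temporal consistency: shape-context + cyclic DTW contour matching (TC), adjacent-frame dice variation (TCD) |
| `echoflow.downstream` | LV area curve → Savitzky–Golay (13/3) → peak detection for ED/ES phases; heatmap-centroid dimension measurement |

## CLI

```bash
echoflow generate --config phantom.yaml --out data/v0 --seed 0
echoflow train    --config train.yaml --data data --out run
echoflow predict  --checkpoint run/checkpoint.npz --video data/v0 --out pred
echoflow evaluate --pred pred --gt data/v0/labels --classes 4 --out metrics.csv
echoflow phases   --pred pred --lv-class 4 --gt-phases data/v0/annotation.json --out phases.json
echoflow measure  --heatmaps maps/ --spacing 0.5 --out measures.csv
```

Configs are YAML; any `TrainConfig` / `PhantomConfig` / solver field can be
set (see the dataclasses for names and defaults). Videos are exchanged as
per-frame PNG directories with a JSON annotation index.

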