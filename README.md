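# radarposture

A toolkit for radar-based sleep-posture monitoring with multiple bedside
impulse-radio ultra-wideband (IR-UWB) radars.  Sleep posture matters
clinically — lateral positions relieve obstructive sleep apnea, supine
helps some back pain — but camera-based monitoring fails under blankets
and in the dark.  An IR-UWB radar sees through both, at the price of
delivering only a 1D range profile per sensor: how much energy returned
from each distance, with no direction.  This package implements the full
pipeline that turns a ring of such radars into a posture estimate, for
researchers in biomedical signal processing who want a reproducible,
dataset-free testbed:

* **Simulation** — posture-labelled multi-radar frames from parametric
  body phantoms, y(t) = Σᵢ Aᵢ δ(t − τᵢ) + n(t), with static clutter,
  blanket attenuation, range point-spread and pulse-to-pulse body
  scintillation.
* **Clutter suppression** — per-range-bin slow-time mean subtraction,
  X′[n,m] = X[n,m] − (1/M) Σᵢ X[n,i], removing everything static.
* **SREM** (Spatial Radar Echo Map) — each radar's 1D profile spread
  over a bed-aligned 2D grid by distance-based two-bin interpolation
  (b = ⌊D/d⌋, ⌈D/d⌉), masked to the ±65° azimuth sector, one
  sector-shaped view per radar.
* **Multiview CNN** — a shared convolutional backbone per view,
  element-wise max pooling across views, a fully connected head;
  cross-entropy + AdamW (lr 0.001, betas (0.9, 0.999)); implemented in
  pure NumPy with gradient-checked backward passes.
* **Ensemble ablation** — the 22 pre-planned radar-subset
  configurations of the eight canonical slots (3 headboard + 5 side),
  subject-wise 55:15 splits, per-configuration retraining, and mean
  accuracy per radar count.

## Worked example

Simulate 20 subjects in all nine postures under a thin blanket, build
the eight SREM views per sample, and train the four-class (supine /
left / right / prone) classifier on 16 subjects, holding out 4:

```python
import numpy as np
import radarposture as rp

params = rp.SimParams(n_pulses=16)
samples = rp.iter_samples(20, rp.FINE_LABELS, ("thin",), 1, params=params, seed=1)
x, postures, subjects, _ = rp.views_from_samples(samples, input_size=32)
y = rp.encode_labels(postures, "coarse")

subjects = np.asarray(subjects)
train_subj, test_subj = rp.subject_split(subjects, seed=1)   # 55:15 proportion -> 16:4
tr, te = np.isin(subjects, train_subj), np.isin(subjects, test_subj)

model = rp.build_model(rp.ModelSpec(backbone="tiny_cnn", n_classes=4, input_size=32), seed=1)
rp.train(model, x[tr], y[tr], rp.TrainConfig(epochs=15, seed=1))
acc, cm = rp.evaluate(model, x[te], y[te])
print(f"held-out accuracy: {acc:.3f}")
print(cm)
```

Output:

```
held-out accuracy: 0.917
[[ 2  0  0  2]
 [ 0 12  0  0]
 [ 0  0 12  0]
 [ 1  0  0  7]]
```

The classifier separates left from right lying perfectly on unseen
subjects (rows 2–3 of the confusion matrix); the residual errors confuse
supine with prone, the two midline postures that differ only in trunk
reflectivity and head turn — exactly the hard pair in this modality.

The packaged reference accuracies of the published four backbones under
all 22 radar configurations aggregate to mean accuracy per radar count:

```python
print(rp.aggregate_by_count(rp.load_reference_accuracies()))
```

```
model     densenet121  resnet50  efficientnet_b0  phresnet50
n_radars
8               0.804     0.721            0.775       0.723
7               0.756     0.777            0.703       0.732
6               0.799     0.767            0.676       0.736
5               0.718     0.736            0.704       0.702
4               0.696     0.704            0.700       0.668
3               0.550     0.672            0.678       0.656
2               0.594     0.649            0.633       0.613
```

Six well-placed radars (the single-left-head-radar family) lose almost
nothing against the eight-radar baseline; below four, accuracy drops
steeply.

The same stages are available from a shell:

```bash
radarposture simulate --subjects 6 --trials 1 --blankets thin --seed 2 --out ds.h5
radarposture srem --in ds.h5 --out stacks.h5 --interp as_printed --masked
radarposture train --srems stacks.h5 --classes 4 --backbone tiny_cnn --seed 7
radarposture ablate --srems stacks.h5 --configs 1,5,22 --seed 7 --out results.csv
radarposture aggregate --in results.csv --out by_count.csv
```

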