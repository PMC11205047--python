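# leafseg

Instance segmentation of individual plant leaves in top-down rosette
images (Arabidopsis, tobacco), with an exact implementation of the five
Leaf Segmentation Challenge evaluation measures, a one-stage
prototype-mask segmentation model in three variants, and a seeded
synthetic rosette generator so the whole pipeline is testable without any
dataset download.

Segmenting every leaf of a living plant is the prerequisite for
non-destructive phenotyping — leaf counting, area and shape tracking,
growth monitoring. The package is aimed at plant-phenotyping researchers
who need (a) trustworthy challenge-compatible scoring of their own
segmentation outputs and (b) a compact, dependency-light training pipeline
for the standard one-stage segmentation architecture and two efficiency /
multi-scale variants of it.

## Evaluation measures

For a predicted label map `L^ar` with instances `L_i^ar` (i = 1..M) and a
ground-truth map `L^gt` with instances `L_j^gt` (j = 1..N):

* **Dice**  `Dice(a, b) = 2|a ∩ b| / (|a| + |b|)`
* **Best Dice**  `BD(L^ar, L^gt) = (1/M) Σ_i max_j Dice(L_i^ar, L_j^gt)`
* **Symmetric Best Dice**  `SBD = min{BD(L^ar, L^gt), BD(L^gt, L^ar)}` —
  the challenge's primary segmentation score
* **FGBGDice** — Dice of the binarised foregrounds (instance identity ignored)
* **DiffFG / AbsDiffFG**  `#L^ar − #L^gt` and its absolute value (leaf counting)

Two empty masks score Dice 1.0; a map with no instances scores Best Dice
0.0 so batch evaluation never aborts on a failed prediction. Dataset
aggregation is the unweighted mean over images.

## Models

All three variants share an anchor-free, decoupled-head architecture with
YOLACT-style prototype masks: per-level box branches predict each box edge
as a discrete distribution over distance bins (distribution focal loss),
a class branch scores leaf presence, and a coefficient branch combines a
shared prototype stack into per-instance masks. Training uses
task-aligned assignment (`t = score^α · IoU^β`, top-k anchor points per
instance) with CIoU + DFL box losses and per-instance mask BCE.

* `standard` — C2f backbone (P3–P5 taps), path-aggregation neck.
* `bifpn` — neck fusion nodes replaced by fast normalised weighted fusion
  `Conv((Σ wᵢ·xᵢ)/(Σ wᵢ + ε))` with learnable non-negative weights and
  same-level skip connections.
* `ghost` — the P4 backbone downsampling convolution replaced by a Ghost
  module: a few intrinsic maps from a dense primary convolution, the rest
  from a cheap 5×5 depthwise transform (strictly fewer parameters).

The numerical backend is a compact NumPy reverse-mode autograd written for
this package (`leafseg.autograd`), so training and inference run anywhere
NumPy does; the networks are defined declaratively in YAML graphs
(`leafseg/configs/`).

## Worked example

```python
import numpy as np
from leafseg import synthetic, metrics
from leafseg.synthetic import RosetteConfig

scene = synthetic.generate_rosette(RosetteConfig(size=256, k_min=6, k_max=10, seed=7))
print("leaves:", metrics.instance_ids(scene.labels).size)

# a deliberately imperfect "prediction": merge the two largest leaves
pred = scene.labels.copy()
ids, counts = np.unique(pred[pred > 0], return_counts=True)
a, b = ids[np.argsort(counts)[-2:]]
pred[pred == a] = b
report = metrics.evaluate_dataset([(pred, scene.labels)], ids=["plant007"], percent=True)
print(report.format_table())
```

prints

```
leaves: 10
image                  BD      SBD  FGBGDice  DiffFG AbsDiffFG
plant007            96.74    93.31    100.00   -1.00      1.00
ALL                 96.74    93.31    100.00   -1.00      1.00
```

Merging two leaves leaves the foreground untouched (FGBGDice 100), costs
one leaf in the count (DiffFG −1), and drags SBD below BD because the
ground-truth→prediction direction pays for the split instance.

The same operations are available from the shell:

```bash
leafseg simulate --n 8 --size 64 --out data        # synthetic rosettes
leafseg split data --out splits                    # every 4th file -> val
leafseg train --data data --out run --variant ghost --scale n \
    --image-size 64 --epochs 20 --seed 0
leafseg predict data/images --checkpoint run/model.npz --out preds
leafseg evaluate --pred preds/pred_png --gt data/labels_png
```

## Layout

```
src/leafseg/metrics.py     evaluation measures + report writers
src/leafseg/masks_io.py    PNG/HDF5 label maps, polygon txt, split, resize
src/leafseg/net_blocks.py  C2f, Ghost module, BiFPN weighted fusion
src/leafseg/model.py       assembly, assignment, losses, training, inference
src/leafseg/augment.py     HSV / flip / affine / mosaic / erasing stack
src/leafseg/synthetic.py   seeded rosette-scene generator
src/leafseg/cli.py         the `leafseg` command
src/leafseg/autograd.py    NumPy reverse-mode autograd
src/leafseg/nn.py          layers and SGD on top of it
docs/methods.md            modelling assumptions and design notes
```
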