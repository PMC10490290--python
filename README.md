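# appledet

A lightweight one-stage apple detector in pure scientific Python: a YOLOv5-style
CSP network whose C3 blocks are replaced by a partial-convolution ("C3-light")
variant and whose neck carries parameter-free SimAM attention, together with

* exact learnable-parameter and FLOP accounting per block and per model,
* the Pascal VOC / YOLO label pipeline (conversion, augmentation, 8:1:1
  splitting, IoU-distance k-means anchors),
* a synthetic orchard scene generator (occlusion, lighting, blur) with
  pixel-accurate ground truth,
* a complete training/evaluation stack (CIoU + BCE loss, anchor assignment,
  cosine LR schedule, precision/recall/F1/AP/mAP0.5:0.95),

all running on NumPy/SciPy only — the network forward **and** backward passes
are implemented on a small reverse-mode autodiff engine (`appledet._nn`), so
no deep-learning framework is required.

## Model variants

| variant    | C3 blocks | SimAM | parameters (80-class head) | GFLOPs @640 |
|------------|-----------|-------|----------------------------|-------------|
| `baseline` | standard  | no    | 1,872,157                  | 4.5         |
| `cs`       | C3-light  | yes   | 1,564,525                  | 3.8         |

The C3-light bottleneck is a FasterNet-style block: bare PConv(3×3, ratio 1/4)
→ 1×1 expansion conv (BN+SiLU) → bare 1×1 projection, with a residual add in
the backbone form and none in the neck form. FLOPs follow a documented
convention (2 FLOPs per conv MAC; BN 2, SiLU 4, pool k²−1, SimAM 10 ops per
element; copies free) under which the totals above round to the printed
figures.

## CLI

One entry point with eight subcommands:

```bash
appledet synth   --n 100 --img-size 160 --seed 0 --out runs/synth
appledet convert --data runs/synth --classes apple --out runs/labels
appledet split   --data runs/synth --ratios 8:1:1 --seed 0 --out runs/split
appledet anchors --data runs/synth --k 9 --img 160
appledet profile --variant cs --nc 80 --img 640 --per-module
appledet train   --data runs/synth --variant cs --img 160 --epochs 40 --out runs/train
appledet detect  --weights runs/train/model.npz --data runs/synth --conf 0.25
appledet eval    --weights runs/train/model.npz --data runs/synth
```

All subcommands accept `--seed` where randomness is involved and write a JSON
manifest next to their artifacts; identical config + seed reproduces identical
outputs.

## Package layout

```
src/appledet/
  _nn/               reverse-mode autodiff engine (conv, BN, pooling, SGD)
  core_layers.py     Conv-BN-SiLU, PConv, C3 / C3-light, SPP(F), SimAM + cost models
  model_builder.py   layer-graph assembly, decoding, NMS, checkpoints
  profiling.py       parameter / FLOP accounting and reduction arithmetic
  data_io.py         VOC XML ⇄ YOLO TXT, augmentation, splits, k-means anchors
  synthetic_orchard.py  labeled synthetic scene generator
  train_eval.py      losses, target assignment, LR schedule, metrics, training loop
  benchmarks.py      reproducible smoke-training benchmark
  cli.py             argparse entry point
```
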