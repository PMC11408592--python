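# kidneyfusion

Classification of kidney CT images into **Cyst / Normal / Stone / Tumor**
by *frozen-backbone feature fusion*: the features of one or two frozen
image-classification backbones are concatenated and a single linear head is
trained on top (linear probing), optionally with a gradient-norm–scaled
Adam variant.  The package is aimed at researchers who want to study this
architecture family — exact parameter accounting, the optimizer variant,
the data pipeline, and the per-class evaluation suite — at sizes a laptop
CPU handles, using a built-in synthetic CT-like image generator in place of
clinical data.

## The model

A classifier is

```
images [B,3,H,W] ──► frozen extractor A ──► f_A ∈ R^{d_A} ─┐
                                                            ├─► concat ──► W x + b ──► logits [B,C]
images [B,3,H,W] ──► frozen extractor B ──► f_B ∈ R^{d_B} ─┘
```

Only the head `(W, b)` is trainable: `(d_A + d_B)·C + C` parameters.  The
registry provides truncated AlexNet (d = 4096), ViT-B/16 (768), Swin-B
(1024), ConvNeXt-Large (1536), and two small fixed stand-ins `tiny_a` (32)
and `tiny_b` (48) for desk-scale experiments.  Because every backbone is
frozen, training needs no backpropagation through the extractors — the
softmax cross-entropy gradient of a linear head is closed form — so the
whole stack is implemented in NumPy.

**Optimizer.**  Standard Adam updates
`θ ← θ − α·m̂/(√v̂ + ε)` from bias-corrected moment estimates `m̂, v̂`.
The norm-scaled variant additionally computes `n = ‖g‖` per parameter
tensor and divides the learning rate by it:

```
θ ← θ − α/(n + ε) · m̂/(√v̂ + ε)          (custom_adam)
```

so tensors with large gradients take proportionally smaller steps.  A
`literal` variant with `m̂` in the denominator and `√v̂` in the numerator is
also provided (guarded against `m̂ → 0`); see `docs/methods.md` for why two
readings exist.

**Metrics.**  One-vs-rest precision, recall (sensitivity), F1, specificity
`TN/(TN+FP)`, and class-wise error rate `1 − recall` per class, with
unweighted macro averages and overall accuracy, plus CSV/PNG reports.

## Worked example

Audit the fused AlexNet + ConvNeXt-Large classifier and run the desk-scale
benchmark (400 synthetic images, tiny fused model, 30 epochs, ~1 minute on
one CPU):

```python
import json
from kidneyfusion.backbones import count_parameters, lookup
from kidneyfusion.fusion import build_fused_classifier
from kidneyfusion.benchmark import run_desk_benchmark

model = build_fused_classifier(lookup("alexnet"), lookup("convnext_large"),
                               weights_a="zeros", weights_b="zeros")
print(json.dumps(count_parameters(model).to_dict(), indent=2))

res = run_desk_benchmark(seed=0, work_dir="scratch/demo")
print("val_accuracy:", res.val_accuracy)
print(res.confusion.to_frame())
```

prints

```
{
  "total": 253253636,
  "trainable": 22532,
  "by_component": [["extractor_a", 57003840],
                   ["extractor_b", 196227264],
                   ["head", 22532]]
}
val_accuracy: 0.99
        Cyst  Normal  Stone  Tumor
Cyst      25       0      0      0
Normal     0      25      0      0
Stone     0       1     24      0
Tumor     0       0      0     25
```

The audit says: the truncated AlexNet contributes 57,003,840 frozen
parameters, ConvNeXt-Large (fusion truncation) 196,227,264, and the
trainable 5632→4 head 22,532 — 253,253,636 in total.  The benchmark trains
that architecture's tiny analogue with the norm-scaled optimizer and
reaches 99% validation accuracy on held-out synthetic images (one Stone
image is mistaken for Normal), with every backbone weight bit-identical
before and after training.

The same workflows are available from a shell:

```sh
kidneyfusion synth --counts cyst:100,normal:100,stone:100,tumor:100 \
    --size 96 --seed 0 --out data/
kidneyfusion audit-params --model alexnet+convnext_large --classes 4
kidneyfusion train --data data/ --backbone-a tiny_a --backbone-b tiny_b \
    --optimizer custom_adam --lr 3e-3 --batch-size 16 --epochs 30 \
    --resize-to 108 --crop-to 96 --seed 0 --out runs/demo
kidneyfusion evaluate --checkpoint runs/demo/checkpoint.npz --data data/ \
    --resize-to 108 --crop-to 96 --out runs/demo-eval
```

## Layout

| module | contents |
| --- | --- |
| `kidneyfusion.optim` | Adam, the norm-scaled and literal variants, `step_all` |
| `kidneyfusion.backbones` | architecture registry, builders, freezing, `count_parameters` |
| `kidneyfusion.fusion` | single / concatenated classifiers with trainable linear head |
| `kidneyfusion.datapipe` | folder scanning, stratified split, augmentation, synthetic generator |
| `kidneyfusion.trainer` | training loop, confusion matrix, per-class metrics, reports |
| `kidneyfusion.benchmark` | the desk-scale reference run |
| `kidneyfusion.nn` | minimal forward-only NumPy layers |

See `docs/methods.md` for the modelling assumptions, parameter choices, and
known limitations.
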