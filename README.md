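# nodulepipe

Two-stage segmentation of lung nodules in chest CT, with
imbalance-aware labeling.

Lung nodules occupy well under 1% of the pixels of an axial CT slice,
which makes pixel-wise segmentation a severely class-imbalanced
problem. `nodulepipe` implements a complete, testable pipeline for this
setting:

1. **Pre-processing** — DICOM series are converted to HU-valued NIfTI
   volumes; slices are mapped through a CT display window (lung window,
   center −600 HU / width 1500 HU, by default), resized to the working
   resolution, contrast-enhanced with CLAHE (contrast-limited adaptive
   histogram equalization) and denoised with a locally adaptive Wiener
   filter.
2. **Lung-ROI stage** — a Res-U-Net is trained on lung masks; its
   prediction zeroes everything outside the pulmonary region so the
   nodule model cannot fire on extrapulmonary structures.
3. **Nodule stage** — a 2D U-Net (LeakyReLU α = 0.3, He initialization,
   per-channel sigmoid head) is trained with soft dice loss under one of
   three labeling modes:
   * `mono_positive` — the usual nodule mask;
   * `mono_negative` — the *complementary* label 1 − Y, turning the
     sub-1% foreground into a >99% one;
   * `hybrid` — a two-channel target stacking the mask and its
     complement, with the dice loss averaged per channel, decoded back
     to a single mask by `pos ≥ t AND neg < t`.

The dice coefficient between pixel sets X and Y is
`2|X∩Y| / (|X|+|Y|)`; its soft relaxation
`1 − (2Σpt + ε)/(Σp + Σt + ε)` is the training loss. Evaluation reports
dice plus confusion-derived accuracy `(TP+TN)/(TP+FP+TN+FN)`,
sensitivity `TP/(TP+FN)` and specificity `TN/(FP+TN)`, pooled over all
test pixels and per case.

A synthetic chest-phantom generator (air −1000 HU, lung parenchyma
−650 HU, soft-tissue body +100 HU, nodule discs +60 HU, Gaussian noise)
produces aligned image / lung-mask / nodule-mask volumes so every stage
runs and is verified without clinical data. The networks are a compact
numpy implementation with hand-written forward/backward passes and an
Adam optimizer, sized for CPU-scale experiments.

## Worked example

Train the nodule U-Net on phantom data and evaluate on held-out cases:

```python
from nodulepipe import PhantomConfig, SegModelSpec, TrainConfig, LabelMode
from nodulepipe.phantom import generate_dataset
from nodulepipe.pipeline import (prepare_case, split_cases,
                                 train_nodule_model, evaluate_model)

cfg = PhantomConfig(image_size=64, n_slices=6,
                    nodule_radius_px=(2, 5), nodules_per_case=(2, 4))
cases, _ = generate_dataset(cfg, n_cases=40, master_seed=7)
plan = split_cases([c.case_id for c in cases], (0.8, 0.0, 0.2), seed=7)
by_id = {c.case_id: c for c in cases}

def collect(ids):
    return [p for cid in ids
            for p in prepare_case(by_id[cid], (64, 64), only_nodule_slices=True)]

train, test = collect(plan.train), collect(plan.test)
print(f"training slices: {len(train)}, test slices: {len(test)}")

result = train_nodule_model(
    train, LabelMode.MONO_POSITIVE,
    SegModelSpec(depth=2, base_channels=8, out_channels=1),
    TrainConfig(epochs=20, batch_size=8, learning_rate=1e-3, seed=7))
print(f"dice loss: first epoch {result.history[0]:.3f}, "
      f"last epoch {result.history[-1]:.3f}")

pooled = evaluate_model(result, test)[-1]
print(f"held-out pooled dice {pooled.dice:.3f}, sensitivity {pooled.sensitivity:.3f}, "
      f"specificity {pooled.specificity:.4f}, accuracy {pooled.accuracy:.4f}")
```

Output:

```
training slices: 76, test slices: 18
dice loss: first epoch 0.973, last epoch 0.199
held-out pooled dice 0.850, sensitivity 0.824, specificity 0.9985, accuracy 0.9962
```

The training loss falls from ~1 (no overlap) to 0.2 over 20 epochs, and
the model recovers 85% dice on unseen phantom cases; specificity is
near 1 because background dominates the pixel count — exactly the
imbalance the complementary-labeling modes are designed to probe.

The same workflow is available from the shell:

```sh
nodulepipe synth --cases 10 --seed 7 --size 64 --out phantoms/
nodulepipe convert --in dicom_series/ --out volume.nii.gz
nodulepipe preprocess --in volume.nii.gz --window lung --size 256 --out pre.nii.gz
nodulepipe experiment --cases 12 --seed 1 --size 48 --out grid.json
```

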