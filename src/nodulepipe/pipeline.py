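"""Two-stage segmentation pipeline: splits, augmentation, training, evaluation.

Stage one trains a Res-U-Net on lung masks to delineate the pulmonary
region of interest (ROI); its mask zeroes everything outside the lungs
so the nodule model cannot fire on non-pulmonary structures.  Stage two
trains a U-Net on nodule masks under one of three labeling modes
(mono-positive, mono-negative/complementary, hybrid two-channel) with
soft dice loss, and the experiment grid crosses labeling mode x
pre-processing x data quantity over multiple seeds, reporting pooled
confusion metrics with across-seed mean/std.

Splits are at case level (no slice of one case appears in two splits)
and every trained artifact records its seed and config hash, so runs
are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import rotate as _nd_rotate, shift as _nd_shift

from .image_io import SliceImage, resize_slice
from .labeling import (BinaryMask, LabelMode, Polarity, combine_hybrid_prediction,
                       complement_mask, make_bundle, resize_mask)
from .losses_metrics import (ConfusionCounts, MetricsReport, confusion_metrics,
                             report_from_counts)
from .nets import Adam, ModelHandle, SegModelSpec, build_model, dice_loss_and_grad
from .phantom import PhantomCase
from .preprocess import ClaheParams, LUNG_WINDOW, WienerParams, apply_window, \
    clahe, preprocess_slice, wiener_filter

__all__ = [
    "SplitPlan", "TrainConfig", "AugmentConfig", "SlicePair", "TrainResult",
    "ExperimentReport",
    "split_cases", "augment_case", "prepare_case", "apply_roi_mask",
    "train_roi_model", "train_nodule_model", "evaluate_model",
    "evaluate_with_predictor", "run_experiment_grid",
]


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitPlan:
    """Case-level partition into train/validation/test."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        all_ids = list(self.train) + list(self.validation) + list(self.test)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split lists overlap: case-level leakage")


def split_cases(case_ids: Sequence[str], ratios: tuple[float, float, float],
                seed: int) -> SplitPlan:
    """Deterministic seeded shuffle, then case-level partition by ratios.

    Train and test must end up non-empty; validation may be empty only
    when its ratio is zero.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    ids = list(case_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 cases to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_test = n - n_train - n_val
    if n_train < 1 or n_test < 1 or (ratios[1] > 0 and n_val < 1):
        raise ValueError(
            f"ratios {ratios} leave an empty split for {n} cases "
            f"(train {n_train}, val {n_val}, test {n_test})"
        )
    return SplitPlan(
        train=tuple(shuffled[:n_train]),
        validation=tuple(shuffled[n_train:n_train + n_val]),
        test=tuple(shuffled[n_train + n_val:]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sample container and per-case preparation

@dataclass
class SlicePair:
    """One working-resolution sample: image plus aligned masks."""

    image: np.ndarray          # (H, W) float in [0, 1]
    nodule: BinaryMask         # positive polarity
    lung: BinaryMask | None
    case_id: str
    slice_index: int


def apply_roi_mask(img: SliceImage, lung_mask: BinaryMask) -> SliceImage:
    """Zero every pixel outside the lung ROI; pixels inside are unchanged."""
    if img.shape != lung_mask.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {lung_mask.shape}")
    out = np.where(lung_mask.pixels, img.pixels, 0.0)
    return SliceImage(out, unit_normalized=img.unit_normalized,
                      case_id=img.case_id, slice_index=img.slice_index)


def prepare_case(case: PhantomCase, target_size: tuple[int, int],
                 use_preprocess: bool = True,
                 clahe_params: ClaheParams = ClaheParams(),
                 wiener_params: WienerParams = WienerParams(),
                 use_roi_mask: bool = False,
                 only_nodule_slices: bool = False) -> list[SlicePair]:
    """Window, resize and (optionally) CLAHE+Wiener every slice of a case.

    ``use_preprocess=False`` keeps only the lung-window normalization
    and resize.  ``use_roi_mask`` multiplies in the case's lung mask
    after pre-processing (oracle ROI).
    """
    pairs = []
    for z in range(case.image.n_slices):
        if only_nodule_slices and not case.nodule_mask[z].any():
            continue
        sl = case.image.slice(z)
        img = preprocess_slice(
            sl, w=LUNG_WINDOW,
            c=clahe_params if use_preprocess else None,
            n=wiener_params if use_preprocess else None,
            target_size=target_size,
        )
        nod = resize_mask(BinaryMask(case.nodule_mask[z], case_id=case.case_id,
                                     slice_index=z), target_size)
        lung = resize_mask(BinaryMask(case.lung_mask[z], case_id=case.case_id,
                                      slice_index=z), target_size)
        if use_roi_mask:
            img = apply_roi_mask(img, lung)
        pairs.append(SlicePair(image=img.pixels, nodule=nod, lung=lung,
                               case_id=case.case_id, slice_index=z))
    return pairs


# ---------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentConfig:
    """Random affine jitter applied identically to image and mask."""

    flip: bool = True
    max_rotate_deg: float = 10.0
    max_translate_frac: float = 0.05

    @property
    def is_identity(self) -> bool:
        return (not self.flip and self.max_rotate_deg == 0
                and self.max_translate_frac == 0)


def _jitter(img: np.ndarray, masks: list[np.ndarray], cfg: AugmentConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray]]:
    """One random transform, shared by the image and all its masks."""
    do_lr = cfg.flip and rng.random() < 0.5
    do_ud = cfg.flip and rng.random() < 0.5
    angle = rng.uniform(-cfg.max_rotate_deg, cfg.max_rotate_deg)
    h, w = img.shape
    dy = rng.uniform(-cfg.max_translate_frac, cfg.max_translate_frac) * h
    dx = rng.uniform(-cfg.max_translate_frac, cfg.max_translate_frac) * w

    def apply(arr: np.ndarray, order: int) -> np.ndarray:
        out = arr.astype(np.float64)
        if do_lr:
            out = out[:, ::-1]
        if do_ud:
            out = out[::-1, :]
        if angle:
            out = _nd_rotate(out, angle, reshape=False, order=order, mode="nearest")
        if dy or dx:
            out = _nd_shift(out, (dy, dx), order=order, mode="nearest")
        return out

    img_out = np.clip(apply(img, order=1), 0.0, 1.0)
    mask_out = [apply(m.astype(np.float64), order=0) > 0.5 for m in masks]
    return img_out, mask_out


def augment_case(pairs: Sequence[SlicePair], n_target: int = 300,
                 seed: int = 0, cfg: AugmentConfig = AugmentConfig()
                 ) -> list[SlicePair]:
    """Grow one case's slice set to exactly ``n_target`` pairs.

    Originals are kept; the remainder are random affine jitters (flips,
    small rotation, small translation) applied identically to image and
    masks, so masks stay binary and aligned.
    """
    if not pairs:
        raise ValueError("augment_case needs at least one source pair")
    if n_target < len(pairs):
        raise ValueError(
            f"n_target {n_target} smaller than the {len(pairs)} source pairs"
        )
    rng = np.random.default_rng(seed)
    out = list(pairs)
    while len(out) < n_target:
        src = pairs[int(rng.integers(len(pairs)))]
        masks = [src.nodule.pixels]
        has_lung = src.lung is not None
        if has_lung:
            masks.append(src.lung.pixels)
        if cfg.is_identity:
            img, masks_t = src.image.copy(), [m.copy() for m in masks]
        else:
            img, masks_t = _jitter(src.image, masks, cfg, rng)
        out.append(SlicePair(
            image=img,
            nodule=BinaryMask(masks_t[0], case_id=src.case_id,
                              slice_index=src.slice_index),
            lung=BinaryMask(masks_t[1], case_id=src.case_id,
                            slice_index=src.slice_index) if has_lung else None,
            case_id=src.case_id,
            slice_index=src.slice_index,
        ))
    return out


# ---------------------------------------------------------------------------
# training

@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings for one training run."""

    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    patience: int | None = None   # early stop on epoch loss; None disables
    loss: str | None = None       # "mono" | "hybrid"; derived from mode if None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class TrainResult:
    """A trained model plus the provenance needed to reproduce it."""

    model: ModelHandle
    mode: LabelMode
    history: list[float]
    config: TrainConfig
    config_hash: str

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.model.save(path)
        meta = {"mode": self.mode.value, "history": self.history,
                "config": asdict(self.config), "config_hash": self.config_hash}
        path.with_suffix(".train.json").write_text(json.dumps(meta, indent=2))


def _targets_for_mode(pairs: Sequence[SlicePair], mode: LabelMode,
                      label_attr: str = "nodule") -> np.ndarray:
    """Stack per-slice label bundles into an (N, C, H, W) target array."""
    rows = []
    for p in pairs:
        gt = getattr(p, label_attr)
        rows.append(make_bundle(gt, mode).as_array())
    return np.stack(rows).astype(np.float32)


def _fit(handle: ModelHandle, x: np.ndarray, t: np.ndarray,
         cfg: TrainConfig) -> list[float]:
    """Mini-batch Adam on soft dice loss; returns per-epoch mean loss."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(handle.graph, lr=cfg.learning_rate)
    n = x.shape[0]
    history: list[float] = []
    best, since_best = np.inf, 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, tb = x[idx], t[idx]
            y = handle.graph.forward(xb)
            loss, grad = dice_loss_and_grad(y, tb)
            handle.graph.zero_grads()
            handle.graph.backward(grad)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if cfg.patience is not None:
            if epoch_loss < best - 1e-6:
                best, since_best = epoch_loss, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    return history


def _train(pairs: Sequence[SlicePair], mode: LabelMode, spec: SegModelSpec,
           cfg: TrainConfig, label_attr: str) -> TrainResult:
    if not pairs:
        raise ValueError("training set is empty")
    mode = LabelMode(mode)
    needed = 2 if mode is LabelMode.HYBRID else 1
    if spec.out_channels != needed:
        raise ValueError(
            f"mode {mode.value} needs out_channels={needed}, spec has {spec.out_channels}"
        )
    x = np.stack([p.image for p in pairs]).astype(np.float32)[:, None]
    t = _targets_for_mode(pairs, mode, label_attr)
    handle = build_model(spec, seed=cfg.seed)
    history = _fit(handle, x, t, cfg)
    return TrainResult(model=handle, mode=mode, history=history,
                       config=cfg, config_hash=cfg.config_hash())


def train_roi_model(pairs: Sequence[SlicePair], spec: SegModelSpec,
                    cfg: TrainConfig) -> TrainResult:
    """Train the lung-ROI Res-U-Net on mono-positive lung labels."""
    if not spec.residual:
        raise ValueError("ROI model requires a residual spec (Res-U-Net)")
    if any(p.lung is None for p in pairs):
        raise ValueError("ROI training needs lung masks on every pair")
    return _train(pairs, LabelMode.MONO_POSITIVE, spec, cfg, label_attr="lung")


def train_nodule_model(pairs: Sequence[SlicePair], mode: LabelMode | str,
                       spec: SegModelSpec, cfg: TrainConfig) -> TrainResult:
    """Train the nodule U-Net under one of the three labeling modes."""
    return _train(pairs, LabelMode(mode), spec, cfg, label_attr="nodule")


# ---------------------------------------------------------------------------
# evaluation

def _decode_prediction(pred: np.ndarray, mode: LabelMode, threshold: float,
                       case_id: str, slice_index: int) -> BinaryMask:
    """Binarize a (C, H, W) soft prediction into a positive-polarity mask."""
    mode = LabelMode(mode)
    if mode is LabelMode.HYBRID:
        return combine_hybrid_prediction(np.clip(pred, 0, 1), threshold,
                                         case_id=case_id, slice_index=slice_index)
    binary = pred[0] >= threshold
    if mode is LabelMode.MONO_NEGATIVE:
        # model predicts non-nodule foreground; complement back to positive
        neg = BinaryMask(binary, polarity=Polarity.NEGATIVE,
                         case_id=case_id, slice_index=slice_index)
        return complement_mask(neg)
    return BinaryMask(binary, case_id=case_id, slice_index=slice_index)


def evaluate_with_predictor(pred_fn: Callable[[SlicePair], np.ndarray],
                            pairs: Sequence[SlicePair], mode: LabelMode | str,
                            threshold: float = 0.5) -> list[MetricsReport]:
    """Score any predictor over a test set.

    ``pred_fn`` maps a pair to a (C, H, W) soft map in the given mode's
    channel convention.  Returns one per-case report per test case plus
    a final pooled report (pooled over all test pixels).
    """
    if not pairs:
        raise ValueError("test set is empty")
    mode = LabelMode(mode)
    per_case: dict[str, ConfusionCounts] = {}
    total = ConfusionCounts(0, 0, 0, 0)
    for p in pairs:
        pred = np.asarray(pred_fn(p), dtype=np.float64)
        mask = _decode_prediction(pred, mode, threshold, p.case_id, p.slice_index)
        rep = confusion_metrics(mask, p.nodule, case_id=p.case_id)
        per_case[p.case_id] = per_case.get(p.case_id, ConfusionCounts(0, 0, 0, 0)) \
            + rep.counts
        total = total + rep.counts
    reports = [report_from_counts(c, scope="per-case", case_id=cid)
               for cid, c in sorted(per_case.items())]
    reports.append(report_from_counts(total, scope="pooled", case_id="ALL"))
    return reports


def evaluate_model(result: TrainResult, pairs: Sequence[SlicePair],
                   mode: LabelMode | str | None = None,
                   threshold: float = 0.5) -> list[MetricsReport]:
    """Evaluate a trained model; hybrid outputs are decoded first.

    The mode must match the model's training mode (defaults to it).
    """
    mode = result.mode if mode is None else LabelMode(mode)
    if mode is not result.mode:
        raise ValueError(
            f"evaluation mode {mode.value} does not match training mode "
            f"{result.mode.value}"
        )

    def pred_fn(p: SlicePair) -> np.ndarray:
        return result.model.predict(p.image[None].astype(np.float32))

    return evaluate_with_predictor(pred_fn, pairs, mode, threshold)


# ---------------------------------------------------------------------------
# experiment grid

@dataclass
class CellResult:
    """All runs of one grid cell plus across-seed summary statistics."""

    mode: LabelMode
    use_preprocess: bool
    n_cases: int
    seeds: list[int]
    pooled: list[MetricsReport]          # one per seed
    histories: list[list[float]]
    split_plans: list[SplitPlan]
    config_hash: str

    def summary(self) -> dict:
        """Across-seed mean/std of pooled dice and confusion metrics."""
        stats = {}
        for key in ("dice", "accuracy", "sensitivity", "specificity"):
            vals = [getattr(r, key) for r in self.pooled if getattr(r, key) is not None]
            stats[f"{key}_mean"] = float(np.mean(vals)) if vals else None
            stats[f"{key}_std"] = float(np.std(vals)) if vals else None
        return stats


@dataclass
class ExperimentReport:
    """Labeling-mode x pre-processing x data-quantity grid results."""

    cells: dict[tuple[str, bool, int], CellResult]

    def to_rows(self) -> list[dict]:
        rows = []
        for (mode, pre, qty), cell in sorted(self.cells.items()):
            row = {"mode": mode, "preprocess": pre, "n_cases": qty,
                   "seeds": list(cell.seeds), "config_hash": cell.config_hash}
            row.update(cell.summary())
            rows.append(row)
        return rows

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_rows(), indent=2))


def run_experiment_grid(
    cases: Sequence[PhantomCase],
    modes: Sequence[LabelMode | str],
    preprocess_options: Sequence[bool],
    quantities: Sequence[int],
    seeds: Sequence[int],
    spec_mono: SegModelSpec,
    spec_hybrid: SegModelSpec,
    cfg: TrainConfig,
    target_size: tuple[int, int] = (64, 64),
    split_ratios: tuple[float, float, float] = (0.6, 0.0, 0.4),
    only_nodule_slices: bool = True,
) -> ExperimentReport:
    """Train and evaluate one run per (mode, preprocess, quantity, seed) cell.

    Smaller quantities subsample the case pool deterministically under
    the run seed before splitting; splits are case-level, asserted
    leak-free on every run.
    """
    modes = [LabelMode(m) for m in modes]
    case_by_id = {c.case_id: c for c in cases}
    cells: dict[tuple[str, bool, int], CellResult] = {}
    for qty in quantities:
        if qty > len(cases):
            raise ValueError(f"grid requests {qty} cases but only {len(cases)} exist")
    for mode in modes:
        spec = spec_hybrid if mode is LabelMode.HYBRID else spec_mono
        for pre in preprocess_options:
            for qty in quantities:
                pooled, plans, hists, used_seeds = [], [], [], []
                for seed in seeds:
                    rng = np.random.default_rng(seed)
                    pool = [c.case_id for c in cases]
                    pick = sorted(rng.choice(len(pool), size=qty, replace=False))
                    subset = [pool[i] for i in pick]
                    plan = split_cases(subset, split_ratios, seed=seed)
                    assert not (set(plan.train) & set(plan.test)), "case leakage"

                    def collect(ids):
                        out = []
                        for cid in ids:
                            out.extend(prepare_case(
                                case_by_id[cid], target_size,
                                use_preprocess=pre,
                                only_nodule_slices=only_nodule_slices))
                        return out

                    train_pairs = collect(plan.train)
                    test_pairs = collect(plan.test)
                    run_cfg = TrainConfig(
                        epochs=cfg.epochs, batch_size=cfg.batch_size,
                        learning_rate=cfg.learning_rate, seed=seed,
                        patience=cfg.patience,
                        loss="hybrid" if mode is LabelMode.HYBRID else "mono",
                    )
                    result = train_nodule_model(train_pairs, mode, spec, run_cfg)
                    reports = evaluate_model(result, test_pairs)
                    pooled.append(reports[-1])
                    plans.append(plan)
                    hists.append(result.history)
                    used_seeds.append(seed)
                cells[(mode.value, pre, qty)] = CellResult(
                    mode=mode, use_preprocess=pre, n_cases=qty,
                    seeds=used_seeds, pooled=pooled, histories=hists,
                    split_plans=plans, config_hash=cfg.config_hash(),
                )
    return ExperimentReport(cells=cells)
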