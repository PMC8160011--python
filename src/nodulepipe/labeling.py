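"""Binary masks, complementary labels and hybrid two-channel bundles.

Lung nodules occupy a tiny foreground fraction of a CT slice, so the
positive label is heavily outnumbered by background.  Complementary
labeling inverts the mask — the background becomes the labeled class,
turning a <1% foreground problem into a >99% one — and hybrid labeling
stacks the original and the complement into a two-channel target so the
network predicts both views at once.

Channel order in hybrid bundles is fixed as [positive, negative]; the
two channels partition every pixel (they sum to exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Polarity",
    "LabelMode",
    "BinaryMask",
    "LabelBundle",
    "complement_mask",
    "make_bundle",
    "combine_hybrid_prediction",
    "resize_mask",
]


class Polarity(str, Enum):
    """Which class the mask foreground denotes."""

    POSITIVE = "positive"  # foreground = nodule
    NEGATIVE = "negative"  # foreground = non-nodule


class LabelMode(str, Enum):
    MONO_POSITIVE = "mono_positive"
    MONO_NEGATIVE = "mono_negative"
    HYBRID = "hybrid"


@dataclass
class BinaryMask:
    """A per-slice boolean foreground map on a known grid."""

    pixels: np.ndarray
    polarity: Polarity = Polarity.POSITIVE
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be in {0, 1}")
        self.pixels = arr.astype(bool)
        self.polarity = Polarity(self.polarity)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())


@dataclass
class LabelBundle:
    """A training target: 1 channel (mono) or 2 stacked channels (hybrid)."""

    mode: LabelMode
    channels: list[BinaryMask]

    def __post_init__(self) -> None:
        self.mode = LabelMode(self.mode)
        expected = 2 if self.mode is LabelMode.HYBRID else 1
        if len(self.channels) != expected:
            raise ValueError(
                f"{self.mode.value} bundle needs {expected} channel(s), got {len(self.channels)}"
            )
        if self.mode is LabelMode.HYBRID:
            total = self.channels[0].pixels.astype(int) + self.channels[1].pixels.astype(int)
            if not np.all(total == 1):
                raise ValueError("hybrid channels must sum to exactly 1 at every pixel")

    def as_array(self) -> np.ndarray:
        """Stack channels into a (C, H, W) float array."""
        return np.stack([m.pixels.astype(np.float64) for m in self.channels])


def complement_mask(m: BinaryMask) -> BinaryMask:
    """Pixelwise inversion; the polarity flag flips with the pixels."""
    flipped = (Polarity.NEGATIVE if m.polarity is Polarity.POSITIVE
               else Polarity.POSITIVE)
    return BinaryMask(~m.pixels, polarity=flipped,
                      case_id=m.case_id, slice_index=m.slice_index)


def make_bundle(gt: BinaryMask, mode: LabelMode | str) -> LabelBundle:
    """Build the training target for one of the three labeling modes.

    mono_positive -> [gt]; mono_negative -> [complement(gt)];
    hybrid -> [gt, complement(gt)].
    """
    mode = LabelMode(mode)
    if gt.polarity is not Polarity.POSITIVE:
        raise ValueError("ground truth must have positive polarity")
    if mode is LabelMode.MONO_POSITIVE:
        return LabelBundle(mode, [gt])
    if mode is LabelMode.MONO_NEGATIVE:
        return LabelBundle(mode, [complement_mask(gt)])
    return LabelBundle(mode, [gt, complement_mask(gt)])


def combine_hybrid_prediction(
    pred: np.ndarray, threshold: float = 0.5,
    case_id: str = "", slice_index: int = 0,
) -> BinaryMask:
    """Fold a two-channel soft prediction back into a nodule mask.

    A pixel is called nodule when the positive channel asserts it AND
    the negative channel does not: ``(pos >= t) & (neg < t)``.  Pixels
    both channels claim resolve to background — conservative for a
    screening aid.  Decoding a perfect hybrid prediction returns the
    ground truth exactly.
    """
    pred = np.asarray(pred, dtype=np.float64)
    if pred.ndim != 3 or pred.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) prediction, got shape {pred.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("prediction values must lie in [0, 1]")
    pos, neg = pred[0], pred[1]
    nodule = (pos >= threshold) & (neg < threshold)
    return BinaryMask(nodule, polarity=Polarity.POSITIVE,
                      case_id=case_id, slice_index=slice_index)


def resize_mask(m: BinaryMask, target: tuple[int, int]) -> BinaryMask:
    """Nearest-neighbor mask resampling; output stays binary."""
    rows, cols = target
    if rows < 1 or cols < 1:
        raise ValueError(f"target dims must be positive, got {target}")
    out = _sk_resize(m.pixels.astype(np.uint8), (rows, cols), order=0,
                     anti_aliasing=False, preserve_range=True)
    return BinaryMask(out.astype(bool), polarity=m.polarity,
                      case_id=m.case_id, slice_index=m.slice_index)
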