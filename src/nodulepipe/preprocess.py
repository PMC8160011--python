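"""HU windowing, CLAHE contrast enhancement and adaptive Wiener denoising.

A CT window (center c, width w) displays only HU values in
[c - w/2, c + w/2], mapped linearly to [0, 1].  The lung window
(-600/1500) is the standard setting for reading lung parenchyma and is
the default input window of the nodule stage; the soft-tissue window is
50/400.

CLAHE (contrast-limited adaptive histogram equalization) equalizes each
tile's histogram after clipping every bin at a fraction of the tile's
pixel count and redistributing the clipped excess equally over all
bins, then blends the per-tile mappings bilinearly so tile seams are
invisible.  The clip limit is what separates CLAHE from plain AHE,
which over-amplifies noise in near-constant regions.

The Wiener filter is a locally adaptive linear denoiser for constant-
power additive noise: each pixel is shrunk toward its local mean by the
local signal-to-noise variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .image_io import SliceImage, resize_slice

__all__ = [
    "WindowSpec",
    "ClaheParams",
    "WienerParams",
    "LUNG_WINDOW",
    "SOFT_TISSUE_WINDOW",
    "apply_window",
    "clahe",
    "wiener_filter",
    "preprocess_slice",
]


@dataclass(frozen=True)
class WindowSpec:
    """A CT display window given as HU center and width."""

    center: float
    width: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")

    @property
    def low(self) -> float:
        return self.center - self.width / 2

    @property
    def high(self) -> float:
        return self.center + self.width / 2


LUNG_WINDOW = WindowSpec(center=-600.0, width=1500.0, name="lung")
SOFT_TISSUE_WINDOW = WindowSpec(center=50.0, width=400.0, name="softtissue")


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE parameters.

    clip_limit is a fraction of the tile pixel count: a bin may hold at
    most ``clip_limit * tile_pixels`` counts before its excess is
    redistributed.  ``tile_grid`` is (n_rows, n_cols) of tiles.
    """

    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if min(self.tile_grid) < 1:
            raise ValueError("tile grid dims must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class WienerParams:
    """Local Wiener filter parameters.

    noise_power is the constant noise variance sigma^2; when None it is
    estimated as the mean of the local variances over the image.
    """

    kernel: tuple[int, int] = (5, 5)
    noise_power: float | None = None

    def __post_init__(self) -> None:
        if any(k < 1 or k % 2 == 0 for k in self.kernel):
            raise ValueError(f"kernel dims must be odd and >= 1, got {self.kernel}")


def apply_window(img: SliceImage, w: WindowSpec) -> SliceImage:
    """Map HU to [0, 1] through a window: clip at the bounds, linear between.

    HU <= low -> 0, HU >= high -> 1, otherwise (hu - low) / width.
    """
    if img.unit_normalized:
        raise ValueError("apply_window expects a HU-valued slice, got unit-normalized")
    out = np.clip((img.pixels - w.low) / w.width, 0.0, 1.0)
    return SliceImage(out, unit_normalized=True,
                      case_id=img.case_id, slice_index=img.slice_index)


def _tile_mapping(tile: np.ndarray, clip_limit: float, n_bins: int) -> np.ndarray:
    """Equalization lookup table for one tile (unit-valued pixels).

    Histogram bins are clipped at clip_limit * n_pixels; the excess is
    redistributed equally among all bins, then the CDF gives the map.
    """
    n_pix = tile.size
    bins = np.minimum((tile * n_bins).astype(np.int64), n_bins - 1)
    hist = np.bincount(bins.ravel(), minlength=n_bins).astype(np.float64)
    ceiling = max(clip_limit * n_pix, 1.0)
    excess = np.maximum(hist - ceiling, 0.0).sum()
    hist = np.minimum(hist, ceiling) + excess / n_bins
    cdf = np.cumsum(hist)
    # anchor so the lowest occupied bin maps near 0, like classic equalization
    cdf_min = cdf[np.nonzero(hist)[0][0]] if hist.any() else 0.0
    denom = cdf[-1] - cdf_min
    if denom <= 0:
        # single occupied bin: identity-ish map
        return np.linspace(0.0, 1.0, n_bins)
    return np.clip((cdf - cdf_min) / denom, 0.0, 1.0)


def clahe(img: SliceImage, p: ClaheParams = ClaheParams()) -> SliceImage:
    """Contrast-limited adaptive histogram equalization.

    The image is split into ``tile_grid`` tiles; each tile gets a
    clipped-equalization lookup table; every output pixel bilinearly
    blends the tables of the four nearest tile centers (clamped at the
    borders).  Output stays in [0, 1].
    """
    if not img.unit_normalized:
        raise ValueError("clahe expects a unit-normalized slice")
    h, wdt = img.shape
    tr, tc = p.tile_grid
    if tr > h or tc > wdt:
        raise ValueError(f"tile grid {p.tile_grid} larger than image {img.shape}")

    x = img.pixels
    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, wdt, tc + 1).astype(int)
    # per-tile lookup tables
    luts = np.empty((tr, tc, p.n_bins))
    for i in range(tr):
        for j in range(tc):
            tile = x[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            luts[i, j] = _tile_mapping(tile, p.clip_limit, p.n_bins)

    centers_r = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:]) / 2.0
    rr = np.arange(h)[:, None].astype(float)
    cc = np.arange(wdt)[None, :].astype(float)

    # fractional tile coordinates, clamped so border pixels use edge tiles
    fi = np.interp(rr, centers_r, np.arange(tr)) if tr > 1 else np.zeros((h, 1))
    fj = np.interp(cc, centers_c, np.arange(tc)) if tc > 1 else np.zeros((1, wdt))
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, tr - 1)
    j1 = np.minimum(j0 + 1, tc - 1)
    wi = fi - i0
    wj = fj - j0

    b = np.minimum((x * p.n_bins).astype(np.int64), p.n_bins - 1)
    i0b, i1b = np.broadcast_to(i0, x.shape), np.broadcast_to(i1, x.shape)
    j0b, j1b = np.broadcast_to(j0, x.shape), np.broadcast_to(j1, x.shape)
    v00 = luts[i0b, j0b, b]
    v01 = luts[i0b, j1b, b]
    v10 = luts[i1b, j0b, b]
    v11 = luts[i1b, j1b, b]
    out = ((1 - wi) * ((1 - wj) * v00 + wj * v01)
           + wi * ((1 - wj) * v10 + wj * v11))
    out = np.clip(out, 0.0, 1.0)
    return SliceImage(out, unit_normalized=True,
                      case_id=img.case_id, slice_index=img.slice_index)


def wiener_filter(img: SliceImage, p: WienerParams = WienerParams()) -> SliceImage:
    """Locally adaptive Wiener denoiser.

    With local mean m and variance v over the kernel window and noise
    variance s2, the output is ``m + max(v - s2, 0)/max(v, s2) * (x - m)``,
    clipped to [0, 1].  Local moments use reflective boundaries so a
    constant image passes through unchanged.
    """
    if not img.unit_normalized:
        raise ValueError("wiener_filter expects a unit-normalized slice")
    x = img.pixels
    size = p.kernel
    m = uniform_filter(x, size=size, mode="reflect")
    m2 = uniform_filter(x * x, size=size, mode="reflect")
    v = np.maximum(m2 - m * m, 0.0)
    s2 = float(np.mean(v)) if p.noise_power is None else float(p.noise_power)
    denom = np.maximum(v, s2)
    gain = np.where(denom > 0, np.maximum(v - s2, 0.0) / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.clip(m + gain * (x - m), 0.0, 1.0)
    return SliceImage(out, unit_normalized=True,
                      case_id=img.case_id, slice_index=img.slice_index)


def preprocess_slice(
    img: SliceImage,
    w: WindowSpec = LUNG_WINDOW,
    c: ClaheParams | None = ClaheParams(),
    n: WienerParams | None = WienerParams(),
    target_size: tuple[int, int] = (256, 256),
) -> SliceImage:
    """Full slice pre-processing chain: window -> resize -> CLAHE -> Wiener.

    The windowing already produces the [0, 1] normalization.  Passing
    ``c=None`` or ``n=None`` disables the corresponding stage.  The
    chain is a pure function: identical inputs give identical outputs.
    """
    out = apply_window(img, w)
    if target_size is not None and tuple(target_size) != out.shape:
        out = resize_slice(out, target_size)
    if c is not None:
        out = clahe(out, c)
    if n is not None:
        out = wiener_filter(out, n)
    return out
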