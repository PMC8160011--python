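"""Synthetic chest-CT phantom: HU-valued slices with lung and nodule masks.

Each phantom case is a stack of axial slices built from simple
geometry at realistic Hounsfield levels: an air background (-1000 HU),
a soft-tissue body ellipse (+100 HU), two lung ellipses (-650 HU,
within the -700..-600 parenchyma band) and zero or more soft-tissue-
like nodule discs (+60 HU) strictly inside the lungs, plus constant-
power additive Gaussian noise.  Nodules are kept below 30 mm diameter
at the configured pixel spacing and occupy well under 1% of the pixels,
which is the class-imbalance regime the nodule-segmentation stage has
to cope with.

The generator is deterministic under (config, seed) and emits aligned
image / lung-mask / nodule-mask volumes, so every pipeline stage is
testable without clinical data.  Ellipses and discs stand in for
anatomy: enough to exercise windowing, masking, imbalance and
learning, with no texture or ground-glass simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .image_io import CTVolume, write_nifti

__all__ = ["PhantomConfig", "PhantomCase", "generate_case", "generate_dataset",
           "foreground_fraction"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, HU levels and noise of the phantom generator.

    HU levels sit inside the standard tissue bands (air -1000, lung
    -700..-600, soft tissue +100..+300).  ``spacing_mm`` is in-plane
    pixel spacing; the nodule radius cap keeps every nodule diameter
    under 30 mm at that spacing.
    """

    image_size: int = 256
    n_slices: int = 6
    hu_air: float = -1000.0
    hu_lung: float = -650.0
    hu_soft_tissue: float = 100.0
    hu_nodule: float = 60.0
    spacing_mm: float = 0.7
    slice_thickness_mm: float = 5.0
    # semi-axes as fractions of image size
    body_axes: tuple[float, float] = (0.36, 0.44)
    lung_axes: tuple[float, float] = (0.22, 0.14)
    lung_offset: float = 0.18        # lung center offset from midline, fraction
    nodules_per_case: tuple[int, int] = (1, 3)
    nodule_radius_px: tuple[int, int] = (3, 8)
    noise_sigma: float = 20.0        # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-700 <= self.hu_lung <= -600):
            raise ValueError("lung HU must lie in the parenchyma band [-700, -600]")
        if not (100 <= self.hu_soft_tissue <= 300):
            raise ValueError("soft-tissue HU must lie in [+100, +300]")
        if self.hu_air != -1000.0:
            raise ValueError("air HU must be -1000")
        max_diam_mm = 2 * self.nodule_radius_px[1] * self.spacing_mm
        if max_diam_mm >= 30.0:
            raise ValueError(
                f"max nodule diameter {max_diam_mm:.1f} mm violates the < 30 mm cap"
            )
        if self.nodule_radius_px[0] < 1 or self.nodule_radius_px[0] > self.nodule_radius_px[1]:
            raise ValueError("invalid nodule radius range")


@dataclass
class PhantomCase:
    """One generated case: HU volume plus aligned lung and nodule masks."""

    image: CTVolume
    lung_mask: np.ndarray     # (slices, H, W) bool
    nodule_mask: np.ndarray   # (slices, H, W) bool
    case_id: str
    seed: int


def _ellipse(size: int, center: tuple[float, float],
             axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def generate_case(cfg: PhantomConfig, case_seed: int,
                  case_id: str | None = None) -> PhantomCase:
    """Generate one deterministic phantom case from (cfg, case_seed)."""
    rng = np.random.default_rng(case_seed)
    s = cfg.image_size
    mid = s / 2.0

    body = _ellipse(s, (mid, mid), (cfg.body_axes[1] * s, cfg.body_axes[0] * s))
    lungs = np.zeros((s, s), dtype=bool)
    for side in (-1.0, 1.0):
        lungs |= _ellipse(
            s, (mid, mid + side * cfg.lung_offset * s),
            (cfg.lung_axes[0] * s, cfg.lung_axes[1] * s),
        )
    lungs &= body

    n_nod = int(rng.integers(cfg.nodules_per_case[0], cfg.nodules_per_case[1] + 1))
    voxels = np.empty((cfg.n_slices, s, s), dtype=np.float64)
    lung_vol = np.repeat(lungs[None], cfg.n_slices, axis=0)
    nodule_vol = np.zeros_like(lung_vol)

    # candidate nodule centers: lung pixels with full disc clearance
    from scipy.ndimage import binary_erosion
    for _ in range(n_nod):
        r = int(rng.integers(cfg.nodule_radius_px[0], cfg.nodule_radius_px[1] + 1))
        interior = binary_erosion(lungs, iterations=r + 1)
        centers = np.argwhere(interior)
        if centers.size == 0:
            raise ValueError(
                f"nodule radius {r}px does not fit inside the lung geometry"
            )
        cy, cx = centers[rng.integers(len(centers))]
        z = int(rng.integers(cfg.n_slices))
        disc = _ellipse(s, (float(cy), float(cx)), (float(r), float(r)))
        nodule_vol[z] |= disc

    base = np.full((s, s), cfg.hu_air)
    base[body] = cfg.hu_soft_tissue
    base[lungs] = cfg.hu_lung
    for z in range(cfg.n_slices):
        sl = base.copy()
        sl[nodule_vol[z]] = cfg.hu_nodule
        voxels[z] = sl
    voxels += rng.normal(0.0, cfg.noise_sigma, voxels.shape)
    voxels = np.clip(voxels, -1024.0, 3000.0)

    cid = case_id or f"phantom-{case_seed:08d}"
    vol = CTVolume(
        voxels=voxels,
        spacing=(cfg.slice_thickness_mm, cfg.spacing_mm, cfg.spacing_mm),
        case_id=cid,
    )
    return PhantomCase(image=vol, lung_mask=lung_vol, nodule_mask=nodule_vol,
                       case_id=cid, seed=case_seed)


def generate_dataset(cfg: PhantomConfig, n_cases: int, master_seed: int,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[PhantomCase], dict]:
    """Generate ``n_cases`` phantom cases with per-case seeds from master_seed.

    Returns the cases plus a manifest recording config, seeds and
    per-case nodule counts/areas.  With ``out_dir`` set, each case is
    written as a NIfTI triplet (image, lung mask, nodule mask) and the
    manifest as JSON.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    seed_rng = np.random.default_rng(master_seed)
    case_seeds = seed_rng.integers(0, 2 ** 31 - 1, size=n_cases)
    cases = [generate_case(cfg, int(cs), case_id=f"case-{i:04d}")
             for i, cs in enumerate(case_seeds)]

    manifest = {
        "config": asdict(cfg),
        "master_seed": master_seed,
        "cases": [
            {
                "case_id": c.case_id,
                "seed": c.seed,
                "nodule_pixels": int(c.nodule_mask.sum()),
                "lung_pixels": int(c.lung_mask.sum()),
                "n_nodule_slices": int(c.nodule_mask.any(axis=(1, 2)).sum()),
            }
            for c in cases
        ],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for c in cases:
            write_nifti(c.image, out_dir / f"{c.case_id}_image.nii.gz", kind="hu")
            write_nifti(CTVolume(c.lung_mask.astype(np.float64), c.image.spacing,
                                 case_id=c.case_id),
                        out_dir / f"{c.case_id}_lung.nii.gz", kind="mask")
            write_nifti(CTVolume(c.nodule_mask.astype(np.float64), c.image.spacing,
                                 case_id=c.case_id),
                        out_dir / f"{c.case_id}_nodule.nii.gz", kind="mask")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cases, manifest


def foreground_fraction(mask: np.ndarray) -> float:
    """Foreground pixels / total pixels of a binary mask (any shape)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        return 0.0
    return float(mask.astype(bool).mean())
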