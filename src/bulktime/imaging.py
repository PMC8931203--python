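"""PET tumor delineation and SUV metric extraction.

Tumors are delineated with the Nestle adaptive threshold: with SUVmax
the peak inside a user-supplied seed box, I_70 the mean SUV of the 70%
isocontour (voxels >= 0.7*SUVmax within the box) and I_bg the mean SUV
of a 2-voxel-thick background shell around the dilated box, the
threshold is

    T = beta * I_70 + I_bg        (beta = 0.3 by default),

and the mask is the 26-connected component containing the peak among
in-box voxels >= T. From a mask, SUVmax, SUVmean, metabolic tumor
volume MTV (mL) and total lesion glycolysis TLG = SUVmean * MTV follow.

Note the symbol collision: this deterministic beta is unrelated to the
trajectory model's interaction coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import PETVolume

logger = logging.getLogger("bulktime")

__all__ = ["SUVMetrics", "segment_nestle", "suv_metrics"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SUVMetrics:
    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float
    voxel_count: int
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        if not self.suv_max >= self.suv_mean >= 0:
            raise ValueError("requires suv_max >= suv_mean >= 0")


def _box_slices(box, shape):
    if len(box) != 6:
        raise ValueError("seed box must be 6 integers: x0,x1,y0,y1,z0,z1 (half-open)")
    sl = []
    for d in range(3):
        a, b = int(box[2 * d]), int(box[2 * d + 1])
        if not 0 <= a < b <= shape[d]:
            raise ValueError(f"seed box out of bounds on axis {d}: [{a},{b}) vs {shape[d]}")
        sl.append(slice(a, b))
    return tuple(sl)


def _expand_box_mask(box, shape, by):
    m = np.zeros(shape, dtype=bool)
    sl = tuple(
        slice(max(int(box[2 * d]) - by, 0), min(int(box[2 * d + 1]) + by, shape[d]))
        for d in range(3)
    )
    m[sl] = True
    return m


def segment_nestle(vol: PETVolume, seed_box, beta: float = 0.3):
    """Nestle adaptive-threshold tumor mask inside ``seed_box``.

    ``seed_box`` is (x0, x1, y0, y1, z0, z1), 0-based half-open voxel
    coordinates, and must contain the tumor peak. Returns (mask, threshold).
    """
    img = vol.voxels
    sl = _box_slices(seed_box, img.shape)
    region = img[sl]
    suv_max = float(region.max())
    if suv_max <= region.min():
        raise ValueError("flat seed region: 70% isocontour is undefined")
    iso = region >= 0.7 * suv_max
    i70 = float(region[iso].mean())

    # background: 2-voxel shell around the box dilated by 2 voxels
    inner = _expand_box_mask(seed_box, img.shape, by=2)
    outer = _expand_box_mask(seed_box, img.shape, by=4)
    shell = outer & ~inner
    if not shell.any():
        raise ValueError("background shell falls entirely outside the volume")
    i_bg = float(img[shell].mean())

    threshold = beta * i70 + i_bg
    candidates = np.zeros(img.shape, dtype=bool)
    candidates[sl] = region >= threshold
    labels, _ = ndimage.label(candidates, structure=_STRUCT_26)
    peak_local = np.unravel_index(np.argmax(region), region.shape)
    peak = tuple(peak_local[d] + sl[d].start for d in range(3))
    lab = labels[peak]
    if lab == 0:
        raise ValueError("peak voxel falls below the adaptive threshold")
    mask = labels == lab

    # warn if the mask touches the seed box boundary (possible truncation)
    for d in range(3):
        idx_lo = [slice(None)] * 3
        idx_lo[d] = sl[d].start
        idx_hi = [slice(None)] * 3
        idx_hi[d] = sl[d].stop - 1
        if mask[tuple(idx_lo)].any() or mask[tuple(idx_hi)].any():
            logger.warning("tumor mask touches the seed box boundary; enlarge the box")
            break
    return mask, float(threshold)


def suv_metrics(vol: PETVolume, mask: np.ndarray, threshold: float | None = None) -> SUVMetrics:
    """SUVmax / SUVmean / MTV / TLG over the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.voxels.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("empty mask")
    vals = vol.voxels[mask]
    suv_mean = float(vals.mean())
    mtv = int(mask.sum()) * vol.voxel_volume_ml
    return SUVMetrics(
        suv_max=float(vals.max()),
        suv_mean=suv_mean,
        mtv_ml=mtv,
        tlg=suv_mean * mtv,
        voxel_count=int(mask.sum()),
        threshold_used=threshold,
    )
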