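"""Detection of penetrating-aortic-ulcer (PAU) candidates.

PAU pixels are by construction excluded from the lumen mask: they sit
strictly above the lumen HU range, so after segmentation they appear as
holes or fringes inside the aortic cross-section.  "Inside the
boundary" is therefore implemented as the morphologically hole-filled
interior of the object's pixel mask.  Calcifications are not
distinguished from contrast-filled pouches; both are candidate signal.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure

from .types import AortaObject, CTSlice, HURange, PAUCandidate

__all__ = [
    "DEFAULT_PAU_MIN_PX",
    "hyperintense_mask",
    "filled_interior",
    "inside_aorta",
    "detect_pau",
]

log = logging.getLogger(__name__)

#: Minimum component size; suppresses single-pixel artifact hits.
DEFAULT_PAU_MIN_PX = 3


def hyperintense_mask(ct: CTSlice, hu_range: HURange) -> np.ndarray:
    """Binary mask, true exactly where ``HU > hu_range.upper`` (strict).

    Strictness matters: the lumen threshold is inclusive of the upper
    bound, so the two stages partition intensities with no overlap.
    """
    return ct.pixels > hu_range.upper


def filled_interior(obj: AortaObject, shape: tuple[int, int]) -> np.ndarray:
    """Hole-filled mask of the object on an image of the given shape."""
    return ndimage.binary_fill_holes(obj.mask(shape))


def inside_aorta(mask: np.ndarray, obj: AortaObject) -> np.ndarray:
    """Restrict ``mask`` to pixels inside the object's filled interior.

    The filled interior includes pixels excluded from the lumen by the
    HU threshold (holes), which is exactly where PAU pixels arise.  If
    the object encloses no interior beyond its own pixels the result may
    be empty; a debug record is logged rather than raising.
    """
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    interior = filled_interior(obj, mask.shape)
    if not (interior & ~obj.mask(mask.shape)).any():
        log.debug(
            "slice %d: object at %s has no enclosed interior beyond its lumen pixels",
            obj.slice_index, tuple(round(c, 1) for c in obj.centroid),
        )
    return mask & interior


def detect_pau(
    ct: CTSlice,
    obj: AortaObject,
    hu_range: HURange,
    min_size: int = DEFAULT_PAU_MIN_PX,
) -> list[PAUCandidate]:
    """PAU candidates for one aortic object.

    8-connected components of the interior hyperintense mask with at
    least ``min_size`` pixels are returned with their peak HU.  An empty
    list means the object as a whole is labeled healthy.
    """
    interior_hits = inside_aorta(hyperintense_mask(ct, hu_range), obj)
    labeled = measure.label(interior_hits, connectivity=2)
    out: list[PAUCandidate] = []
    for region in measure.regionprops(labeled):
        if region.num_pixels < min_size:
            continue
        coords = frozenset(map(tuple, region.coords))
        peak = float(max(ct.pixels[r, c] for r, c in coords))
        out.append(PAUCandidate(pixel_coords=coords, host_object=obj, peak_hu=peak))
    log.debug(
        "slice %d: %d hyperintense px inside aorta, %d PAU candidates (min_size=%d)",
        obj.slice_index, int(interior_hits.sum()), len(out), min_size,
    )
    return out
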