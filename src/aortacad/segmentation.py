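"""Aortic lumen extraction and slice-to-slice tracking.

The lumen is extracted per slice by inclusive HU-range thresholding and
8-connected component labeling; cross-sections are then linked along the
series by nearest-centroid tracking seeded on the first slice.  Slices
where no candidate lies within the continuity limit are recorded as
gaps rather than silently dropped, and tracking resumes from the last
known position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from skimage import measure

from .types import AortaObject, CTSlice, HURange

__all__ = [
    "SeedPoint",
    "VesselTrack",
    "DEFAULT_MIN_COMPONENT_PX",
    "DEFAULT_CONTINUITY_LIMIT_PX",
    "threshold_lumen",
    "label_components",
    "select_aorta",
    "segment_series",
]

log = logging.getLogger(__name__)

#: Components smaller than this many pixels are discarded as noise.
DEFAULT_MIN_COMPONENT_PX = 50
#: Maximum centroid displacement (px) tolerated between adjacent slices.
DEFAULT_CONTINUITY_LIMIT_PX = 20.0


@dataclass(frozen=True)
class SeedPoint:
    """Starting position of one vessel on the first slice."""

    position: tuple[int, int]
    anatomy_label: str

    def __post_init__(self) -> None:
        if self.anatomy_label not in ("ascending", "descending"):
            raise ValueError(f"seed label must be ascending/descending, got {self.anatomy_label!r}")


@dataclass
class VesselTrack:
    """Chain of linked cross-sections for one vessel across the series."""

    anatomy_label: str
    objects: dict[int, AortaObject] = field(default_factory=dict)
    gaps: list[int] = field(default_factory=list)

    @property
    def n_linked(self) -> int:
        return len(self.objects)


def threshold_lumen(ct: CTSlice, hu_range: HURange) -> np.ndarray:
    """Binary mask, true exactly where ``lower <= HU <= upper`` (inclusive)."""
    px = ct.pixels
    return (px >= hu_range.lower) & (px <= hu_range.upper)


def label_components(
    mask: np.ndarray,
    min_size: int = DEFAULT_MIN_COMPONENT_PX,
    slice_index: int = 0,
) -> list[AortaObject]:
    """8-connected components of ``mask`` of size >= ``min_size``.

    Returns unlinked :class:`AortaObject` candidates with centroid and
    boundary computed; smaller components are discarded.
    """
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    labeled = measure.label(mask, connectivity=2)
    out: list[AortaObject] = []
    for region in measure.regionprops(labeled):
        if region.num_pixels < min_size:
            continue
        out.append(
            AortaObject.from_pixels(
                map(tuple, region.coords), slice_index=slice_index
            )
        )
    return out


def _reference_position(previous: Union[AortaObject, SeedPoint]) -> tuple[float, float]:
    if isinstance(previous, SeedPoint):
        return (float(previous.position[0]), float(previous.position[1]))
    return previous.centroid


def select_aorta(
    candidates: Sequence[AortaObject],
    previous: Union[AortaObject, SeedPoint],
    continuity_limit: float = DEFAULT_CONTINUITY_LIMIT_PX,
) -> Optional[AortaObject]:
    """Candidate whose centroid is nearest the previous position.

    Returns None when no candidate lies within ``continuity_limit``
    pixels (Euclidean distance, inclusive).
    """
    ref = _reference_position(previous)
    best: Optional[AortaObject] = None
    best_d = float("inf")
    for cand in candidates:
        d = float(np.hypot(cand.centroid[0] - ref[0], cand.centroid[1] - ref[1]))
        if d < best_d:
            best, best_d = cand, d
    if best is None or best_d > continuity_limit:
        return None
    return best


def segment_series(
    slices: Sequence[CTSlice],
    hu_range: HURange,
    seeds: Sequence[SeedPoint],
    min_size: int = DEFAULT_MIN_COMPONENT_PX,
    continuity_limit: float = DEFAULT_CONTINUITY_LIMIT_PX,
) -> list[VesselTrack]:
    """Track each seeded vessel across an ordered slice series.

    For every slice the lumen mask is thresholded, components labeled,
    and each vessel linked to the nearest candidate within the
    continuity limit of its last known centroid (the seed position on
    the first slice).  Linked objects are relabeled with the vessel's
    anatomy label; failures are recorded in ``VesselTrack.gaps``.

    Raises
    ------
    ValueError
        If a seed lies outside the first slice's bounds or the series
        is empty / unordered.
    """
    if not slices:
        raise ValueError("empty slice series")
    order = [s.slice_index for s in slices]
    if order != sorted(order):
        raise ValueError("slices must be ordered by slice_index")
    shape = slices[0].shape
    for seed in seeds:
        r, c = seed.position
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"seed {seed.position} outside image bounds {shape}")

    tracks = [VesselTrack(anatomy_label=s.anatomy_label) for s in seeds]
    previous: list[Union[AortaObject, SeedPoint]] = list(seeds)

    for ct in slices:
        mask = threshold_lumen(ct, hu_range)
        candidates = label_components(mask, min_size=min_size, slice_index=ct.slice_index)
        log.debug(
            "slice %d: %d lumen px, %d candidate objects",
            ct.slice_index, int(mask.sum()), len(candidates),
        )
        for i, track in enumerate(tracks):
            chosen = select_aorta(candidates, previous[i], continuity_limit)
            if chosen is None:
                track.gaps.append(ct.slice_index)
                continue
            linked = AortaObject(
                slice_index=ct.slice_index,
                pixel_coords=chosen.pixel_coords,
                centroid=chosen.centroid,
                boundary=chosen.boundary,
                anatomy_label=track.anatomy_label,
            )
            track.objects[ct.slice_index] = linked
            previous[i] = linked
    for track in tracks:
        log.info(
            "vessel %s: %d slices linked, %d gaps",
            track.anatomy_label, track.n_linked, len(track.gaps),
        )
    return tracks
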