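"""Shared domain types and coordinate conventions.

Conventions used by every module in this package:

* Images are 2-D :class:`numpy.ndarray` objects indexed ``(row, col)``,
  0-based.  Row increases downward (image *y*), column increases
  rightward (image *x*).  Wherever an x/y naming is convenient, ``x``
  maps to col and ``y`` maps to row.
* Angles are degrees in ``[0, 360)``.  Pixels with no defined gradient
  direction (zero gradient) carry :data:`UNDEFINED_ANGLE` (NaN).
* Object connectivity is 8-connected; a boundary pixel is an object
  pixel with at least one 4-neighbour outside the object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "UNDEFINED_ANGLE",
    "HU_PLAUSIBLE_MIN",
    "HU_PLAUSIBLE_MAX",
    "CTSlice",
    "HURange",
    "AortaObject",
    "GradientField",
    "BoundaryPair",
    "CircleDecision",
    "PAUCandidate",
    "ConfusionCounts",
    "make_slice",
]

#: Sentinel for "no defined gradient direction" (gx == gy == 0).
UNDEFINED_ANGLE = math.nan

#: Plausible Hounsfield-unit bounds for CT pixel data.
HU_PLAUSIBLE_MIN = -2048
HU_PLAUSIBLE_MAX = 4096

#: Labels an aortic cross-section may carry after slice-to-slice linking.
ANATOMY_LABELS = ("ascending", "descending", "unlinked")

#: Shape labels produced by the circle-likeness classifier.
CIRCLE_LIKE = "circle_like"
DISSECTION_CANDIDATE = "dissection_candidate"

# 4-neighbour offsets, used for boundary extraction.
_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class HURange:
    """Inclusive Hounsfield-unit range of the contrast-enhanced lumen.

    The default used throughout the package is 200-500 HU.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"HURange requires lower < upper, got ({self.lower}, {self.upper})"
            )

    def contains(self, hu: float) -> bool:
        """True iff ``lower <= hu <= upper`` (inclusive on both ends)."""
        return self.lower <= hu <= self.upper


#: Paper-default lumen range for contrast-enhanced aortic blood.
DEFAULT_LUMEN_RANGE = HURange(200, 500)


@dataclass(frozen=True)
class CTSlice:
    """One axial CT image of Hounsfield units plus series metadata.

    Parameters
    ----------
    pixels
        2-D integer array of HU values, shape ``(rows, cols)``.
    slice_index
        0-based ordinal position in the series, superior to inferior.
    pixel_spacing_mm
        Optional ``(row, col)`` physical spacing in millimetres.
    """

    pixels: np.ndarray
    slice_index: int
    pixel_spacing_mm: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.dtype == object:
            raise ValueError("pixel array must be rectangular (got ragged rows)")
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError(f"pixels must be numeric, got dtype {arr.dtype}")
        lo, hi = float(arr.min()), float(arr.max())
        if lo < HU_PLAUSIBLE_MIN or hi > HU_PLAUSIBLE_MAX:
            raise ValueError(
                f"HU values [{lo}, {hi}] outside plausible CT range "
                f"[{HU_PLAUSIBLE_MIN}, {HU_PLAUSIBLE_MAX}]"
            )
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def make_slice(
    pixels: Iterable,
    slice_index: int,
    pixel_spacing_mm: Optional[tuple[float, float]] = None,
) -> CTSlice:
    """Validate a raw array into a :class:`CTSlice`.

    Raises
    ------
    ValueError
        If the array is empty, ragged, non-2-D, or outside the plausible
        HU range.
    """
    if isinstance(pixels, np.ndarray):
        arr = pixels
    else:
        rows = list(pixels)
        if rows and any(len(np.atleast_1d(r)) != len(np.atleast_1d(rows[0])) for r in rows):
            raise ValueError("pixel array must be rectangular (got ragged rows)")
        arr = np.asarray(rows)
    return CTSlice(arr, slice_index, pixel_spacing_mm)


@dataclass
class AortaObject:
    """A labeled connected pixel region representing one aortic cross-section.

    ``centroid`` is the arithmetic mean of ``pixel_coords`` in
    ``(row, col)``; ``boundary`` lists the object pixels that have at
    least one 4-neighbour outside the object (pixels on the image border
    count as boundary).
    """

    slice_index: int
    pixel_coords: frozenset[tuple[int, int]]
    centroid: tuple[float, float]
    boundary: tuple[tuple[int, int], ...]
    anatomy_label: str = "unlinked"

    def __post_init__(self) -> None:
        if not self.pixel_coords:
            raise ValueError("AortaObject requires a non-empty pixel set")
        if self.anatomy_label not in ANATOMY_LABELS:
            raise ValueError(f"unknown anatomy label {self.anatomy_label!r}")
        if not set(self.boundary) <= self.pixel_coords:
            raise ValueError("boundary pixels must be a subset of pixel_coords")

    @classmethod
    def from_pixels(
        cls,
        pixel_coords: Iterable[tuple[int, int]],
        slice_index: int = 0,
        anatomy_label: str = "unlinked",
        image_shape: Optional[tuple[int, int]] = None,
    ) -> "AortaObject":
        """Build an object from a pixel set, deriving centroid and boundary.

        ``image_shape`` only matters for boundary status of pixels on
        the image border; out-of-image neighbours count as exterior
        either way.
        """
        coords = frozenset((int(r), int(c)) for r, c in pixel_coords)
        if not coords:
            raise ValueError("empty pixel set")
        arr = np.array(sorted(coords))
        centroid = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
        boundary = tuple(
            (r, c)
            for r, c in map(tuple, arr)
            if any((r + dr, c + dc) not in coords for dr, dc in _N4)
        )
        return cls(slice_index, coords, centroid, boundary, anatomy_label)

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of the object on an image of the given shape."""
        m = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixel_coords)
        m[list(rows), list(cols)] = True
        return m


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient components and angle for one slice.

    ``gx`` is the intensity change along columns (image x), ``gy`` along
    rows (image y).  ``gtheta`` holds degrees in ``[0, 360)`` and NaN
    where ``gx == gy == 0``.
    """

    gx: np.ndarray
    gy: np.ndarray
    gtheta: np.ndarray

    def __post_init__(self) -> None:
        if not (self.gx.shape == self.gy.shape == self.gtheta.shape):
            raise ValueError("gx, gy, gtheta must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.gx.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BoundaryPair:
    """An ordered pair of boundary pixels with their gradient angles."""

    p1: tuple[int, int]
    p2: tuple[int, int]
    gtheta1: float
    gtheta2: float

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("boundary pair requires two distinct pixels")


@dataclass(frozen=True)
class CircleDecision:
    """Outcome of the circle-likeness test for one aortic object.

    ``label`` is derived from ``score >= threshold`` (inclusive: a score
    that reaches the threshold counts as circle-like).
    """

    score: float
    threshold: float = 0.60
    label: str = field(init=False, default="")

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in (0, 1], got {self.threshold}")
        label = CIRCLE_LIKE if self.score >= self.threshold else DISSECTION_CANDIDATE
        object.__setattr__(self, "label", label)


@dataclass(frozen=True)
class PAUCandidate:
    """A connected component of above-lumen-range pixels inside an aorta."""

    pixel_coords: frozenset[tuple[int, int]]
    host_object: AortaObject
    peak_hu: float

    def __post_init__(self) -> None:
        if not self.pixel_coords:
            raise ValueError("PAUCandidate requires a non-empty pixel set")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies of per-object diagnostic decisions."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )
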