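"""Synthetic CT slice stacks with ground truth.

Generates axial phantoms — a circular contrast-filled lumen on a
soft-tissue background — with optional dissection distortion (a dark
intimal-flap band splitting the lumen, or an elongated elliptical
lumen) and optional hyperintense wall-adjacent blobs emulating PAU /
calcification.  Every stage of the pipeline can be exercised against
the returned truth without patient data.

Noise-class separation is validated at the 3-sigma level when a spec is
constructed, so thresholding stays reliable for the configured noise.
Output is deterministic for a fixed seed: each slice draws from a
generator keyed on ``(seed, slice_index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import CTSlice, HURange, DEFAULT_LUMEN_RANGE

__all__ = [
    "Lesion",
    "PhantomSpec",
    "PhantomStack",
    "make_healthy_slice",
    "make_dissection_slice",
    "make_pau_slice",
    "generate_stack",
]


@dataclass(frozen=True)
class Lesion:
    """One lesion active on a half-open slice range ``[start, stop)``.

    kind "dissection": ``mode`` is "flap" (dark band of width
    ``flap_width_px`` through the lumen centre at ``angle_deg``) or
    "ellipse" (lumen redrawn as an equal-area ellipse of the given
    ``axis_ratio``).  kind "pau": a blob of radius ``blob_radius_px`` at
    ``blob_hu`` planted just inside the wall at ``angle_deg``.
    """

    kind: str
    start: int
    stop: int
    mode: str = "flap"
    flap_width_px: float = 3.0
    axis_ratio: float = 3.0
    angle_deg: float = 0.0
    blob_radius_px: float = 2.0
    blob_hu: float = 800.0

    def __post_init__(self) -> None:
        if self.kind not in ("dissection", "pau"):
            raise ValueError(f"lesion kind must be dissection/pau, got {self.kind!r}")
        if self.mode not in ("flap", "ellipse"):
            raise ValueError(f"dissection mode must be flap/ellipse, got {self.mode!r}")
        if self.stop <= self.start:
            raise ValueError("lesion slice range must be non-empty")

    def active(self, slice_index: int) -> bool:
        return self.start <= slice_index < self.stop


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic slice stack.

    ``lumen_hu`` and ``background_hu`` are ``(mean, spread)`` pairs: the
    per-slice class mean is jittered uniformly within +/- spread, then
    Gaussian noise of ``noise_sd`` HU is added per pixel.
    """

    shape: tuple[int, int] = (128, 128)
    n_slices: int = 10
    lumen_hu: tuple[float, float] = (350.0, 40.0)
    background_hu: tuple[float, float] = (40.0, 20.0)
    flap_hu: float = 60.0
    center: tuple[float, float] = (64.0, 64.0)
    radius: float = 20.0
    drift: tuple[float, float] = (0.0, 0.0)
    lesions: tuple[Lesion, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    hu_range: HURange = DEFAULT_LUMEN_RANGE

    def __post_init__(self) -> None:
        lm, ls = self.lumen_hu
        bm, bs = self.background_hu
        margin = 3.0 * self.noise_sd
        if not (self.hu_range.lower <= lm <= self.hu_range.upper):
            raise ValueError("lumen mean must lie within the HU range")
        if lm - ls - margin < self.hu_range.lower or lm + ls + margin > self.hu_range.upper:
            raise ValueError("lumen HU not separated from the range bounds at 3 sigma")
        if bm + bs + margin >= self.hu_range.lower:
            raise ValueError("background HU not separated from the lumen range at 3 sigma")
        for lesion in self.lesions:
            if lesion.kind == "pau" and lesion.blob_hu - margin <= self.hu_range.upper:
                raise ValueError("PAU blob HU not above the lumen range at 3 sigma")
        if self.radius < 3:
            raise ValueError("vessel radius must be >= 3 px")

    def vessel_center(self, slice_index: int) -> tuple[float, float]:
        return (
            self.center[0] + self.drift[0] * slice_index,
            self.center[1] + self.drift[1] * slice_index,
        )

    def _check_in_image(self, center: tuple[float, float]) -> None:
        r0, c0 = center
        rad = self.radius
        if not (rad <= r0 <= self.shape[0] - 1 - rad and rad <= c0 <= self.shape[1] - 1 - rad):
            raise ValueError(f"vessel at {center} radius {rad} does not fit in {self.shape}")


@dataclass
class PhantomStack:
    """Generated slices with per-slice ground truth."""

    slices: list[CTSlice]
    lumen_masks: list[np.ndarray]
    shape_labels: list[str]  # "healthy" or "diseased" per slice
    pau_blobs: list[list[frozenset]]  # planted blob pixel sets per slice


def _rng(spec: PhantomSpec, slice_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, slice_index])


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = _grid(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _base_image(spec: PhantomSpec, rng: np.random.Generator):
    """Background canvas plus the per-slice jittered class means."""
    bg = spec.background_hu[0] + rng.uniform(-spec.background_hu[1], spec.background_hu[1])
    lum = spec.lumen_hu[0] + rng.uniform(-spec.lumen_hu[1], spec.lumen_hu[1])
    img = np.full(spec.shape, bg, dtype=float)
    return img, lum


def _finish(spec: PhantomSpec, img: np.ndarray, rng: np.random.Generator, slice_index: int) -> CTSlice:
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return CTSlice(np.rint(img).astype(np.int32), slice_index)


def make_healthy_slice(spec: PhantomSpec, slice_index: int) -> tuple[CTSlice, np.ndarray]:
    """Circular lumen on soft tissue; truth mask is the rasterized disk."""
    center = spec.vessel_center(slice_index)
    spec._check_in_image(center)
    rng = _rng(spec, slice_index)
    img, lum = _base_image(spec, rng)
    disk = _disk_mask(spec.shape, center, spec.radius)
    img[disk] = lum
    return _finish(spec, img, rng, slice_index), disk


def make_dissection_slice(
    spec: PhantomSpec,
    slice_index: int,
    lesion: Optional[Lesion] = None,
) -> tuple[CTSlice, np.ndarray, str]:
    """Dissection-distorted cross-section; returns slice, lumen mask, label.

    A flap of width 0 degenerates to the healthy slice (label stays
    "diseased" only when lumen pixels were actually removed).
    """
    if lesion is None:
        active = [l for l in spec.lesions if l.kind == "dissection" and l.active(slice_index)]
        lesion = active[0] if active else Lesion("dissection", slice_index, slice_index + 1)
    center = spec.vessel_center(slice_index)
    spec._check_in_image(center)
    rng = _rng(spec, slice_index)
    img, lum = _base_image(spec, rng)
    rr, cc = _grid(spec.shape)
    if lesion.mode == "flap":
        disk = _disk_mask(spec.shape, center, spec.radius)
        ang = math.radians(lesion.angle_deg)
        # signed distance to the line through the centre at angle_deg
        # (angle 0 = band along image x)
        perp = (rr - center[0]) * math.cos(ang) - (cc - center[1]) * math.sin(ang)
        flap = disk & (np.abs(perp) < lesion.flap_width_px / 2.0)
        lumen = disk & ~flap
        img[lumen] = lum
        img[flap] = spec.flap_hu
        distorted = bool(flap.any())
    else:
        ratio = lesion.axis_ratio
        a = spec.radius * math.sqrt(ratio)  # semi-axis along angle_deg
        b = spec.radius / math.sqrt(ratio)
        ang = math.radians(lesion.angle_deg)
        u = (rr - center[0]) * math.sin(ang) + (cc - center[1]) * math.cos(ang)
        v = (rr - center[0]) * math.cos(ang) - (cc - center[1]) * math.sin(ang)
        lumen = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[lumen] = lum
        distorted = True
    label = "diseased" if distorted else "healthy"
    return _finish(spec, img, rng, slice_index), lumen, label


def make_pau_slice(
    spec: PhantomSpec,
    slice_index: int,
    lesions: Optional[list[Lesion]] = None,
) -> tuple[CTSlice, np.ndarray, list[frozenset]]:
    """Healthy lumen with hyperintense blob(s) carved just inside the wall.

    Each blob is placed fully within the disk so it becomes a hole in
    the thresholded lumen mask; truth returns the exact blob pixel sets.
    """
    if lesions is None:
        lesions = [l for l in spec.lesions if l.kind == "pau" and l.active(slice_index)]
    center = spec.vessel_center(slice_index)
    spec._check_in_image(center)
    rng = _rng(spec, slice_index)
    img, lum = _base_image(spec, rng)
    disk = _disk_mask(spec.shape, center, spec.radius)
    img[disk] = lum
    blobs: list[frozenset] = []
    lumen = disk.copy()
    for lesion in lesions:
        ang = math.radians(lesion.angle_deg)
        dist = spec.radius - lesion.blob_radius_px - 2.0
        if dist <= 0:
            raise ValueError("blob too large to fit inside the vessel wall")
        bc = (center[0] + dist * math.sin(ang), center[1] + dist * math.cos(ang))
        blob = _disk_mask(spec.shape, bc, lesion.blob_radius_px) & disk
        img[blob] = lesion.blob_hu
        lumen &= ~blob
        blobs.append(frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(blob))))
    return _finish(spec, img, rng, slice_index), lumen, blobs


def generate_stack(spec: PhantomSpec) -> PhantomStack:
    """Generate the whole series, dispatching per slice on active lesions."""
    slices: list[CTSlice] = []
    masks: list[np.ndarray] = []
    labels: list[str] = []
    blobs_per_slice: list[list[frozenset]] = []
    for idx in range(spec.n_slices):
        dissections = [l for l in spec.lesions if l.kind == "dissection" and l.active(idx)]
        paus = [l for l in spec.lesions if l.kind == "pau" and l.active(idx)]
        if dissections:
            ct, mask, label = make_dissection_slice(spec, idx, dissections[0])
            blobs: list[frozenset] = []
        elif paus:
            ct, mask, blobs = make_pau_slice(spec, idx, paus)
            label = "healthy"
        else:
            ct, mask = make_healthy_slice(spec, idx)
            label, blobs = "healthy", []
        slices.append(ct)
        masks.append(mask)
        labels.append(label)
        blobs_per_slice.append(blobs)
    return PhantomStack(slices, masks, labels, blobs_per_slice)
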