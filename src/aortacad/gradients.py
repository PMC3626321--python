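"""Sobel gradient approximation and the gradient-angle image.

The gradient angle is the full-quadrant arctangent ``atan2(gy, gx)``
mapped to ``[0, 360)`` degrees; a plain arctan of the ratio cannot
distinguish opposite directions, which the pair conditions downstream
require.  Pixels where both components vanish get NaN and never
participate in pair tests.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .types import CTSlice, GradientField, UNDEFINED_ANGLE

__all__ = ["SOBEL_X", "SOBEL_Y", "sobel_field", "gradient_angle", "gradient_angle_image"]

#: 3x3 mask for the column-direction (image x) intensity change.
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
#: Transpose: row-direction (image y) change.
SOBEL_Y = SOBEL_X.T.copy()


def gradient_angle(gx: float, gy: float) -> float:
    """Full-quadrant gradient angle in degrees, ``[0, 360)``.

    Returns :data:`~aortacad.types.UNDEFINED_ANGLE` (NaN) when both
    components are zero; the degenerate case is a value, not an error.
    """
    if gx == 0 and gy == 0:
        return UNDEFINED_ANGLE
    return math.degrees(math.atan2(gy, gx)) % 360.0


def gradient_angle_image(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Vectorised :func:`gradient_angle` over whole component arrays."""
    theta = np.degrees(np.arctan2(gy, gx)) % 360.0
    theta[(gx == 0) & (gy == 0)] = UNDEFINED_ANGLE
    return theta


def sobel_field(ct: CTSlice) -> GradientField:
    """Sobel gradient components and angle image for one slice.

    Borders are handled by edge replication, so a constant image yields
    an identically zero field.  ``gx`` is positive where intensity
    increases with column index, ``gy`` where it increases with row
    index.

    Raises
    ------
    ValueError
        If the slice is smaller than the 3x3 mask.
    """
    rows, cols = ct.shape
    if rows < 3 or cols < 3:
        raise ValueError(f"slice {ct.shape} is smaller than the 3x3 Sobel mask")
    img = ct.pixels.astype(float)
    gx = ndimage.correlate(img, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(img, SOBEL_Y, mode="nearest")
    return GradientField(gx=gx, gy=gy, gtheta=gradient_angle_image(gx, gy))
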