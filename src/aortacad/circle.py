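"""Fast circle-likeness classifier for aortic cross-sections.

An object's boundary is scanned for pixel pairs ``(p1, p2)`` satisfying
three geometric conditions:

1. the gradient angles at the two pixels are opposed (180 deg apart);
2. the gradient angle at ``p1`` is aligned with the chord through the
   pair (tested modulo 180 deg, a chord being undirected);
3. the chord passes through the object centroid.

The score is the fraction of boundary pixels belonging to at least one
satisfying pair; each pixel counts once no matter how many partners it
has.  Exact equalities are measure-zero on a pixel grid, so explicit
angular and line tolerances are part of the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import AortaObject, BoundaryPair, CircleDecision, GradientField

__all__ = [
    "PairTolerances",
    "DEFAULT_CIRCLE_THRESHOLD",
    "opposed_gradients",
    "gradient_aligned_with_chord",
    "chord_through_centroid",
    "circle_score",
    "classify_shape",
]

#: Fraction of boundary pixels that must participate for "circle_like".
DEFAULT_CIRCLE_THRESHOLD = 0.60

#: Minimum boundary size below which the shape test is degenerate.
MIN_BOUNDARY_PIXELS = 8


@dataclass(frozen=True)
class PairTolerances:
    """Tolerances applied to the three pair conditions."""

    angle_tol_deg: float = 10.0
    line_tol_px: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_tol_deg <= 45.0:
            raise ValueError(f"angle_tol_deg must lie in (0, 45], got {self.angle_tol_deg}")
        if self.line_tol_px < 0:
            raise ValueError(f"line_tol_px must be >= 0, got {self.line_tol_px}")


def _circular_diff_360(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _circular_diff_180(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def opposed_gradients(pair: BoundaryPair, tol: PairTolerances) -> bool:
    """True iff the two gradient angles are within tolerance of 180 deg apart.

    An undefined (NaN) angle at either pixel yields False.
    """
    if math.isnan(pair.gtheta1) or math.isnan(pair.gtheta2):
        return False
    return abs(_circular_diff_360(pair.gtheta1, pair.gtheta2) - 180.0) <= tol.angle_tol_deg


def _chord_angle_deg(p1: tuple[int, int], p2: tuple[int, int]) -> float:
    """Angle of the undirected line through two pixels, degrees mod 180."""
    dr = p2[0] - p1[0]
    dc = p2[1] - p1[1]
    return math.degrees(math.atan2(dr, dc)) % 180.0


def gradient_aligned_with_chord(pair: BoundaryPair, tol: PairTolerances) -> bool:
    """True iff ``gtheta1`` is aligned (mod 180 deg) with the p1-p2 chord."""
    if tuple(pair.p1) == tuple(pair.p2):
        raise ValueError("chord requires two distinct pixels")
    if math.isnan(pair.gtheta1):
        return False
    chord = _chord_angle_deg(pair.p1, pair.p2)
    return _circular_diff_180(pair.gtheta1 % 180.0, chord) <= tol.angle_tol_deg


def chord_through_centroid(
    pair: BoundaryPair,
    centroid: tuple[float, float],
    tol: PairTolerances,
) -> bool:
    """True iff the infinite line through the pair passes within
    ``line_tol_px`` (inclusive) of the centroid."""
    (r1, c1), (r2, c2) = pair.p1, pair.p2
    if (r1, c1) == (r2, c2):
        raise ValueError("chord requires two distinct pixels")
    dr, dc = r2 - r1, c2 - c1
    cr, cc = centroid
    dist = abs(dr * (cc - c1) - dc * (cr - r1)) / math.hypot(dr, dc)
    return dist <= tol.line_tol_px


def circle_score(
    obj: AortaObject,
    field: GradientField,
    tol: PairTolerances = PairTolerances(),
) -> float:
    """Fraction of boundary pixels that have at least one satisfying partner.

    For each boundary pixel ``p1`` the remaining boundary pixels are
    searched for a partner ``p2`` such that all three pair conditions
    hold (the chord-alignment condition uses ``p1``'s angle).  The full
    O(B^2) scan is used; boundaries here stay in the low hundreds.

    Raises
    ------
    ValueError
        If the object has fewer than 8 boundary pixels.
    """
    b = np.asarray(obj.boundary, dtype=float)
    n = len(b)
    if n < MIN_BOUNDARY_PIXELS:
        raise ValueError(f"degenerate object: {n} boundary pixels < {MIN_BOUNDARY_PIXELS}")

    theta = field.gtheta[b[:, 0].astype(int), b[:, 1].astype(int)]
    defined = ~np.isnan(theta)

    dr = b[None, :, 0] - b[:, None, 0]  # [i, j] = row_j - row_i
    dc = b[None, :, 1] - b[:, None, 1]
    off_diag = ~np.eye(n, dtype=bool)

    # condition 1: opposed gradient angles
    d = np.abs(theta[:, None] - theta[None, :]) % 360.0
    d = np.minimum(d, 360.0 - d)
    with np.errstate(invalid="ignore"):
        opposed = np.abs(d - 180.0) <= tol.angle_tol_deg

    # condition 2: p1's gradient aligned with the chord, mod 180
    chord = np.degrees(np.arctan2(dr, dc)) % 180.0
    a = np.abs((theta[:, None] % 180.0) - chord) % 180.0
    a = np.minimum(a, 180.0 - a)
    with np.errstate(invalid="ignore"):
        aligned = a <= tol.angle_tol_deg

    # condition 3: chord passes within line_tol_px of the centroid
    cr, cc = obj.centroid
    cross = dr * (cc - b[:, None, 1]) - dc * (cr - b[:, None, 0])
    length = np.hypot(dr, dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        near = np.where(off_diag, np.abs(cross) / np.where(length > 0, length, 1.0), np.inf)
    through = near <= tol.line_tol_px

    ok = opposed & aligned & through & off_diag
    ok &= defined[:, None] & defined[None, :]
    return float(np.count_nonzero(ok.any(axis=1))) / n


def classify_shape(
    obj: AortaObject,
    field: GradientField,
    threshold: float = DEFAULT_CIRCLE_THRESHOLD,
    tol: PairTolerances = PairTolerances(),
) -> CircleDecision:
    """Label the object circle_like (score reaches the threshold,
    inclusive) or dissection_candidate."""
    return CircleDecision(score=circle_score(obj, field, tol), threshold=threshold)
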