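"""Independent brute-force oracle for the circle-likeness score.

Deliberately coded in plain Python with scalar math (no numpy
broadcasting) so it shares no structure with the vectorised
implementation it checks.
"""

import math


def brute_circle_score(boundary, angles, centroid, angle_tol_deg, line_tol_px):
    """O(B^2) enumeration of satisfying boundary-pixel pairs.

    boundary: list of (row, col); angles: matching list of gradient
    angles in degrees (NaN = undefined); centroid: (row, col).
    Returns (score, satisfied_pixel_count).
    """
    n = len(boundary)
    cr, cc = centroid
    satisfied = 0
    for i in range(n):
        th1 = angles[i]
        if math.isnan(th1):
            continue
        r1, c1 = boundary[i]
        found = False
        for j in range(n):
            if j == i:
                continue
            th2 = angles[j]
            if math.isnan(th2):
                continue
            # opposed gradient angles
            d = abs(th1 - th2) % 360.0
            d = min(d, 360.0 - d)
            if abs(d - 180.0) > angle_tol_deg:
                continue
            r2, c2 = boundary[j]
            # gradient of p1 aligned with the (undirected) chord
            chord = math.degrees(math.atan2(r2 - r1, c2 - c1)) % 180.0
            a = abs(th1 % 180.0 - chord) % 180.0
            a = min(a, 180.0 - a)
            if a > angle_tol_deg:
                continue
            # chord passes near the centroid
            dr, dc = r2 - r1, c2 - c1
            dist = abs(dr * (cc - c1) - dc * (cr - r1)) / math.sqrt(dr * dr + dc * dc)
            if dist > line_tol_px:
                continue
            found = True
            break
        if found:
            satisfied += 1
    return satisfied / n, satisfied
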