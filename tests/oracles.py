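"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised Green's-theorem code paths:
areas and perimeters are plain Python loops, second moments come from a
centroid triangle fan with exact triangle moment formulas, and variances are
two-pass loops.  shapely provides a second independent cross-check where a
geometry library implements the same primitive.
"""

from __future__ import annotations

import math

import numpy as np


def shoelace_area(poly) -> float:
    total = 0.0
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        total += x0 * y1 - x1 * y0
    return abs(total) / 2.0


def perimeter_loop(poly) -> float:
    total = 0.0
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        total += math.hypot(x1 - x0, y1 - y0)
    return total


def centroid_loop(poly) -> tuple[float, float]:
    a = 0.0
    cx = cy = 0.0
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        c = x0 * y1 - x1 * y0
        a += c
        cx += (x0 + x1) * c
        cy += (y0 + y1) * c
    a /= 2.0
    return cx / (6 * a), cy / (6 * a)


def second_moments_triangle_fan(poly) -> np.ndarray:
    """Central second moments via a centroid triangle fan (exact per triangle).

    For a triangle with vertices p0, p1, p2 the second moment about its own
    centroid is (sum of squared edge midpoint offsets)/ ... the closed form
    used here integrates x_i x_j over the triangle directly:
    integral over T of x^a y^b dA with vertices v0,v1,v2 via the standard
    formula I = (A/12) * (sum_i sum_j<=i vi_a vj_b-ish); implemented with the
    exact quadratic-moment identity below.
    """
    poly = np.asarray(poly, dtype=float)
    cx, cy = centroid_loop(poly)
    origin = np.array([cx, cy])
    total_area = 0.0
    M = np.zeros((2, 2))
    n = len(poly)
    for i in range(n):
        p1 = poly[i] - origin
        p2 = poly[(i + 1) % n] - origin
        cross = p1[0] * p2[1] - p2[0] * p1[1]
        a = cross / 2.0  # signed triangle area (origin, p1, p2)
        total_area += a
        # integral of x_a x_b over triangle with one vertex at origin:
        # A/12 * (p1 p1^T + p2 p2^T + (p1+p2)(p1+p2)^T)
        outer = (
            np.outer(p1, p1) + np.outer(p2, p2) + np.outer(p1 + p2, p1 + p2)
        )
        M += a / 12.0 * outer
    return M / total_area


def aspect_from_fan(poly) -> float:
    evals = np.linalg.eigvalsh(second_moments_triangle_fan(poly))
    return math.sqrt(evals[1] / evals[0])


def radius_ratio_loop(poly) -> float:
    cx, cy = centroid_loop(poly)
    dmax = 0.0
    dmin = float("inf")
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        dmax = max(dmax, math.hypot(x0 - cx, y0 - cy))
        x1, y1 = poly[(i + 1) % n]
        # point-to-segment distance by scalar projection
        vx, vy = x1 - x0, y1 - y0
        L2 = vx * vx + vy * vy
        t = 0.0 if L2 == 0 else max(0.0, min(1.0, ((cx - x0) * vx + (cy - y0) * vy) / L2))
        dmin = min(dmin, math.hypot(x0 + t * vx - cx, y0 + t * vy - cy))
    return dmax / dmin


def variance_two_pass(values) -> float:
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / (n - 1)


def descriptor_reference(poly) -> dict:
    """All seven descriptors from the loop/fan oracles."""
    area = shoelace_area(poly)
    perim = perimeter_loop(poly)
    xs = [p[0] for p in poly]
    ys = [p[1] for p in poly]
    return {
        "area": area,
        "perimeter": perim,
        "aspect": aspect_from_fan(poly),
        "area_box": area / ((max(xs) - min(xs)) * (max(ys) - min(ys))),
        "radius_ratio": radius_ratio_loop(poly),
        "roundness": perim**2 / (4 * math.pi * area),
        "circularity": 4 * math.pi * area / perim**2,
    }
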