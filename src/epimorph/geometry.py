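"""Planar geometry primitives shared across the package.

All coordinates live in a right-handed (AP, DV) frame in micrometres:
AP = +x toward the posterior, DV = +y away from the ventral midline.
Undirected angles (interface orientations, cell long axes) are reported in
degrees from the AP axis in [0, 90]; directed axis angles (bipolarity phase,
ellipse long axis) in [0, 180).
"""

from __future__ import annotations

import numpy as np

AP = np.array([1.0, 0.0])
DV = np.array([0.0, 1.0])

__all__ = [
    "AP",
    "DV",
    "polygon_area",
    "polygon_centroid",
    "polygon_second_moment",
    "ensure_ccw",
    "equivalent_ellipse",
    "spd_pow",
    "spd_log",
    "spd_map",
    "acute_angle_from_ap",
    "directed_angle_from_ap",
]


def _cross_terms(points: np.ndarray):
    p = np.asarray(points, dtype=float)
    q = np.roll(p, -1, axis=0)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    return p, q, cross


def polygon_area(points) -> float:
    """Signed shoelace area (positive for counter-clockwise loops)."""
    _, _, cross = _cross_terms(points)
    return 0.5 * float(np.sum(cross))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if polygon_area(points) < 0:
        return points[::-1]
    return points


def polygon_centroid(points) -> np.ndarray:
    p, q, cross = _cross_terms(points)
    a = 0.5 * np.sum(cross)
    if a == 0:
        return np.mean(p, axis=0)
    cx = np.sum((p[:, 0] + q[:, 0]) * cross) / (6.0 * a)
    cy = np.sum((p[:, 1] + q[:, 1]) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_second_moment(points) -> np.ndarray:
    """Area-normalised central second-moment (covariance) tensor of a polygon.

    For a rectangle of side lengths (a, b) this is diag(a^2/12, b^2/12); for
    the ellipse with semi-axes (a, b) it is diag(a^2/4, b^2/4).
    """
    p, q, cross = _cross_terms(points)
    a = 0.5 * np.sum(cross)
    if a == 0:
        raise ValueError("degenerate polygon with zero area")
    c = polygon_centroid(points)
    x0, y0 = p[:, 0], p[:, 1]
    x1, y1 = q[:, 0], q[:, 1]
    ixx = np.sum((x0 * x0 + x0 * x1 + x1 * x1) * cross) / 12.0
    iyy = np.sum((y0 * y0 + y0 * y1 + y1 * y1) * cross) / 12.0
    ixy = np.sum((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross) / 24.0
    cov = np.array([[ixx, ixy], [ixy, iyy]]) / a - np.outer(c, c)
    return cov


def equivalent_ellipse(moment: np.ndarray):
    """(semi_major, semi_minor, directed long-axis angle deg in [0, 180)).

    The ellipse with the same area-normalised second moments as the shape:
    semi-axis = 2 * sqrt(eigenvalue).
    """
    w, v = np.linalg.eigh(np.asarray(moment, dtype=float))
    w = np.clip(w, 0.0, None)
    a = 2.0 * np.sqrt(w[1])
    b = 2.0 * np.sqrt(w[0])
    theta = directed_angle_from_ap(v[:, 1])
    return a, b, theta


def spd_pow(mat: np.ndarray, power: float) -> np.ndarray:
    """Real power of a symmetric positive-definite 2x2 matrix."""
    w, v = np.linalg.eigh(np.asarray(mat, dtype=float))
    if np.any(w <= 0):
        raise ValueError("matrix is not positive definite")
    return (v * w**power) @ v.T


def spd_log(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(np.asarray(mat, dtype=float))
    if np.any(w <= 0):
        raise ValueError("matrix is not positive definite")
    return (v * np.log(w)) @ v.T


def spd_map(s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    """The unique SPD tensor F with F @ s0 @ F = s1.

    This is the symmetric deformation mapping one second-moment ellipse onto
    another: F = s0^(-1/2) (s0^(1/2) s1 s0^(1/2))^(1/2) s0^(-1/2).
    """
    r = spd_pow(s0, 0.5)
    rinv = spd_pow(s0, -0.5)
    inner = spd_pow(r @ s1 @ r, 0.5)
    return rinv @ inner @ rinv


def acute_angle_from_ap(vec) -> float:
    """Undirected angle of a vector from the AP axis, degrees in [0, 90]."""
    vec = np.asarray(vec, dtype=float)
    n = np.hypot(vec[0], vec[1])
    if n == 0:
        return float("nan")
    return float(np.degrees(np.arccos(min(1.0, abs(vec[0]) / n))))


def directed_angle_from_ap(vec) -> float:
    """Directed axis angle of a vector from AP, degrees in [0, 180)."""
    vec = np.asarray(vec, dtype=float)
    ang = np.degrees(np.arctan2(vec[1], vec[0])) % 180.0
    return float(ang)
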