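"""Strain-rate tensors and cell-shape metrics.

The local tissue strain rate is the symmetric part of a least-squares linear
fit of centroid velocities over a focal cell plus its first-ring neighbours.
The cell-shape strain rate is the symmetric part of the best affine map of
the cell's own boundary across the window (falling back to a second-moment
log-map when boundary correspondence is unavailable). The intercalation
strain rate is their difference, so the decomposition

    tissue = cell shape + intercalation

holds exactly by construction. All rates are in proportion/min (pp/min);
time derivatives use a centred window of +/-2 frames (1 minute each side at
the standard 30-s frame interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    AP,
    DV,
    directed_angle_from_ap,
    equivalent_ellipse,
    polygon_second_moment,
    spd_log,
    spd_map,
)
from .mesh import TrackSet

RATE_WINDOW_FRAMES = 2  # +/- frames for all centred derivatives


@dataclass
class StrainTensor2:
    """Symmetric 2x2 rate-of-deformation tensor in the (AP, DV) frame,
    units proportion/min."""

    exx: float
    exy: float
    eyy: float
    time_min: float | None = None
    domain_id: int | None = None

    @classmethod
    def from_matrix(cls, m, time_min=None, domain_id=None) -> "StrainTensor2":
        m = np.asarray(m, dtype=float)
        s = 0.5 * (m + m.T)
        return cls(s[0, 0], s[0, 1], s[1, 1], time_min, domain_id)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.exx, self.exy], [self.exy, self.eyy]])

    def project(self, axis) -> float:
        """u^T E u for a unit axis; axis may be 'ap', 'dv' or a vector."""
        if isinstance(axis, str):
            u = {"ap": AP, "dv": DV}[axis.lower()]
        else:
            u = np.asarray(axis, dtype=float)
            u = u / np.linalg.norm(u)
        return float(u @ self.matrix @ u)

    @property
    def trace(self) -> float:
        return self.exx + self.eyy

    def __sub__(self, other: "StrainTensor2") -> "StrainTensor2":
        return StrainTensor2(
            self.exx - other.exx, self.exy - other.exy, self.eyy - other.eyy,
            self.time_min, self.domain_id,
        )

    def __add__(self, other: "StrainTensor2") -> "StrainTensor2":
        return StrainTensor2(
            self.exx + other.exx, self.exy + other.exy, self.eyy + other.eyy,
            self.time_min, self.domain_id,
        )


def project(tensor: StrainTensor2, axis) -> float:
    return tensor.project(axis)


def _window_ok(ts: TrackSet, cid: int, idx: int, window: int) -> bool:
    lo, hi = idx - window, idx + window
    if lo < 0 or hi >= ts.n_frames:
        return False
    return cid in ts.frames[lo].cells and cid in ts.frames[hi].cells


def tissue_strain_rate(
    ts: TrackSet, cell_id: int, frame_idx: int, window: int = RATE_WINDOW_FRAMES
) -> StrainTensor2 | None:
    """Symmetric part of the linear velocity-gradient fit over the focal cell
    and its first-ring neighbours; None (undefined) with < 3 usable
    neighbours."""
    dt_min = ts.frame_interval_s / 60.0
    elapsed = 2 * window * dt_min
    if not _window_ok(ts, cell_id, frame_idx, window):
        return None
    frame = ts.frames[frame_idx]
    domain = [cell_id] + sorted(frame.neighbours(cell_id))
    pos, vel = [], []
    for cid in domain:
        if not _window_ok(ts, cid, frame_idx, window) or cid not in frame.cells:
            continue
        c0 = ts.frames[frame_idx - window].cells[cid].centroid
        c1 = ts.frames[frame_idx + window].cells[cid].centroid
        pos.append(frame.cells[cid].centroid)
        vel.append((c1 - c0) / elapsed)
    if len(pos) < 4:  # focal + >= 3 neighbours
        return None
    pos = np.asarray(pos)
    vel = np.asarray(vel)
    a = np.column_stack([pos - pos.mean(axis=0), np.ones(len(pos))])
    coef, *_ = np.linalg.lstsq(a, vel, rcond=None)
    grad = coef[:2].T  # L with v = L x + c
    return StrainTensor2.from_matrix(
        grad, time_min=ts.times_min[frame_idx], domain_id=cell_id
    )


def _matched_boundary(ts: TrackSet, cid: int, i0: int, i1: int):
    """Index-matched boundary vertex positions at two frames, or None.

    Mesh-backed tracks carry per-cell vertex ids in ``polygon_vertex_ids``
    attached by the synthetic generator / mesh converter.
    """
    f0, f1 = ts.frames[i0], ts.frames[i1]
    c0, c1 = f0.cells.get(cid), f1.cells.get(cid)
    if c0 is None or c1 is None:
        return None
    ids0 = getattr(c0, "vertex_ids", None)
    ids1 = getattr(c1, "vertex_ids", None)
    if ids0 is None or ids1 is None:
        return None
    common = [v for v in ids0 if v in set(ids1)]
    if len(common) < 3:
        return None
    m0 = {v: p for v, p in zip(ids0, c0.polygon)}
    m1 = {v: p for v, p in zip(ids1, c1.polygon)}
    p0 = np.array([m0[v] for v in common])
    p1 = np.array([m1[v] for v in common])
    return p0, p1


def cell_shape_strain_rate(
    ts: TrackSet, cell_id: int, frame_idx: int, window: int = RATE_WINDOW_FRAMES
) -> StrainTensor2 | None:
    """Rate tensor of the best mapping of the cell's shape across the window.

    Primary estimator: least-squares affine map of index-matched boundary
    vertices from t-window to t+window; the rate is the symmetric part of
    log(F)/elapsed. Exact for affine motion and exactly zero for rigid
    rotation. Fallback (no vertex correspondence): SPD log-map between the
    cell's second-moment tensors, which cannot see rotations.
    """
    from scipy.linalg import logm

    dt_min = ts.frame_interval_s / 60.0
    elapsed = 2 * window * dt_min
    if not _window_ok(ts, cell_id, frame_idx, window):
        return None
    i0, i1 = frame_idx - window, frame_idx + window
    matched = _matched_boundary(ts, cell_id, i0, i1)
    if matched is not None:
        p0, p1 = matched
        a = np.column_stack([p0 - p0.mean(axis=0), np.ones(len(p0))])
        coef, *_ = np.linalg.lstsq(a, p1 - p1.mean(axis=0) + p0.mean(axis=0),
                                   rcond=None)
        f = coef[:2].T
        if np.linalg.det(f) <= 0:
            return None
        rate = logm(f).real / elapsed
    else:
        c0 = ts.frames[i0].cells[cell_id]
        c1 = ts.frames[i1].cells[cell_id]
        try:
            s0 = polygon_second_moment(c0.polygon)
            s1 = polygon_second_moment(c1.polygon)
            f = spd_map(s0, s1)
        except (ValueError, np.linalg.LinAlgError):
            return None
        rate = spd_log(f) / elapsed
    return StrainTensor2.from_matrix(
        rate, time_min=ts.times_min[frame_idx], domain_id=cell_id
    )


def intercalation_strain_rate(
    tissue: StrainTensor2, cell_shape: StrainTensor2
) -> StrainTensor2:
    """Tissue minus cell-shape strain rate (same domain and time)."""
    if tissue.domain_id != cell_shape.domain_id or not np.isclose(
        tissue.time_min, cell_shape.time_min
    ):
        raise ValueError("tensors describe different domains or times")
    return tissue - cell_shape


def area_strain_rate(
    ts: TrackSet, cell_id: int, frame_idx: int, window: int = RATE_WINDOW_FRAMES
) -> float:
    """d(ln area)/dt in pp/min via centred difference; NaN when undefined."""
    dt_min = ts.frame_interval_s / 60.0
    if not _window_ok(ts, cell_id, frame_idx, window):
        return float("nan")
    a0 = ts.frames[frame_idx - window].cells[cell_id].area_um2
    a1 = ts.frames[frame_idx + window].cells[cell_id].area_um2
    if a0 <= 0 or a1 <= 0:
        return float("nan")
    return float((np.log(a1) - np.log(a0)) / (2 * window * dt_min))


@dataclass
class ShapeEllipse:
    """Equivalent second-moment ellipse of a cell outline."""

    semi_major: float
    semi_minor: float
    orientation_deg: float  # directed long-axis angle from AP, [0, 180)

    @classmethod
    def from_polygon(cls, polygon) -> "ShapeEllipse":
        a, b, theta = equivalent_ellipse(polygon_second_moment(polygon))
        return cls(a, b, theta)

    @property
    def eccentricity(self) -> float:
        """(a - b) / (a + b), 0 for a circle."""
        return (self.semi_major - self.semi_minor) / (self.semi_major + self.semi_minor)

    @property
    def is_isotropic(self) -> bool:
        return self.eccentricity < 1e-9


def cell_orientation(shape: ShapeEllipse) -> float:
    """Acute angle of the long axis from AP, degrees in [0, 90]; NaN for
    isotropic shapes (orientation undefined)."""
    if shape.is_isotropic:
        return float("nan")
    theta = shape.orientation_deg % 180.0
    return theta if theta <= 90.0 else 180.0 - theta


def axial_shape_elongation(shape: ShapeEllipse) -> float:
    """Signed combined elongation-and-orientation measure in [-1, 1].

    value = e * (-cos 2*theta), e = (a-b)/(a+b), theta the directed long-axis
    angle from AP: +1 for strong DV elongation, -1 for strong AP elongation,
    0 for isotropic cells or cells elongated at 45 degrees.
    """
    e = shape.eccentricity
    if e == 0:
        return 0.0
    theta = np.radians(shape.orientation_deg)
    return float(e * (-np.cos(2 * theta)))


def rate_of_change(series, dt_min: float, window: int = RATE_WINDOW_FRAMES):
    """Centred per-minute derivative of a per-frame series.

    x'(t) = (x[t+window] - x[t-window]) / elapsed minutes; NaN where the
    window is truncated at the ends (undefined, never extrapolated).
    """
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    if len(x) > 2 * window:
        out[window:-window] = (x[2 * window:] - x[:-2 * window]) / (
            2 * window * dt_min
        )
    return out


def projection_deficit_pct(misalignment_deg: float) -> float:
    """Maximum projected-strain-rate deficit (%) from a misalignment angle:
    100 * (1 - cos(angle))."""
    return 100.0 * (1.0 - float(np.cos(np.radians(misalignment_deg))))


def compute_cell_metrics(
    ts: TrackSet,
    window: int = RATE_WINDOW_FRAMES,
    cell_types: tuple = ("ectoderm", "unassigned"),
) -> pd.DataFrame:
    """Per-cell-per-frame kinematics table.

    Columns: tissue/cell-shape/intercalation tensor components and AP/DV
    projections, area strain rate, orientation, axial elongation, centroid
    position. Undefined values are NaN and excluded from all summaries.
    """
    rows = []
    times = ts.times_min
    for idx, frame in enumerate(ts.frames):
        for cid, cell in frame.cells.items():
            if cell.type_label not in cell_types:
                continue
            tis = tissue_strain_rate(ts, cid, idx, window)
            shp = cell_shape_strain_rate(ts, cid, idx, window)
            inter = tis - shp if (tis is not None and shp is not None) else None
            ell = ShapeEllipse.from_polygon(cell.polygon)
            row = dict(
                cell_id=cid, frame=idx, time_min=times[idx],
                x_um=cell.centroid[0], y_um=cell.centroid[1],
                area_um2=cell.area_um2, type=cell.type_label,
                area_rate=area_strain_rate(ts, cid, idx, window),
                orientation_deg=cell_orientation(ell),
                axial_elongation=axial_shape_elongation(ell),
            )
            for name, t in (("tissue", tis), ("shape", shp), ("intercalation", inter)):
                if t is None:
                    row.update({f"{name}_xx": np.nan, f"{name}_xy": np.nan,
                                f"{name}_yy": np.nan, f"{name}_ap": np.nan,
                                f"{name}_dv": np.nan})
                else:
                    row.update({f"{name}_xx": t.exx, f"{name}_xy": t.exy,
                                f"{name}_yy": t.eyy, f"{name}_ap": t.project("ap"),
                                f"{name}_dv": t.project("dv")})
            rows.append(row)
    return pd.DataFrame(rows)
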