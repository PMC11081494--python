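"""Junctional fluorescence processing and planar-polarity quantification.

The pipeline: (i) channel normalisation (per-frame background zeroing at the
5th percentile, then a single histogram stretch putting the reference frame's
98.5th percentile at greyscale 200, clipped at 255); (ii) optional channel
registration by fractional flow; (iii) per-interface mean densities from
1-pixel junction lines with vertex-proximal pixels excluded; (iv) per-cell
period-2 (bipolar) Fourier measure with cell unstretching, and its projection
onto the AP axis.

Phase convention: the period-2 harmonic is fit against junction *orientation*
(directed angle mod 180 deg from AP), so phase 90 deg means enrichment on
DV-oriented junctions, i.e. intensity peaks at the cell's anterior and
posterior faces; the AP projection amplitude*cos 2(phase - 90 deg) is then
positive for the planar-polarised configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .geometry import directed_angle_from_ap, polygon_second_moment, spd_pow
from .mesh import Frame

DEFAULTS = dict(
    background_percentile=5.0,
    reference_percentile=98.5,
    reference_grey=200.0,
    ceiling=255.0,
    vertex_exclusion_px=2.0,
)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalise_channel(
    stack: np.ndarray,
    reference_frame: int,
    background_percentile: float = 5.0,
    reference_percentile: float = 98.5,
    reference_grey: float = 200.0,
    ceiling: float = 255.0,
) -> np.ndarray:
    """Normalise a fluorescence stack to a common greyscale.

    Per frame, pixels at or below that frame's background percentile are set
    to zero; then every frame is scaled by the single factor
    ``reference_grey / P_ref(reference frame)`` and clipped at ``ceiling``.
    Accepts a (T, H, W) stack or a single 2D frame (treated as T=1).
    """
    arr = np.asarray(stack, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if not 0 <= reference_frame < len(arr):
        raise ValueError("reference frame outside the sequence")
    zeroed = np.empty_like(arr)
    for t, frame in enumerate(arr):
        thr = np.percentile(frame, background_percentile)
        zeroed[t] = np.where(frame <= thr, 0.0, frame)
    ref_val = np.percentile(zeroed[reference_frame], reference_percentile)
    if ref_val <= 0:
        raise ValueError("reference frame has no signal above background")
    out = np.clip(zeroed * (reference_grey / ref_val), 0.0, ceiling)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Channel registration
# ---------------------------------------------------------------------------

def register_sample(
    image: np.ndarray,
    points_rc: np.ndarray,
    flow_rc: np.ndarray,
    offset_fraction: float,
):
    """Sample ``image`` at points displaced by a fraction of their predicted
    inter-frame flow.

    ``points_rc`` and ``flow_rc`` are (n, 2) in (row, col) pixels; the flow is
    the full frame-to-frame displacement, of which ``offset_fraction`` (the
    channel time offset divided by the frame interval) is applied. Returns
    (displaced points, bilinear samples).
    """
    if not 0.0 <= offset_fraction <= 1.0:
        raise ValueError("offset_fraction must be in [0, 1]")
    pts = np.asarray(points_rc, dtype=float) + offset_fraction * np.asarray(
        flow_rc, dtype=float
    )
    vals = ndi.map_coordinates(np.asarray(image, dtype=float), pts.T, order=1,
                               mode="nearest")
    return pts, vals


def predict_pixel_flow(
    frame_t: Frame,
    frame_t1: Frame,
    points_rc: np.ndarray,
    cell_id: int,
    shape_strain: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted frame-to-frame flow of junction pixels of a focal cell.

    The flow is the focal cell's centroid displacement plus, when a cell-shape
    strain-rate tensor (pp/min, AP/DV frame) is given, the shape deformation
    applied about the centroid over the frame interval.
    """
    c0 = frame_t.cells[cell_id]
    c1 = frame_t1.cells.get(cell_id)
    if c1 is None:
        return np.zeros_like(np.asarray(points_rc, dtype=float))
    px = frame_t.pixel_size_um or 1.0
    disp_um = c1.centroid - c0.centroid
    pts = np.asarray(points_rc, dtype=float)
    xy_um = np.column_stack([(pts[:, 1] + 0.5), (pts[:, 0] + 0.5)]) * px
    flow_um = np.tile(disp_um, (len(pts), 1))
    if shape_strain is not None:
        dt_min = (frame_t1.time_s - frame_t.time_s) / 60.0
        flow_um = flow_um + (xy_um - c0.centroid) @ (
            np.asarray(shape_strain, dtype=float).T * dt_min
        )
    return np.column_stack([flow_um[:, 1], flow_um[:, 0]]) / px


# ---------------------------------------------------------------------------
# Junctional pools
# ---------------------------------------------------------------------------

def _um_to_rc(points_um: np.ndarray, pixel_size: float) -> np.ndarray:
    pts = np.atleast_2d(points_um)
    return np.column_stack([pts[:, 1] / pixel_size - 0.5,
                            pts[:, 0] / pixel_size - 0.5])


def junction_line_pixels(p0_rc, p1_rc, shape) -> np.ndarray:
    """Pixels of the two 1-pixel cortical lines of a junction.

    A shared junction is bounded by the two abutting cells' cortices; it is
    rasterised (and measured) as the straight vertex-to-vertex line offset
    half a pixel to either side, mirroring the two per-cell boundary lines
    whose values are averaged for shared interfaces.
    """
    p0 = np.asarray(p0_rc, dtype=float)
    p1 = np.asarray(p1_rc, dtype=float)
    seg = p1 - p0
    n = np.hypot(*seg)
    normal = np.array([-seg[1], seg[0]]) / n if n > 0 else np.array([0.0, 0.0])
    pts = []
    for off in (0.5, -0.5):
        (r0, c0), (r1, c1) = np.round([p0 + off * normal,
                                       p1 + off * normal]).astype(int)
        rr, cc = draw_line(r0, c0, r1, c1)
        pts.append(np.column_stack([rr, cc]))
    out = np.unique(np.vstack(pts), axis=0)
    ok = (
        (out[:, 0] >= 0) & (out[:, 0] < shape[0])
        & (out[:, 1] >= 0) & (out[:, 1] < shape[1])
    )
    return out[ok]


def _interface_line_pixels(iface, pixel_size: float, shape) -> np.ndarray:
    p0, p1 = _um_to_rc(iface.endpoints, pixel_size)
    return junction_line_pixels(p0, p1, shape)


def _exclude_near_vertices(pixels_rc, vertices_rc, radius_px):
    if len(pixels_rc) == 0 or len(vertices_rc) == 0:
        return pixels_rc
    d2 = ((pixels_rc[:, None, :] - vertices_rc[None]) ** 2).sum(-1)
    return pixels_rc[(d2 > radius_px**2).all(axis=1)]


def quantify_interface_myosin(
    frame: Frame,
    image: np.ndarray,
    vertex_exclusion_px: float = 2.0,
    sample_points: dict | None = None,
):
    """Mean junctional fluorescence per interface, plus vertex and
    nonjunctional pools.

    Interfaces carry 1-pixel lines (from the label image's two per-cell
    boundary lines when available, else the straight vertex-to-vertex
    rasterisation); pixels within ``vertex_exclusion_px`` of a vertex are
    removed from the junctional pool and reported as the vertex pool. The
    nonjunctional pool is the remaining pixels of each cell.

    ``sample_points`` optionally overrides pixel positions with registered
    (row, col) float coordinates per interface pair (see `register_sample`).
    Returns (interface DataFrame, cell DataFrame).
    """
    img = np.asarray(image, dtype=float)
    px = frame.pixel_size_um or 1.0
    # the exclusion zone covers both the sub-pixel vertex point and its
    # nearest pixel centre, so vertex-pixel structures never leak into
    # junctional densities
    if len(frame.vertices):
        exact = _um_to_rc(frame.vertices, px)
        vertices_rc = np.vstack([exact, np.round(exact)])
    else:
        vertices_rc = np.empty((0, 2))

    junctional_mask = np.zeros(img.shape, dtype=bool)
    vertex_mask = np.zeros(img.shape, dtype=bool)
    if len(vertices_rc):
        vr = np.round(vertices_rc).astype(int)
        rad = int(np.ceil(vertex_exclusion_px))
        for r, c in vr:
            rr, cc = np.meshgrid(
                np.arange(r - rad, r + rad + 1), np.arange(c - rad, c + rad + 1),
                indexing="ij",
            )
            keep = ((rr - r) ** 2 + (cc - c) ** 2 <= vertex_exclusion_px**2) & (
                (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
            )
            vertex_mask[rr[keep], cc[keep]] = True

    rows = []
    for pair, iface in frame.interfaces.items():
        a, b = sorted(pair)
        if sample_points is not None and pair in sample_points:
            pts = np.asarray(sample_points[pair], dtype=float)
            pts = _exclude_near_vertices(pts, vertices_rc, vertex_exclusion_px)
            if len(pts) == 0:
                density, n_pix = np.nan, 0
            else:
                density = float(
                    ndi.map_coordinates(img, pts.T, order=1, mode="nearest").mean()
                )
                n_pix = len(pts)
        elif iface.pixel_lines is not None:
            side_means, n_pix = [], 0
            for cid in (a, b):
                pix = np.asarray(iface.pixel_lines[cid], dtype=float)
                pix = _exclude_near_vertices(pix, vertices_rc, vertex_exclusion_px)
                if len(pix):
                    ij = pix.astype(int)
                    side_means.append(img[ij[:, 0], ij[:, 1]].mean())
                    junctional_mask[ij[:, 0], ij[:, 1]] = True
                    n_pix += len(pix)
            density = float(np.mean(side_means)) if side_means else np.nan
        else:
            pix = _interface_line_pixels(iface, px, img.shape).astype(float)
            pix = _exclude_near_vertices(pix, vertices_rc, vertex_exclusion_px)
            if len(pix) == 0:
                density, n_pix = np.nan, 0
            else:
                ij = pix.astype(int)
                density = float(img[ij[:, 0], ij[:, 1]].mean())
                junctional_mask[ij[:, 0], ij[:, 1]] = True
                n_pix = len(pix)
        rows.append(dict(cell_a=a, cell_b=b, density=density, n_pixels=n_pix))
    iface_df = pd.DataFrame(rows)

    cell_rows = []
    for cid, cell in frame.cells.items():
        if frame.labels is not None:
            inside = frame.labels == cid
        else:
            rc = _um_to_rc(cell.polygon, px)
            rr, cc = draw_polygon(rc[:, 0], rc[:, 1], shape=img.shape)
            inside = np.zeros(img.shape, dtype=bool)
            inside[rr, cc] = True
        nonj = inside & ~junctional_mask & ~vertex_mask
        cell_rows.append(
            dict(
                cell_id=cid,
                nonjunctional_mean=float(img[nonj].mean()) if nonj.any() else np.nan,
                vertex_mean=float(img[inside & vertex_mask].mean())
                if (inside & vertex_mask).any() else np.nan,
            )
        )
    return iface_df, pd.DataFrame(cell_rows)


# ---------------------------------------------------------------------------
# Bipolarity
# ---------------------------------------------------------------------------

@dataclass
class BipolarityMeasure:
    """Period-2 planar-polarity measure of junctional fluorescence.

    ``amplitude`` in fluorescence-intensity units; ``phase_deg`` the junction
    orientation of enrichment in [0, 180); ``mean_density`` the weighted mean
    interface fluorescence.
    """

    amplitude: float
    phase_deg: float
    mean_density: float

    @property
    def ap_projected(self) -> float:
        return project_bipolarity(self)


def _unstretch_transform(polygon: np.ndarray) -> np.ndarray:
    s = polygon_second_moment(polygon)
    s = s / np.sqrt(np.linalg.det(s))  # det-normalised: pure shape, no size
    return spd_pow(s, -0.5)


def bipolarity(
    cell,
    interface_densities: dict,
    frame: Frame,
    unstretch: bool = True,
) -> BipolarityMeasure | None:
    """Period-2 Fourier component of interface fluorescence around a cell.

    ``interface_densities`` maps the cell's interfaces (frozenset pairs) to
    densities. Each interface contributes one sample at its junction
    orientation angle; samples are weighted by the interface's angular extent
    about the centroid measured on the *unstretched* outline (boundary mapped
    by the inverse square root of the cell's det-normalised second-moment
    tensor), so that elongated cells do not bias the harmonic through unequal
    interface coverage. The period-2 harmonic is then fit by weighted least
    squares. Returns None for cells with < 3 interfaces with defined
    densities.
    """
    pairs = [p for p in frame.interfaces if cell.id in p]
    t = _unstretch_transform(cell.polygon) if unstretch else np.eye(2)

    angles, weights, values = [], [], []
    for pair in pairs:
        d = interface_densities.get(pair)
        if d is None or not np.isfinite(d):
            continue
        iface = frame.interfaces[pair]
        seg = iface.endpoints[1] - iface.endpoints[0]
        if np.hypot(*seg) == 0:
            continue
        ang = np.radians(directed_angle_from_ap(seg))
        e0, e1 = (iface.endpoints - cell.centroid) @ t.T
        a0 = np.arctan2(e0[1], e0[0])
        a1 = np.arctan2(e1[1], e1[0])
        extent = abs((a1 - a0 + np.pi) % (2 * np.pi) - np.pi)
        angles.append(ang)
        weights.append(extent)
        values.append(d)
    if len(values) < 3:
        return None
    angles = np.array(angles)
    w = np.array(weights)
    v = np.array(values)
    design = np.column_stack([np.ones_like(angles), np.cos(2 * angles),
                              np.sin(2 * angles)])
    sw = np.sqrt(w / w.sum())
    coef, *_ = np.linalg.lstsq(design * sw[:, None], v * sw, rcond=None)
    mean, a_c, a_s = coef
    amplitude = float(np.hypot(a_c, a_s))
    phase = float(np.degrees(0.5 * np.arctan2(a_s, a_c)) % 180.0)
    return BipolarityMeasure(amplitude, phase, float(mean))


def project_bipolarity(b: BipolarityMeasure) -> float:
    """Signed AP projection: amplitude * cos 2(phase - 90 deg).

    Positive when enrichment sits on DV-oriented junctions (intensity peaks at
    the cell's anterior and posterior faces)."""
    return float(b.amplitude * np.cos(2 * np.radians(b.phase_deg - 90.0)))


def cell_bipolarity_table(
    frame: Frame,
    iface_df: pd.DataFrame,
    unstretch: bool = True,
    cell_types: tuple = ("ectoderm", "unassigned"),
) -> pd.DataFrame:
    """Per-cell bipolarity measures from a per-interface density table."""
    densities = {
        frozenset((int(r.cell_a), int(r.cell_b))): r.density
        for r in iface_df.itertuples()
    }
    rows = []
    for cid, cell in frame.cells.items():
        if cell.type_label not in cell_types:
            continue
        b = bipolarity(cell, densities, frame, unstretch=unstretch)
        if b is None:
            continue
        rows.append(
            dict(cell_id=cid, amplitude=b.amplitude, phase_deg=b.phase_deg,
                 ap_projected=b.ap_projected, mean_density=b.mean_density)
        )
    return pd.DataFrame(rows)
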