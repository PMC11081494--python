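"""Tracked cell-mesh data model and I/O.

A movie is a :class:`TrackSet`: an ordered list of :class:`Frame` objects in
which cell ids are stable track identifiers. Frames can be built from integer
label images (`build_frame` + `link_frames`) or arrive pre-linked from the
synthetic generator / delimited tables.

Geometry is in micrometres in the (AP, DV) frame; pixel (row, col) centres map
to x = (col + 0.5) * pixel_size, y = (row + 0.5) * pixel_size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import (
    acute_angle_from_ap,
    ensure_ccw,
    polygon_area,
    polygon_centroid,
)

CELL_TYPES = ("ectoderm", "mesoderm", "mesectoderm", "excluded", "unassigned")


class FormatError(ValueError):
    """Raised for malformed input images or tables."""


class DegenerateCellError(ValueError):
    """Raised when a label is too small to carry a boundary polygon."""


@dataclass
class Cell:
    id: int
    polygon: np.ndarray  # (n, 2) ordered boundary points, um
    centroid: np.ndarray
    area_um2: float
    type_label: str = "unassigned"

    @classmethod
    def from_polygon(cls, cid: int, polygon, type_label: str = "unassigned") -> "Cell":
        poly = ensure_ccw(np.asarray(polygon, dtype=float))
        area = polygon_area(poly)
        if not np.isfinite(poly).all():
            raise FormatError(f"cell {cid}: non-finite polygon coordinates")
        if area <= 0:
            raise DegenerateCellError(f"cell {cid}: non-positive area")
        return cls(cid, poly, polygon_centroid(poly), float(area), type_label)


@dataclass
class Interface:
    cell_pair: frozenset
    endpoints: np.ndarray  # (2, 2) um
    length_um: float
    orientation_deg: float  # from AP axis, [0, 90]
    pixel_lines: dict | None = None  # cell id -> (n, 2) array of (row, col)

    @classmethod
    def from_endpoints(cls, pair, p0, p1, pixel_lines=None) -> "Interface":
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        length = float(np.hypot(*(p1 - p0)))
        orient = acute_angle_from_ap(p1 - p0) if length > 0 else float("nan")
        return cls(frozenset(pair), np.array([p0, p1]), length, orient, pixel_lines)


@dataclass
class Frame:
    index: int
    time_s: float
    cells: dict  # cell id -> Cell
    interfaces: dict  # frozenset pair -> Interface
    vertices: np.ndarray  # (v, 2) um, points where >= 3 cells meet
    pixel_size_um: float | None = None
    labels: np.ndarray | None = None  # original label image, when image-backed

    def interface(self, a: int, b: int) -> Interface | None:
        return self.interfaces.get(frozenset((a, b)))

    def neighbour_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        for pair in self.interfaces:
            g.add_edge(*pair)
        return g

    def neighbour_map(self) -> dict:
        """Cell id -> neighbouring cell ids (cached; call `invalidate_cache`
        after mutating interfaces)."""
        cached = getattr(self, "_nbmap", None)
        if cached is None:
            cached = {cid: set() for cid in self.cells}
            for pair in self.interfaces:
                a, b = pair
                cached.setdefault(a, set()).add(b)
                cached.setdefault(b, set()).add(a)
            self._nbmap = cached
        return cached

    def invalidate_cache(self) -> None:
        self._nbmap = None

    def neighbours(self, cid: int) -> set:
        return set(self.neighbour_map().get(cid, set()))


# ---------------------------------------------------------------------------
# Frame construction from label images
# ---------------------------------------------------------------------------

def _trace_label_polygon(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    from skimage import measure

    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise DegenerateCellError("label has no traceable boundary")
    contour = max(contours, key=len)  # outer boundary
    rc = contour - 1.0  # undo padding
    xy = np.column_stack([(rc[:, 1] + 0.5), (rc[:, 0] + 0.5)]) * pixel_size
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


def _find_vertices(lab: np.ndarray, pixel_size: float):
    """Corners of 2x2 pixel blocks containing >= 3 distinct positive labels.

    Returns the vertex coordinates (um) and, per unordered cell pair, the list
    of vertex points whose block contains both cells.
    """
    blocks = np.stack(
        [lab[:-1, :-1], lab[:-1, 1:], lab[1:, :-1], lab[1:, 1:]], axis=0
    )
    srt = np.sort(blocks, axis=0)
    distinct = (srt[0] > 0).astype(int)
    for i in range(1, 4):
        distinct += (srt[i] > 0) & (srt[i] != srt[i - 1])
    rows, cols = np.nonzero(distinct >= 3)
    points = np.column_stack([(cols + 1.0), (rows + 1.0)]) * pixel_size
    pair_vertices: dict = {}
    for (r, c), pt in zip(zip(rows, cols), points):
        labels_here = sorted({v for v in blocks[:, r, c] if v > 0})
        for i, a in enumerate(labels_here):
            for b in labels_here[i + 1:]:
                pair_vertices.setdefault(frozenset((a, b)), []).append(pt)
    return points, pair_vertices


def build_frame(
    label_image: np.ndarray,
    pixel_size_um: float,
    index: int = 0,
    time_s: float = 0.0,
) -> Frame:
    """Build per-frame geometry from an integer label image.

    Background is 0; each positive label is one cell. Interfaces are extracted
    where two labels touch (4-connectivity); vertices where >= 3 labels meet
    at a pixel corner.
    """
    lab = np.asarray(label_image)
    if not np.issubdtype(lab.dtype, np.integer):
        raise FormatError("label image must have an integer dtype")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")

    cells = {}
    for lbl in np.unique(lab):
        if lbl == 0:
            continue
        mask = lab == lbl
        if mask.sum() < 3:
            raise DegenerateCellError(f"label {lbl} has fewer than 3 pixels")
        poly = _trace_label_polygon(mask, pixel_size_um)
        if len(poly) < 3:
            raise DegenerateCellError(f"label {lbl} has fewer than 3 boundary points")
        cells[int(lbl)] = Cell.from_polygon(int(lbl), poly)

    vertices, pair_vertices = _find_vertices(lab, pixel_size_um)

    # touching label pairs and their per-side boundary pixels
    side_pixels: dict = {}

    def _record(l1, l2, rc1, rc2):
        mask = (l1 > 0) & (l2 > 0) & (l1 != l2)
        for a, b, p1, p2 in zip(l1[mask], l2[mask], rc1[mask], rc2[mask]):
            pair = frozenset((int(a), int(b)))
            d = side_pixels.setdefault(pair, {int(a): [], int(b): []})
            d[int(a)].append(tuple(p1))
            d[int(b)].append(tuple(p2))

    rr, cc = np.indices(lab.shape)
    _record(
        lab[:, :-1], lab[:, 1:],
        np.stack([rr[:, :-1], cc[:, :-1]], -1), np.stack([rr[:, 1:], cc[:, 1:]], -1),
    )
    _record(
        lab[:-1, :], lab[1:, :],
        np.stack([rr[:-1, :], cc[:-1, :]], -1), np.stack([rr[1:, :], cc[1:, :]], -1),
    )

    interfaces = {}
    for pair, sides in side_pixels.items():
        a, b = sorted(pair)
        pix_a = np.array(sides[a])
        pix_b = np.array(sides[b])
        verts = pair_vertices.get(pair, [])
        if len(verts) >= 2:
            vpts = np.array(verts)
            # the two mutually farthest vertex points bound the interface
            d2 = ((vpts[:, None] - vpts[None]) ** 2).sum(-1)
            i, j = np.unravel_index(np.argmax(d2), d2.shape)
            p0, p1 = vpts[i], vpts[j]
        else:
            # border interface: use shared-boundary pixel midpoints, extended
            # half a pixel at each end
            mids = (
                np.column_stack([pix_a[:, 1], pix_a[:, 0]])
                + np.column_stack([pix_b[:, 1], pix_b[:, 0]])
            ) / 2.0 + 0.5
            mids *= pixel_size_um
            if len(verts) == 1:
                anchor = verts[0]
                far = mids[np.argmax(((mids - anchor) ** 2).sum(-1))]
                direction = far - anchor
                n = np.hypot(*direction)
                p0 = anchor
                p1 = far + (direction / n) * (pixel_size_um / 2) if n else far
            else:
                centre = mids.mean(axis=0)
                centred = mids - centre
                # principal direction of the midpoint cloud
                _, _, vt = np.linalg.svd(centred, full_matrices=False)
                axis = vt[0]
                proj = centred @ axis
                p0 = centre + axis * (proj.min() - pixel_size_um / 2)
                p1 = centre + axis * (proj.max() + pixel_size_um / 2)
        interfaces[pair] = Interface.from_endpoints(
            pair, p0, p1, pixel_lines={a: pix_a, b: pix_b}
        )

    return Frame(index, time_s, cells, interfaces, vertices, pixel_size_um, lab)


def link_frames(frame_t: Frame, frame_t1: Frame) -> dict:
    """Match each cell of ``frame_t1`` to the ``frame_t`` cell of maximal
    label overlap (ties broken by smaller centroid displacement).

    Returns ``{cell id in frame_t1: cell id in frame_t or None}``; ``None``
    marks a new track. Requires both frames to be image-backed.
    """
    if frame_t.labels is None or frame_t1.labels is None:
        raise ValueError("link_frames requires image-backed frames")
    l0 = frame_t.labels.ravel()
    l1 = frame_t1.labels.ravel()
    ok = (l0 > 0) & (l1 > 0)
    if not ok.any():
        return {cid: None for cid in frame_t1.cells}
    pairs, counts = np.unique(
        np.stack([l1[ok], l0[ok]]), axis=1, return_counts=True
    )
    best: dict = {}
    for (new, old), n in zip(pairs.T, counts):
        new, old = int(new), int(old)
        cur = best.get(new)
        if cur is None or n > cur[1]:
            best[new] = (old, n)
        elif n == cur[1]:
            d_new = np.linalg.norm(
                frame_t1.cells[new].centroid - frame_t.cells[old].centroid
            )
            d_cur = np.linalg.norm(
                frame_t1.cells[new].centroid - frame_t.cells[cur[0]].centroid
            )
            if d_new < d_cur:
                best[new] = (old, n)
    # enforce one new cell per old id (keep the larger overlap)
    claimed: dict = {}
    for new, (old, n) in sorted(best.items(), key=lambda kv: -kv[1][1]):
        if old not in claimed:
            claimed[old] = new
    mapping = {}
    for cid in frame_t1.cells:
        old = best.get(cid, (None, 0))[0]
        mapping[cid] = old if old is not None and claimed.get(old) == cid else None
    return mapping


def relabel_sequence(frames: list) -> list:
    """Propagate stable track ids through a sequence of image-backed frames."""
    if not frames:
        return frames
    out = [frames[0]]
    next_id = max(frames[0].cells, default=0) + 1
    for cur in frames[1:]:
        mapping = link_frames(out[-1], cur)
        new_cells, new_ifaces = {}, {}
        rename = {}
        for cid, old in mapping.items():
            nonlocal_id = old
            if nonlocal_id is None:
                nonlocal_id = next_id
                next_id += 1
            rename[cid] = nonlocal_id
        for cid, cell in cur.cells.items():
            nid = rename[cid]
            new_cells[nid] = dataclasses.replace(cell, id=nid)
        for pair, iface in cur.interfaces.items():
            a, b = pair
            npair = frozenset((rename[a], rename[b]))
            pl = iface.pixel_lines
            if pl is not None:
                pl = {rename[k]: v for k, v in pl.items()}
            new_ifaces[npair] = dataclasses.replace(
                iface, cell_pair=npair, pixel_lines=pl
            )
        relab = None
        if cur.labels is not None:
            lut = np.zeros(int(cur.labels.max()) + 1, dtype=cur.labels.dtype)
            for cid, nid in rename.items():
                lut[cid] = nid
            relab = lut[cur.labels]
        out.append(
            Frame(cur.index, cur.time_s, new_cells, new_ifaces, cur.vertices,
                  cur.pixel_size_um, relab)
        )
    return out


# ---------------------------------------------------------------------------
# TrackSet
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    frames: list
    frame_interval_s: float = 30.0
    quality_log: dict = field(default_factory=dict)

    @property
    def times_min(self) -> np.ndarray:
        return np.array([f.time_s / 60.0 for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def cell_ids(self) -> set:
        ids: set = set()
        for f in self.frames:
            ids |= set(f.cells)
        return ids

    def cell(self, cid: int, idx: int) -> Cell | None:
        return self.frames[idx].cells.get(cid)

    def presence(self, cid: int) -> list:
        return [i for i, f in enumerate(self.frames) if cid in f.cells]

    def frame_at_time(self, time_min: float) -> int:
        return int(np.argmin(np.abs(self.times_min - time_min)))

    def set_type(self, cid: int, label: str) -> None:
        for f in self.frames:
            if cid in f.cells:
                f.cells[cid].type_label = label

    def drop_cells(self, cids) -> None:
        cids = set(cids)
        for f in self.frames:
            for cid in cids & set(f.cells):
                del f.cells[cid]
            for pair in [p for p in f.interfaces if p & cids]:
                del f.interfaces[pair]
            f.invalidate_cache()


@dataclass
class Axes:
    """Embryonic axes: a straight midline fit and the AP/DV unit vectors.

    ``midline`` may be given as a polyline (n, 2); the AP direction is its
    principal direction and the midline the best-fit line through it.
    """

    midline_point: np.ndarray = field(default_factory=lambda: np.zeros(2))
    ap_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self):
        self.midline_point = np.asarray(self.midline_point, dtype=float)
        d = np.asarray(self.ap_direction, dtype=float)
        self.ap_direction = d / np.linalg.norm(d)

    @classmethod
    def from_polyline(cls, polyline) -> "Axes":
        pts = np.asarray(polyline, dtype=float)
        centre = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
        d = vt[0]
        if d[0] < 0:
            d = -d
        return cls(centre, d)

    @property
    def dv_direction(self) -> np.ndarray:
        ax, ay = self.ap_direction
        return np.array([-ay, ax])

    def dv_position(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.midline_point) @ self.dv_direction

    def ap_position(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.midline_point) @ self.ap_direction


def _median_diameter(frame: Frame) -> float:
    areas = np.array([c.area_um2 for c in frame.cells.values()])
    return float(np.median(2.0 * np.sqrt(areas / np.pi)))


def _row_index(frame: Frame, axes: Axes) -> dict:
    """Cell row numbers from the midline, in bands one median diameter wide."""
    d = _median_diameter(frame)
    out = {}
    for cid, cell in frame.cells.items():
        dv = abs(float(axes.dv_position(cell.centroid)[0]))
        out[cid] = int(dv // d)
    return out


def classify_cells(
    trackset: TrackSet,
    axes: Axes,
    mesoderm_half_width_cells: int,
    overrides: dict | None = None,
) -> TrackSet:
    """Assign cell types from midline proximity.

    Cells within ``mesoderm_half_width_cells`` rows of the midline are
    mesoderm; the next row is mesectoderm; the remainder ectoderm. A track's
    label is the majority vote over its frames; ``overrides`` (cell id ->
    type) are applied last.
    """
    if axes is None:
        raise ValueError("midline/axes must be configured before typing cells")
    votes: dict = {}
    for frame in trackset.frames:
        if not frame.cells:
            continue
        rows = _row_index(frame, axes)
        for cid, row in rows.items():
            if row < mesoderm_half_width_cells:
                lab = "mesoderm"
            elif row == mesoderm_half_width_cells:
                lab = "mesectoderm"
            else:
                lab = "ectoderm"
            votes.setdefault(cid, []).append(lab)
    for cid, vv in votes.items():
        lab = max(set(vv), key=vv.count)
        trackset.set_type(cid, lab)
    for cid, lab in (overrides or {}).items():
        if lab not in CELL_TYPES:
            raise ValueError(f"unknown cell type {lab!r}")
        trackset.set_type(cid, lab)
    return trackset


@dataclass
class QualityThresholds:
    """Track-quality criteria; tracks violating any are removed.

    ``max_relative_velocity_um_min`` bounds a cell's speed relative to the
    mean of its neighbours; areas in um^2; area change as |d ln A/dt| in
    proportion/min.
    """

    min_frames: int = 4
    min_area_um2: float = 10.0
    max_area_um2: float = 600.0
    max_area_change_pp_min: float = 0.5
    max_relative_velocity_um_min: float = 10.0


def quality_filter(trackset: TrackSet, thresholds: QualityThresholds | None = None):
    """Remove inaccurately tracked cells; returns (trackset, removal counts)."""
    thr = thresholds or QualityThresholds()
    dt_min = trackset.frame_interval_s / 60.0
    counts = {"n_frames": 0, "area": 0, "area_change": 0, "relative_velocity": 0}
    bad: set = set()

    for cid in sorted(trackset.cell_ids()):
        pres = trackset.presence(cid)
        if len(pres) < thr.min_frames:
            counts["n_frames"] += 1
            bad.add(cid)
            continue
        areas = np.array([trackset.cell(cid, i).area_um2 for i in pres])
        if areas.min() < thr.min_area_um2 or areas.max() > thr.max_area_um2:
            counts["area"] += 1
            bad.add(cid)
            continue
        rate = np.abs(np.diff(np.log(areas))) / dt_min
        if rate.size and rate.max() > thr.max_area_change_pp_min:
            counts["area_change"] += 1
            bad.add(cid)
            continue

    # relative velocity needs neighbour velocities, computed frame to frame
    vel: dict = {}
    for k in range(len(trackset.frames) - 1):
        f0, f1 = trackset.frames[k], trackset.frames[k + 1]
        for cid in set(f0.cells) & set(f1.cells):
            vel[(cid, k)] = (f1.cells[cid].centroid - f0.cells[cid].centroid) / dt_min
    for cid in sorted(trackset.cell_ids() - bad):
        worst = 0.0
        for k in range(len(trackset.frames) - 1):
            if (cid, k) not in vel:
                continue
            nb = [vel[(n, k)] for n in trackset.frames[k].neighbours(cid)
                  if (n, k) in vel]
            if len(nb) < 2:
                continue
            # median over neighbours: robust to a mistracked neighbour
            rel = np.linalg.norm(vel[(cid, k)] - np.median(nb, axis=0))
            worst = max(worst, rel)
        if worst > thr.max_relative_velocity_um_min:
            counts["relative_velocity"] += 1
            bad.add(cid)

    trackset.drop_cells(bad)
    trackset.quality_log = dict(counts)
    return trackset, counts


def distance_from_mesectoderm(
    trackset: TrackSet,
    axes: Axes,
    reference_time_min: float = 30.0,
) -> pd.Series:
    """Per-cell distance (um) from the first row of ectodermal centroids at
    the reference time, propagated along tracks.

    Non-ectodermal cells and tracks absent at the reference time get NaN.
    """
    ref = trackset.frame_at_time(reference_time_min)
    frame = trackset.frames[ref]
    ect = {cid: c for cid, c in frame.cells.items() if c.type_label == "ectoderm"}
    if not ect:
        raise ValueError("no ectodermal cells at the reference time")
    d = _median_diameter(frame)
    dv = {cid: abs(float(axes.dv_position(c.centroid)[0])) for cid, c in ect.items()}
    dv_min = min(dv.values())
    first_row = [v for v in dv.values() if v < dv_min + d]
    d0 = float(np.mean(first_row))
    out = {}
    for cid in trackset.cell_ids():
        if cid in ect:
            out[cid] = dv[cid] - d0
        else:
            out[cid] = np.nan
    return pd.Series(out, name="distance_from_mesectoderm_um")


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

def _poly_to_str(poly: np.ndarray) -> str:
    return ";".join(f"{x:.6g} {y:.6g}" for x, y in poly)


def _poly_from_str(s: str) -> np.ndarray:
    return np.array([[float(v) for v in pt.split()] for pt in s.split(";")])


def trackset_to_tables(ts: TrackSet):
    """Serialise to (cells, interfaces) DataFrames with one row per
    cell-frame / interface-frame."""
    crows, irows = [], []
    for f in ts.frames:
        for cid, c in sorted(f.cells.items()):
            crows.append(
                dict(frame=f.index, time_s=f.time_s, cell_id=cid,
                     type=c.type_label, centroid_x_um=c.centroid[0],
                     centroid_y_um=c.centroid[1], area_um2=c.area_um2,
                     polygon=_poly_to_str(c.polygon))
            )
        for pair, it in sorted(f.interfaces.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            (x0, y0), (x1, y1) = it.endpoints
            irows.append(
                dict(frame=f.index, time_s=f.time_s, cell_a=a, cell_b=b,
                     length_um=it.length_um, orientation_deg=it.orientation_deg,
                     x0=x0, y0=y0, x1=x1, y1=y1)
            )
    return pd.DataFrame(crows), pd.DataFrame(irows)


def trackset_from_tables(cells: pd.DataFrame, interfaces: pd.DataFrame,
                         frame_interval_s: float = 30.0,
                         pixel_size_um: float | None = None) -> TrackSet:
    frames = []
    iface_groups = dict(tuple(interfaces.groupby("frame"))) if len(interfaces) else {}
    for fidx, grp in cells.groupby("frame"):
        cdict = {}
        for row in grp.itertuples():
            cdict[int(row.cell_id)] = Cell.from_polygon(
                int(row.cell_id), _poly_from_str(row.polygon), row.type
            )
        idict = {}
        pts = []
        for row in iface_groups.get(fidx, pd.DataFrame()).itertuples():
            pair = frozenset((int(row.cell_a), int(row.cell_b)))
            idict[pair] = Interface.from_endpoints(
                pair, (row.x0, row.y0), (row.x1, row.y1)
            )
            pts += [(row.x0, row.y0), (row.x1, row.y1)]
        verts = np.unique(np.round(np.array(pts), 9), axis=0) if pts else np.empty((0, 2))
        frames.append(
            Frame(int(fidx), float(grp.time_s.iloc[0]), cdict, idict, verts,
                  pixel_size_um)
        )
    frames.sort(key=lambda f: f.index)
    return TrackSet(frames, frame_interval_s)


def save_trackset(ts: TrackSet, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells, ifaces = trackset_to_tables(ts)
    cells.to_csv(out / "cells.csv", index=False)
    ifaces.to_csv(out / "interfaces.csv", index=False)


def load_trackset(in_dir, frame_interval_s: float = 30.0) -> TrackSet:
    p = Path(in_dir)
    cells = pd.read_csv(p / "cells.csv")
    ifaces = pd.read_csv(p / "interfaces.csv")
    return trackset_from_tables(cells, ifaces, frame_interval_s)
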