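"""Synthetic embryo movies with known ground truth.

The generator emulates the study conditions of a ventrally mounted germband:
a polygonal tessellation of ~12-um cells over a ~180 x 150 um field, smooth
prescribed flows (a DV-stretch pull decaying away from the ventral midline,
emulating mesoderm invagination, and an AP-stretch pull increasing toward
the posterior, emulating endoderm-driven extension), scripted T1 swaps on
DV-oriented junctions, and rendered label / membrane / Myosin channels with
prescribed per-cell bipolar junctional intensity. Every output carries the
ground truth needed to close the loop: true strain tensors, true swap times
and quartets, true bipolarity parameters, and the true track table.

Movies run from -15 to +30 minutes around germband-extension onset at a
30-s frame interval, matching the analysis window of the imaging study this
package is built for.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from .geometry import directed_angle_from_ap, polygon_area
from .mesh import Cell, Frame, Interface, TrackSet


# ---------------------------------------------------------------------------
# Vertex-indexed mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Polygonal tessellation: shared vertices plus per-cell CCW vertex loops."""

    vertices: np.ndarray  # (v, 2) um
    cells: dict  # cell id -> list of vertex indices (CCW)

    def copy(self) -> "Mesh":
        return Mesh(self.vertices.copy(), {k: list(v) for k, v in self.cells.items()})

    def polygon(self, cid: int) -> np.ndarray:
        return self.vertices[self.cells[cid]]

    def centroid(self, cid: int) -> np.ndarray:
        from .geometry import polygon_centroid

        return polygon_centroid(self.polygon(cid))

    def edges(self) -> dict:
        """Unordered vertex pair -> sorted list of cell ids sharing it."""
        out: dict = {}
        for cid, loop in self.cells.items():
            for vi, vj in zip(loop, loop[1:] + loop[:1]):
                out.setdefault(frozenset((vi, vj)), []).append(cid)
        return out

    def interface_edges(self) -> dict:
        """Unordered cell pair -> (vi, vj) for edges shared by two cells."""
        out = {}
        for vpair, cids in self.edges().items():
            if len(cids) == 2:
                vi, vj = sorted(vpair)
                out[frozenset(cids)] = (vi, vj)
        return out

    def resort_ccw(self, cids) -> None:
        """Re-order the vertex loops of (near-convex) cells counter-clockwise."""
        for cid in cids:
            loop = self.cells[cid]
            pts = self.vertices[loop]
            centre = pts.mean(axis=0)
            ang = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
            self.cells[cid] = [loop[i] for i in np.argsort(ang)]

    def interior_cells(self) -> list:
        edges = self.edges()
        out = []
        for cid, loop in self.cells.items():
            shared = all(
                len(edges[frozenset((vi, vj))]) == 2
                for vi, vj in zip(loop, loop[1:] + loop[:1])
            )
            if shared:
                out.append(cid)
        return sorted(out)


def generate_tessellation(
    n_cells: int,
    mean_diameter_um: float = 12.0,
    jitter: float = 0.2,
    seed: int = 0,
) -> Mesh:
    """Centroidal-perturbed triangular-lattice Voronoi tessellation.

    ``jitter`` is the generator-point displacement s.d. as a fraction of the
    mean diameter; jitter 0 gives a regular hexagonal tessellation.
    Reproducible per seed.
    """
    if n_cells < 4:
        raise ValueError("need at least 4 cells")
    if mean_diameter_um <= 0 or jitter < 0:
        raise ValueError("infeasible geometry parameters")
    rng = np.random.default_rng(seed)
    d = mean_diameter_um
    ny = max(2, int(round(np.sqrt(n_cells * np.sqrt(3) / 2 / 1.2))))
    nx = int(np.ceil(n_cells / ny))
    guard = 3
    pts, core = [], []
    for j in range(-guard, ny + guard):
        for i in range(-guard, nx + guard):
            x = (i + 0.5 * (j % 2)) * d
            y = j * d * np.sqrt(3) / 2
            if 0 <= i < nx and 0 <= j < ny:
                core.append(len(pts))
            pts.append((x, y))
    pts = np.asarray(pts, dtype=float)
    pts = pts + rng.normal(0.0, jitter * d, size=pts.shape)
    vor = Voronoi(pts)
    cells = {}
    for new_id, k in enumerate(core, start=1):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or not region:
            continue
        cells[new_id] = list(region)
    # keep only vertices used by retained cells
    used = sorted({v for loop in cells.values() for v in loop})
    remap = {v: i for i, v in enumerate(used)}
    vertices = vor.vertices[used].copy()
    cells = {cid: [remap[v] for v in loop] for cid, loop in cells.items()}
    # shift geometry so the retained field starts at the origin
    vertices -= vertices.min(axis=0)
    mesh = Mesh(vertices, cells)
    mesh.resort_ccw(list(mesh.cells))
    return mesh


# ---------------------------------------------------------------------------
# Flow specifications
# ---------------------------------------------------------------------------

class FlowField:
    """Time-varying velocity field v(x, t) (um/min) with a known strain-rate
    tensor field (pp/min)."""

    def velocity(self, points: np.ndarray, t: float) -> np.ndarray:
        raise NotImplementedError

    def strain(self, points: np.ndarray, t: float) -> np.ndarray:
        """(n, 2, 2) symmetric velocity-gradient tensors at the points."""
        raise NotImplementedError

    def __add__(self, other: "FlowField") -> "SumFlow":
        return SumFlow([self, other])


@dataclass
class UniformFlow(FlowField):
    """Affine flow v = L (x - origin); the strain is sym(L) everywhere."""

    gradient: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def velocity(self, points, t):
        p = np.atleast_2d(points) - self.origin
        return p @ np.asarray(self.gradient, dtype=float).T

    def strain(self, points, t):
        g = np.asarray(self.gradient, dtype=float)
        s = 0.5 * (g + g.T)
        return np.broadcast_to(s, (len(np.atleast_2d(points)), 2, 2)).copy()


@dataclass
class DVPullFlow(FlowField):
    """DV stretch decaying with distance from the midline.

    E_yy(y) = rate * exp(-|y - midline| / decay); the velocity is its
    integral, directed away from the midline. Emulates the ventral-to-dorsal
    cell-stretching gradient driven by mesoderm invagination.
    """

    rate: float = 0.03  # pp/min at the midline
    decay_um: float = 50.0
    midline_y: float = 0.0

    def velocity(self, points, t):
        p = np.atleast_2d(points)
        dy = p[:, 1] - self.midline_y
        mag = self.rate * self.decay_um * (1 - np.exp(-np.abs(dy) / self.decay_um))
        v = np.zeros_like(p)
        v[:, 1] = np.sign(dy) * mag
        return v

    def strain(self, points, t):
        p = np.atleast_2d(points)
        dy = np.abs(p[:, 1] - self.midline_y)
        eyy = self.rate * np.exp(-dy / self.decay_um)
        out = np.zeros((len(p), 2, 2))
        out[:, 1, 1] = eyy
        return out


@dataclass
class APPullFlow(FlowField):
    """AP stretch increasing toward the posterior.

    E_xx ramps linearly from 0 at ``x_on`` to ``rate`` at ``x_on + ramp_um``
    and stays at ``rate`` beyond; emulates the posterior-high elongation
    gradient of germband extension.
    """

    rate: float = 0.04
    x_on: float = 0.0
    ramp_um: float = 180.0

    def velocity(self, points, t):
        p = np.atleast_2d(points)
        x = p[:, 0] - self.x_on
        r, w = self.rate, self.ramp_um
        vx = np.where(
            x <= 0, 0.0,
            np.where(x <= w, r * x**2 / (2 * w), r * (w / 2 + (x - w))),
        )
        v = np.zeros_like(p)
        v[:, 0] = vx
        return v

    def strain(self, points, t):
        p = np.atleast_2d(points)
        x = p[:, 0] - self.x_on
        exx = self.rate * np.clip(x / self.ramp_um, 0.0, 1.0)
        out = np.zeros((len(p), 2, 2))
        out[:, 0, 0] = exx
        return out


@dataclass
class TimeWindow(FlowField):
    """A flow active between t_on and t_off, with a smooth 1-min ramp."""

    flow: FlowField = None
    t_on_min: float = 0.0
    t_off_min: float = np.inf
    ramp_min: float = 1.0

    def _gate(self, t: float) -> float:
        up = np.clip((t - self.t_on_min) / self.ramp_min, 0.0, 1.0)
        down = np.clip((self.t_off_min - t) / self.ramp_min, 0.0, 1.0)
        return float(up * down)

    def velocity(self, points, t):
        return self._gate(t) * self.flow.velocity(points, t)

    def strain(self, points, t):
        return self._gate(t) * self.flow.strain(points, t)


@dataclass
class SumFlow(FlowField):
    flows: list = field(default_factory=list)

    def velocity(self, points, t):
        return sum(f.velocity(points, t) for f in self.flows)

    def strain(self, points, t):
        return sum(f.strain(points, t) for f in self.flows)


def _advect(points: np.ndarray, flow: FlowField, t0: float, dt: float,
            substeps: int = 4) -> np.ndarray:
    """RK4 integration of the velocity field over one frame interval."""
    p = points.copy()
    h = dt / substeps
    t = t0
    for _ in range(substeps):
        k1 = flow.velocity(p, t)
        k2 = flow.velocity(p + 0.5 * h * k1, t + 0.5 * h)
        k3 = flow.velocity(p + 0.5 * h * k2, t + 0.5 * h)
        k4 = flow.velocity(p + h * k3, t + h)
        p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return p


# ---------------------------------------------------------------------------
# Scripted T1 swaps
# ---------------------------------------------------------------------------

@dataclass
class SwapScript:
    """One scheduled T1: the losing cell pair, its quartet, and timings."""

    losing_pair: frozenset
    gaining_pair: frozenset
    t_swap_min: float
    shrink_duration_min: float = 4.0
    growth_rate_um_min: float = 1.0
    growth_duration_min: float = 4.0
    # runtime state
    v1: int | None = None
    v2: int | None = None
    shrink_len0: float | None = None
    done: bool = False

    @property
    def quartet(self) -> frozenset:
        return self.losing_pair | self.gaining_pair


def make_swap_schedule(
    mesh: Mesh,
    n_swaps: int,
    t_range_min: tuple = (2.0, 25.0),
    seed: int = 0,
    min_orientation_deg: float = 55.0,
) -> list:
    """Schedule T1 swaps on interior, clearly DV-oriented junctions with
    mutually disjoint quartets."""
    rng = np.random.default_rng(seed)
    edges = mesh.edges()
    iface = mesh.interface_edges()
    interior = set(mesh.interior_cells())
    candidates = []
    for pair, (vi, vj) in iface.items():
        a, b = sorted(pair)
        if a not in interior or b not in interior:
            continue
        seg = mesh.vertices[vj] - mesh.vertices[vi]
        orient = abs(directed_angle_from_ap(seg))
        orient = orient if orient <= 90 else 180 - orient
        if orient <= min_orientation_deg:
            continue
        third1 = [c for c in edges_cells(edges, vi, mesh) if c not in pair]
        third2 = [c for c in edges_cells(edges, vj, mesh) if c not in pair]
        if len(third1) != 1 or len(third2) != 1 or third1 == third2:
            continue
        gain = frozenset((third1[0], third2[0]))
        if gain & pair or third1[0] not in interior or third2[0] not in interior:
            continue
        candidates.append((pair, gain))
    rng.shuffle(candidates)
    schedule, used = [], set()
    times = np.sort(rng.uniform(*t_range_min, size=len(candidates)))
    for (pair, gain), t in zip(candidates, times):
        quartet = pair | gain
        if quartet & used:
            continue
        used |= quartet
        schedule.append(SwapScript(pair, gain, float(t)))
        if len(schedule) == n_swaps:
            break
    if len(schedule) < n_swaps:
        raise ValueError(
            f"could only place {len(schedule)} of {n_swaps} requested swaps"
        )
    return schedule


def edges_cells(edges: dict, vertex: int, mesh: Mesh) -> set:
    """Cells whose boundary loop contains the vertex."""
    out = set()
    for cid, loop in mesh.cells.items():
        if vertex in loop:
            out.add(cid)
    return out


def validate_schedule(schedule) -> None:
    seen: dict = {}
    for s in schedule:
        for cid in s.quartet:
            other = seen.get(cid)
            if other is not None and abs(other - s.t_swap_min) < 1e-9:
                raise ValueError(
                    f"conflicting simultaneous swaps share cell {cid}"
                )
            seen[cid] = s.t_swap_min


def _apply_t1(mesh: Mesh, script: SwapScript, eps_um: float = 0.4) -> dict:
    """Collapse the losing edge and open the perpendicular one in place."""
    a, b = sorted(script.losing_pair)
    iface = mesh.interface_edges()
    if script.losing_pair not in iface:
        raise RuntimeError(f"losing pair {a},{b} no longer share an edge")
    v1, v2 = iface[script.losing_pair]
    cells_v1 = {cid for cid, loop in mesh.cells.items() if v1 in loop}
    cells_v2 = {cid for cid, loop in mesh.cells.items() if v2 in loop}
    (c,) = cells_v1 - script.losing_pair
    (d,) = cells_v2 - script.losing_pair
    if frozenset((c, d)) != script.gaining_pair:
        raise RuntimeError("quartet changed since scheduling")
    m = 0.5 * (mesh.vertices[v1] + mesh.vertices[v2])
    ca = mesh.centroid(a)
    u = ca - m
    u = u / np.linalg.norm(u)
    # a keeps v1 (its side), b keeps v2; c and d acquire both
    mesh.cells[a] = [v for v in mesh.cells[a] if v != v2]
    mesh.cells[b] = [v for v in mesh.cells[b] if v != v1]
    loop_c = mesh.cells[c]
    loop_c.insert(loop_c.index(v1) + 1, v2)
    loop_d = mesh.cells[d]
    loop_d.insert(loop_d.index(v2) + 1, v1)
    mesh.vertices[v1] = m + 0.5 * eps_um * u
    mesh.vertices[v2] = m - 0.5 * eps_um * u
    mesh.resort_ccw([a, b, c, d])
    script.v1, script.v2 = v1, v2
    return dict(midpoint=m, axis=u)


# ---------------------------------------------------------------------------
# Movie simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMovie:
    """Frame meshes plus the ground truth they were built from."""

    meshes: list
    times_min: np.ndarray
    truth_strain: pd.DataFrame
    truth_events: pd.DataFrame
    genotype: str = "synthetic"
    movie_id: str = "synthetic"
    frame_interval_s: float = 30.0


def simulate_movie(
    mesh0: Mesh,
    flow: FlowField,
    times_min: np.ndarray,
    schedule: list | None = None,
    genotype: str = "synthetic",
    movie_id: str = "synthetic",
) -> SyntheticMovie:
    """Advect a tessellation through a flow, executing scripted T1 swaps.

    Vertices are advected by RK4 integration of the velocity field; each
    scheduled swap shrinks its losing junction to a 4-way vertex at the
    scripted time, swaps the topology, and grows the new perpendicular
    junction. Per-frame per-cell true strain tensors (from the flow field)
    and the realised event table are returned alongside the meshes. Aborts
    if any cell polygon inverts during deformation.
    """
    times = np.asarray(times_min, dtype=float)
    schedule = [dataclasses.replace(s) for s in (schedule or [])]
    validate_schedule(schedule)
    mesh = mesh0.copy()
    meshes = [mesh.copy()]
    event_rows = []
    swap_cells_by_time: list = []

    for k in range(len(times) - 1):
        t0, t1 = times[k], times[k + 1]
        dt = t1 - t0
        mesh.vertices = _advect(mesh.vertices, flow, t0, dt)

        for s in schedule:
            if s.done:
                # post-swap growth
                if t1 <= s.t_swap_min + s.growth_duration_min:
                    p1, p2 = mesh.vertices[s.v1], mesh.vertices[s.v2]
                    seg = p1 - p2
                    n = np.linalg.norm(seg)
                    if n > 0:
                        step = 0.5 * s.growth_rate_um_min * dt * seg / n
                        mesh.vertices[s.v1] = p1 + step
                        mesh.vertices[s.v2] = p2 - step
                continue
            if t1 >= s.t_swap_min:
                info = _apply_t1(mesh, s)
                s.done = True
                cpair = sorted(s.gaining_pair)
                vec = mesh.centroid(cpair[1]) - mesh.centroid(cpair[0])
                orient = abs(directed_angle_from_ap(vec))
                orient = orient if orient <= 90 else 180 - orient
                event_rows.append(
                    dict(
                        swap_time_min=0.5 * (t0 + t1),
                        losing_a=sorted(s.losing_pair)[0],
                        losing_b=sorted(s.losing_pair)[1],
                        gaining_a=cpair[0], gaining_b=cpair[1],
                        centroid_angle_deg=orient,
                        productivity=-np.cos(2 * np.radians(orient)),
                    )
                )
            elif t1 >= s.t_swap_min - s.shrink_duration_min:
                # enforce the scripted shrink profile on the losing junction
                iface = mesh.interface_edges()
                if s.losing_pair not in iface:
                    raise RuntimeError("scheduled junction lost before swap")
                v1, v2 = iface[s.losing_pair]
                p1, p2 = mesh.vertices[v1], mesh.vertices[v2]
                cur_len = np.linalg.norm(p2 - p1)
                if s.shrink_len0 is None:
                    s.shrink_len0 = cur_len
                frac = max((s.t_swap_min - t1) / s.shrink_duration_min, 0.0)
                target = max(s.shrink_len0 * frac, 0.05)
                if cur_len > 0:
                    mid = 0.5 * (p1 + p2)
                    half = 0.5 * target * (p2 - p1) / cur_len
                    mesh.vertices[v1] = mid - half
                    mesh.vertices[v2] = mid + half

        for cid in mesh.cells:
            if polygon_area(mesh.polygon(cid)) <= 0:
                raise RuntimeError(
                    f"cell {cid} inverted at t={t1:.2f} min during deformation"
                )
        meshes.append(mesh.copy())
        swap_cells_by_time.append(t1)

    # ground-truth strain from the flow, flagged inside swap animations
    def in_swap(cid, t):
        for s in schedule:
            if cid in s.quartet and (
                s.t_swap_min - s.shrink_duration_min - 1e-9
                <= t
                <= s.t_swap_min + s.growth_duration_min + 1e-9
            ):
                return True
        return False

    strain_rows = []
    for mm, t in zip(meshes, times):
        cents = np.array([mm.centroid(cid) for cid in sorted(mm.cells)])
        strains = flow.strain(cents, t)
        for cid, s in zip(sorted(mm.cells), strains):
            strain_rows.append(
                dict(time_min=t, cell_id=cid, exx=s[0, 0], exy=s[0, 1],
                     eyy=s[1, 1], in_swap=in_swap(cid, t))
            )
    return SyntheticMovie(
        meshes, times, pd.DataFrame(strain_rows), pd.DataFrame(event_rows),
        genotype=genotype, movie_id=movie_id,
        frame_interval_s=float(np.median(np.diff(times)) * 60.0) if len(times) > 1 else 30.0,
    )


def apply_flow(mesh: Mesh, flow: FlowField, times_min) -> SyntheticMovie:
    """Advect a tessellation through a flow with no topology changes."""
    return simulate_movie(mesh, flow, times_min, schedule=None)


def script_swaps(mesh: Mesh, schedule: list, times_min,
                 flow: FlowField | None = None) -> SyntheticMovie:
    """Execute a swap schedule (optionally on top of a background flow)."""
    return simulate_movie(mesh, flow or UniformFlow(), times_min, schedule)


# ---------------------------------------------------------------------------
# Conversion to analysis frames
# ---------------------------------------------------------------------------

def mesh_to_frame(mesh: Mesh, index: int = 0, time_s: float = 0.0,
                  pixel_size_um: float | None = None) -> Frame:
    """Build an analysis Frame from a mesh; cells keep their vertex ids so
    downstream shape mapping can use boundary correspondence."""
    cells = {}
    for cid, loop in mesh.cells.items():
        cell = Cell.from_polygon(cid, mesh.vertices[loop])
        # preserve correspondence (ensure_ccw may have reversed the loop)
        ids = list(loop)
        if not np.allclose(cell.polygon[0], mesh.vertices[loop[0]]):
            ids = ids[::-1]
        cell.vertex_ids = ids
        cells[cid] = cell
    interfaces = {}
    vcount: dict = {}
    for cid, loop in mesh.cells.items():
        for v in loop:
            vcount[v] = vcount.get(v, 0) + 1
    for pair, (vi, vj) in mesh.interface_edges().items():
        interfaces[pair] = Interface.from_endpoints(
            pair, mesh.vertices[vi], mesh.vertices[vj]
        )
    verts = np.array([mesh.vertices[v] for v, n in sorted(vcount.items())
                      if n >= 3])
    if verts.size == 0:
        verts = np.empty((0, 2))
    return Frame(index, time_s, cells, interfaces, verts, pixel_size_um)


def movie_to_trackset(movie: SyntheticMovie,
                      pixel_size_um: float | None = None) -> TrackSet:
    frames = [
        mesh_to_frame(m, i, t * 60.0, pixel_size_um)
        for i, (m, t) in enumerate(zip(movie.meshes, movie.times_min))
    ]
    return TrackSet(frames, movie.frame_interval_s)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class IntensityModel:
    """Two-channel rendering model with prescribed junctional bipolarity.

    Per-cell amplitude and phase are smooth spatial fields plus small
    per-cell jitter, emulating the spatially patterned planar polarity of
    the germband; a shared junction is painted with the mean of its two
    cells' contributions. Intensities are on a 0..(2^bit_depth - 1) scale.
    """

    base_density: float = 100.0
    amplitude_mean: float = 40.0
    amplitude_spatial: float = 20.0
    amplitude_jitter: float = 2.0
    phase_mean_deg: float = 90.0
    phase_spatial_deg: float = 15.0
    phase_jitter_deg: float = 3.0
    noise_sd: float = 8.0
    membrane_intensity: float = 180.0
    bit_depth: int = 8

    def cell_parameters(self, mesh: Mesh, rng: np.random.Generator) -> pd.DataFrame:
        cents = {cid: mesh.centroid(cid) for cid in sorted(mesh.cells)}
        xy = np.array(list(cents.values()))
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        rows = []
        for cid, c in cents.items():
            xh, yh = (c - lo) / span
            amp = (
                self.amplitude_mean
                + self.amplitude_spatial
                * (0.6 * np.sin(2 * np.pi * xh) + 0.4 * np.cos(2 * np.pi * yh))
                + rng.normal(0.0, self.amplitude_jitter)
            )
            phase = (
                self.phase_mean_deg
                + self.phase_spatial_deg * np.sin(2 * np.pi * yh + 0.7)
                + rng.normal(0.0, self.phase_jitter_deg)
            )
            rows.append(dict(cell_id=cid, amplitude=max(amp, 0.0),
                             phase_deg=phase % 180.0))
        return pd.DataFrame(rows)


def render_frame(
    mesh: Mesh,
    model: IntensityModel,
    pixel_size_um: float = 0.25,
    seed: int = 0,
    cell_params: pd.DataFrame | None = None,
    shape: tuple | None = None,
):
    """Rasterise one mesh into label, membrane, and Myosin channels.

    Returns a dict with ``labels`` (int32), ``membrane`` and ``myosin``
    (quantised to the model bit depth), and ``truth`` (per-cell amplitude
    and phase). Deterministic per seed.
    """
    from skimage.draw import polygon as draw_polygon

    from .myosin import junction_line_pixels

    rng = np.random.default_rng(seed)
    if cell_params is None:
        cell_params = model.cell_parameters(mesh, rng)
    params = cell_params.set_index("cell_id")

    if shape is None:
        margin = 2.0  # um
        vmax = mesh.vertices.max(axis=0) + margin
        shape = (int(np.ceil(vmax[1] / pixel_size_um)) + 1,
                 int(np.ceil(vmax[0] / pixel_size_um)) + 1)

    def rc(points_um):
        p = np.atleast_2d(points_um)
        return np.column_stack([p[:, 1] / pixel_size_um - 0.5,
                                p[:, 0] / pixel_size_um - 0.5])

    labels = np.zeros(shape, dtype=np.int32)
    for cid in sorted(mesh.cells):
        poly = rc(mesh.polygon(cid))
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
        labels[rr, cc] = cid

    membrane = np.zeros(shape, dtype=float)
    myosin = np.zeros(shape, dtype=float)
    for pair, (vi, vj) in mesh.interface_edges().items():
        p0, p1 = mesh.vertices[vi], mesh.vertices[vj]
        prc = rc(np.array([p0, p1]))
        pix = junction_line_pixels(prc[0], prc[1], shape)
        rr, cc = pix[:, 0], pix[:, 1]
        membrane[rr, cc] = model.membrane_intensity
        theta = directed_angle_from_ap(p1 - p0)
        contrib = []
        for cid in pair:
            if cid in params.index:
                row = params.loc[cid]
                contrib.append(
                    row.amplitude
                    * np.cos(2 * np.radians(theta - row.phase_deg))
                )
        density = model.base_density + (np.mean(contrib) if contrib else 0.0)
        myosin[rr, cc] = density

    top = 2**model.bit_depth - 1
    dtype = np.uint8 if model.bit_depth <= 8 else np.uint16
    if model.noise_sd > 0:
        myosin = myosin + rng.normal(0.0, model.noise_sd, size=shape)
        membrane = membrane + rng.normal(0.0, model.noise_sd, size=shape)
    myosin = np.clip(np.round(myosin), 0, top).astype(dtype)
    membrane = np.clip(np.round(membrane), 0, top).astype(dtype)
    return dict(labels=labels, membrane=membrane, myosin=myosin,
                truth=cell_params, pixel_size_um=pixel_size_um)


def render_movie(movie: SyntheticMovie, model: IntensityModel,
                 pixel_size_um: float = 0.25, seed: int = 0) -> list:
    """Render every frame of a movie; per-cell bipolarity parameters are
    drawn once and held through time."""
    rng = np.random.default_rng(seed)
    params = model.cell_parameters(movie.meshes[0], rng)
    margin = 2.0
    vmax = np.max([m.vertices.max(axis=0) for m in movie.meshes], axis=0) + margin
    shape = (int(np.ceil(vmax[1] / pixel_size_um)) + 1,
             int(np.ceil(vmax[0] / pixel_size_um)) + 1)
    out = []
    for k, mesh in enumerate(movie.meshes):
        present = params[params.cell_id.isin(mesh.cells)]
        out.append(
            render_frame(mesh, model, pixel_size_um,
                         seed=int(rng.integers(2**31 - 1)),
                         cell_params=present, shape=shape)
        )
    return out


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

#: Field and timing defaults matching the imaging study: ~180 x 150 um field
#: of ~12-um cells, 30-s frames spanning -15 to +30 min of germband
#: extension, midline at the ventral (y = 0) edge.
PRESET_N_CELLS = 180
PRESET_T_START = -15.0
PRESET_T_END = 30.0
PRESET_DT_MIN = 0.5

#: Mesoderm invagination pulls DV from about -13 to +7 min; the AP extension
#: engine runs from onset (0) to +20 min.
DV_PULL_WINDOW = (-13.0, 7.0)
AP_PULL_WINDOW = (0.0, 20.0)


def preset_flow(genotype: str, embryo_rate_factor: float = 1.0,
                onset_shift_min: float = 0.0, field_width_um: float = 180.0
                ) -> FlowField:
    """Wild-type-like = DV pull (invagination window) + AP pull; twist-like =
    AP pull only."""
    ap = TimeWindow(
        APPullFlow(rate=0.04 * embryo_rate_factor, x_on=0.0,
                   ramp_um=field_width_um),
        AP_PULL_WINDOW[0] + onset_shift_min, AP_PULL_WINDOW[1] + onset_shift_min,
    )
    if genotype == "wildtype":
        dv = TimeWindow(
            DVPullFlow(rate=0.03 * embryo_rate_factor, decay_um=50.0,
                       midline_y=0.0),
            DV_PULL_WINDOW[0] + onset_shift_min, DV_PULL_WINDOW[1] + onset_shift_min,
        )
        return SumFlow([ap, dv])
    if genotype == "twist":
        return SumFlow([ap])
    raise ValueError(f"unknown preset genotype {genotype!r}")


def preset_movie(
    genotype: str,
    seed: int,
    n_cells: int = PRESET_N_CELLS,
    n_swaps: int = 20,
    movie_id: str | None = None,
    t_start: float = PRESET_T_START,
    t_end: float = PRESET_T_END,
    dt_min: float = PRESET_DT_MIN,
) -> SyntheticMovie:
    """One synthetic embryo of the given genotype with embryo-to-embryo
    variability in rates (~5%) and onset (~1 min s.d.)."""
    rng = np.random.default_rng(seed)
    mesh = generate_tessellation(n_cells, seed=int(rng.integers(2**31 - 1)))
    rate_factor = float(rng.normal(1.0, 0.05))
    onset = float(rng.normal(0.0, 1.0))
    flow = preset_flow(genotype, rate_factor, onset,
                       field_width_um=mesh.vertices[:, 0].max())
    times = np.arange(t_start, t_end + dt_min / 2, dt_min)
    schedule = (
        make_swap_schedule(mesh, n_swaps,
                           t_range_min=(2.0 + onset, 25.0 + onset),
                           seed=int(rng.integers(2**31 - 1)))
        if n_swaps else None
    )
    movie = simulate_movie(mesh, flow, times, schedule, genotype=genotype,
                           movie_id=movie_id or f"{genotype}_{seed}")
    return movie
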