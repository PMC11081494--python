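"""Frame construction from label images, linking, typing, and quality
filters."""

import numpy as np
import pandas as pd
import pytest

from epimorph import mesh as em
from epimorph import synth


def two_squares_label(side=10):
    lab = np.zeros((side, 2 * side), dtype=np.int32)
    lab[:, :side] = 1
    lab[:, side:] = 2
    return lab


def hex_lattice_labels(nx=5, ny=5, d=12.0, px=0.5, jitter=0.0, seed=0):
    """Rasterised hexagonal tessellation via the synthetic generator."""
    m = synth.generate_tessellation(nx * ny, mean_diameter_um=d, jitter=jitter,
                                    seed=seed)
    render = synth.render_frame(m, synth.IntensityModel(noise_sd=0.0),
                                pixel_size_um=px, seed=0)
    return m, render["labels"], px


class TestBuildFrame:
    def test_two_squares_single_interface_length(self):
        frame = em.build_frame(two_squares_label(10), pixel_size_um=0.5)
        assert set(frame.cells) == {1, 2}
        assert len(frame.interfaces) == 1
        iface = frame.interface(1, 2)
        assert iface.length_um == pytest.approx(5.0)
        # vertical boundary => DV-oriented
        assert iface.orientation_deg == pytest.approx(90.0)

    def test_non_integer_image_rejected(self):
        with pytest.raises(em.FormatError):
            em.build_frame(np.ones((5, 5), dtype=float), 0.5)

    def test_tiny_label_rejected(self):
        lab = two_squares_label(10)
        lab[0, 0] = 7  # single-pixel label
        with pytest.raises(em.DegenerateCellError):
            em.build_frame(lab, 0.5)

    def test_hex_lattice_interior_topology(self):
        m, lab, px = hex_lattice_labels(jitter=0.0)
        frame = em.build_frame(lab, px)
        g = frame.neighbour_graph()
        # interior cells of a honeycomb have exactly 6 interfaces
        interior = m.interior_cells()
        degrees = [g.degree(c) for c in interior if c in g]
        assert degrees and all(d == 6 for d in degrees)

    def test_interface_count_matches_pixel_adjacency_oracle(self):
        m, lab, px = hex_lattice_labels(nx=8, ny=7, jitter=0.25, seed=4)
        frame = em.build_frame(lab, px)
        # brute-force oracle: scan all 4-neighbour pixel pairs
        oracle = set()
        h, w = lab.shape
        for r in range(h):
            for c in range(w):
                for dr, dc in ((0, 1), (1, 0)):
                    if r + dr < h and c + dc < w:
                        a, b = lab[r, c], lab[r + dr, c + dc]
                        if a > 0 and b > 0 and a != b:
                            oracle.add(frozenset((int(a), int(b))))
        assert set(frame.interfaces) == oracle

    def test_interface_symmetric_in_pair(self):
        frame = em.build_frame(two_squares_label(), 0.5)
        assert frame.interface(1, 2) is frame.interface(2, 1)

    def test_areas_tile_the_labelled_region(self):
        m, lab, px = hex_lattice_labels(jitter=0.2, seed=9)
        frame = em.build_frame(lab, px)
        total = sum(c.area_um2 for c in frame.cells.values())
        labelled = (lab > 0).sum() * px**2
        # polygon areas trace pixel boundaries: agree within a one-pixel band
        n_boundary = sum(len(i.pixel_lines[a]) for i in frame.interfaces.values()
                         for a in i.pixel_lines)
        assert abs(total - labelled) <= n_boundary * px**2


class TestLinkFrames:
    def test_identity_on_same_frame(self):
        frame = em.build_frame(two_squares_label(), 0.5)
        assert em.link_frames(frame, frame) == {1: 1, 2: 2}

    def test_translation_by_one_pixel_keeps_ids(self):
        lab = two_squares_label(10)
        f0 = em.build_frame(lab, 0.5)
        f1 = em.build_frame(np.roll(lab, 1, axis=0), 0.5, index=1)
        assert em.link_frames(f0, f1) == {1: 1, 2: 2}

    def test_scripted_disappearance_ends_track(self):
        lab0 = np.zeros((12, 32), dtype=np.int32)
        lab0[2:10, 1:10] = 1
        lab0[2:10, 10:18] = 2
        lab0[2:10, 18:30] = 3
        lab1 = lab0.copy()
        lab1[lab1 == 2] = 3  # cell 2 disappears, 3 expands over it
        f0 = em.build_frame(lab0, 0.5)
        f1 = em.build_frame(lab1, 0.5, index=1)
        mapping = em.link_frames(f0, f1)
        assert mapping[1] == 1
        assert mapping[3] == 3
        assert 2 not in mapping  # track 2 ended


def make_synthetic_trackset(n_frames=12, n_cells=120, seed=0):
    m = synth.generate_tessellation(n_cells, seed=seed)
    times = np.arange(n_frames) * 0.5
    movie = synth.simulate_movie(m, synth.UniformFlow(), times)
    return synth.movie_to_trackset(movie), m


class TestClassifyCells:
    def test_midline_cell_is_mesoderm(self):
        ts, _ = make_synthetic_trackset()
        axes = em.Axes(midline_point=(0.0, 0.0))
        em.classify_cells(ts, axes, mesoderm_half_width_cells=2)
        frame = ts.frames[0]
        on_midline = min(frame.cells.values(),
                         key=lambda c: abs(c.centroid[1]))
        assert on_midline.type_label == "mesoderm"

    def test_wildtype_width_cell_12_rows_out_is_ectoderm(self):
        # wild-type-like mesoderm ~18 cells wide => half-width 9 rows
        ts, _ = make_synthetic_trackset(n_cells=350, seed=3)
        axes = em.Axes(midline_point=(0.0, 0.0))
        em.classify_cells(ts, axes, mesoderm_half_width_cells=9)
        frame = ts.frames[0]
        d = np.median([2 * np.sqrt(c.area_um2 / np.pi)
                       for c in frame.cells.values()])
        far = [c for c in frame.cells.values()
               if 12 <= abs(c.centroid[1]) / d < 13]
        assert far and all(c.type_label == "ectoderm" for c in far)

    def test_twist_width_typing(self):
        # twist-like mesoderm ~8-10 cells wide => half-width ~5 rows
        ts, _ = make_synthetic_trackset(n_cells=220, seed=3)
        axes = em.Axes(midline_point=(0.0, 0.0))
        em.classify_cells(ts, axes, mesoderm_half_width_cells=5)
        frame = ts.frames[0]
        d = np.median([2 * np.sqrt(c.area_um2 / np.pi)
                       for c in frame.cells.values()])
        rows4 = [c for c in frame.cells.values()
                 if 4 <= abs(c.centroid[1]) / d < 5]
        assert rows4 and all(c.type_label == "mesoderm" for c in rows4)

    def test_missing_axes_is_an_error(self):
        ts, _ = make_synthetic_trackset()
        with pytest.raises(ValueError):
            em.classify_cells(ts, None, 5)

    def test_override_applied_last(self):
        ts, _ = make_synthetic_trackset()
        axes = em.Axes()
        cid = next(iter(ts.frames[0].cells))
        em.classify_cells(ts, axes, 2, overrides={cid: "excluded"})
        assert ts.frames[0].cells[cid].type_label == "excluded"


class TestQualityFilter:
    def test_clean_trackset_zero_removals(self):
        ts, _ = make_synthetic_trackset()
        n0 = len(ts.cell_ids())
        _, counts = em.quality_filter(ts)
        assert sum(counts.values()) == 0
        assert len(ts.cell_ids()) == n0

    def test_velocity_spike_removes_exactly_that_cell(self):
        ts, m = make_synthetic_trackset()
        interior = m.interior_cells()
        culprit = interior[len(interior) // 2]
        # scripted velocity spike (16 um/min) relative to static neighbours
        for k in (5, 6):
            cell = ts.frames[k].cells[culprit]
            cell.polygon = cell.polygon + [8.0, 0.0]
            cell.centroid = cell.centroid + [8.0, 0.0]
        survivors_before = set(ts.cell_ids())
        _, counts = em.quality_filter(ts)
        removed = survivors_before - set(ts.cell_ids())
        assert counts["relative_velocity"] == 1
        assert removed == {culprit}

    def test_short_track_removed(self):
        ts, _ = make_synthetic_trackset()
        cid = next(iter(ts.frames[0].cells))
        for f in ts.frames[2:]:
            f.cells.pop(cid, None)
            for pair in [p for p in f.interfaces if cid in p]:
                del f.interfaces[pair]
        _, counts = em.quality_filter(ts, em.QualityThresholds(min_frames=4))
        assert counts["n_frames"] >= 1
        assert cid not in ts.cell_ids()


class TestDistanceFromMesectoderm:
    def test_lattice_row_distances(self):
        ts, _ = make_synthetic_trackset(n_frames=6, n_cells=220, seed=3)
        axes = em.Axes(midline_point=(0.0, 0.0))
        em.classify_cells(ts, axes, mesoderm_half_width_cells=2)
        dist = em.distance_from_mesectoderm(ts, axes, reference_time_min=1.0)
        frame = ts.frames[2]
        d = np.median([2 * np.sqrt(c.area_um2 / np.pi)
                       for c in frame.cells.values()])
        ect = {cid: c for cid, c in frame.cells.items()
               if c.type_label == "ectoderm"}
        first_row = [cid for cid, c in ect.items()
                     if dist[cid] == pytest.approx(0.0, abs=d / 2)]
        assert first_row  # first ectodermal row sits at ~0 um
        # rows one diameter further out are ~one row spacing away
        third = [dist[cid] for cid, c in ect.items()
                 if 2 * d <= dist[cid] < 3 * d]
        assert third  # distances propagate outward in row bands
        # mesodermal cells have no defined distance
        meso = [cid for cid, c in frame.cells.items()
                if c.type_label == "mesoderm"]
        assert all(np.isnan(dist[cid]) for cid in meso)

    def test_error_without_ectoderm(self):
        ts, _ = make_synthetic_trackset(n_frames=6)
        axes = em.Axes()
        em.classify_cells(ts, axes, mesoderm_half_width_cells=50)
        with pytest.raises(ValueError):
            em.distance_from_mesectoderm(ts, axes, reference_time_min=1.0)


class TestTableRoundTrip:
    def test_trackset_tables_round_trip(self, tmp_path):
        ts, _ = make_synthetic_trackset(n_frames=4)
        em.save_trackset(ts, tmp_path)
        back = em.load_trackset(tmp_path)
        assert back.n_frames == ts.n_frames
        f0, b0 = ts.frames[1], back.frames[1]
        assert set(f0.cells) == set(b0.cells)
        assert set(f0.interfaces) == set(b0.interfaces)
        cid = next(iter(f0.cells))
        assert b0.cells[cid].centroid == pytest.approx(f0.cells[cid].centroid,
                                                       abs=1e-4)
        pair = next(iter(f0.interfaces))
        assert b0.interfaces[pair].length_um == pytest.approx(
            f0.interfaces[pair].length_um, abs=1e-4
        )
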