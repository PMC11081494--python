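"""Mesh reconstruction and cell typing from a label-image movie.

Renders a synthetic movie to integer label images (the format a segmentation
pipeline produces), rebuilds per-frame geometry with `build_frame`, links
cells across frames by maximal overlap, assigns cell types from midline
proximity, and applies the track-quality filter.
"""

import numpy as np

from epimorph import mesh as em
from epimorph import synth

movie = synth.preset_movie("twist", seed=4, n_cells=80, n_swaps=0,
                           t_start=0.0, t_end=3.0)
rendered = synth.render_movie(movie, synth.IntensityModel(), seed=4)

frames = [
    em.build_frame(r["labels"], r["pixel_size_um"], index=i, time_s=i * 30.0)
    for i, r in enumerate(rendered)
]
frames = em.relabel_sequence(frames)
ts = em.TrackSet(frames, frame_interval_s=30.0)

axes = em.Axes(midline_point=(0.0, 0.0))  # ventral midline at the field edge
em.classify_cells(ts, axes, mesoderm_half_width_cells=5)
ts, removals = em.quality_filter(ts)

n_types = {}
for cell in ts.frames[0].cells.values():
    n_types[cell.type_label] = n_types.get(cell.type_label, 0) + 1

print(f"frames rebuilt from labels: {ts.n_frames}")
print(f"tracks: {len(ts.cell_ids())}")
print(f"interfaces in frame 0: {len(ts.frames[0].interfaces)}")
print(f"cell types in frame 0: {n_types}")
print(f"quality removals: {removals}")
print()
print("Geometry, tracking, and typing reconstructed from images alone; with")
print("a twist-like narrow mesoderm (half-width 5 rows) the cells nearest")
print("the ventral midline are typed mesoderm/mesectoderm and excluded from")
print("ectoderm analyses downstream.")
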