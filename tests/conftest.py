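"""Shared fixtures: synthetic movies and rendered frames reused across the
suite (session-scoped; everything is generated programmatically)."""

import warnings

import numpy as np
import pytest

from epimorph import synth

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def affine_movie():
    """200-cell movie under a prescribed pure-shear affine flow, no swaps."""
    mesh = synth.generate_tessellation(200, jitter=0.2, seed=11)
    flow = synth.UniformFlow(np.array([[0.02, 0.0], [0.0, -0.02]]))
    times = np.arange(0.0, 6.01, 0.5)
    return synth.simulate_movie(mesh, flow, times), flow


@pytest.fixture(scope="session")
def swap_movie():
    """200-cell movie with 25 scripted T1 swaps and no background flow."""
    mesh = synth.generate_tessellation(200, jitter=0.2, seed=2)
    times = np.arange(0.0, 30.01, 0.5)
    schedule = synth.make_swap_schedule(mesh, 25, t_range_min=(4.0, 26.0), seed=3)
    return synth.simulate_movie(mesh, synth.UniformFlow(), times, schedule)


@pytest.fixture(scope="session")
def rendered_frame():
    """150-cell tessellation rendered with the default intensity model."""
    mesh = synth.generate_tessellation(150, jitter=0.2, seed=5)
    render = synth.render_frame(mesh, synth.IntensityModel(), seed=7)
    frame = synth.mesh_to_frame(mesh,
                                pixel_size_um=render["pixel_size_um"])
    return mesh, frame, render


@pytest.fixture(scope="session")
def cohort_results():
    """Full wild-type-like vs twist-like replay at the preset study scale."""
    from epimorph.pipeline import PipelineConfig, run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=1))
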