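"""Shared fixtures: phantoms run once per session through the pipeline."""

import numpy as np
import pytest

import vesselvol as vv


@pytest.fixture(scope="session")
def noisy_tube():
    """Straight tube (r = 4 voxels = 60 um, L = 60 voxels) with blur and
    seeded noise, plus its mask and radius-annotated graph."""
    grid, truth = vv.preset_tube(
        radius_voxels=4, length_voxels=60, blur_sigma_voxels=0.5, noise_sigma=8.0, seed=1
    )
    mask = vv.clean_mask(vv.threshold_segment(grid, 127.5), keep_largest=True)
    graph = vv.estimate_radii(vv.build_graph(vv.skeletonize(mask)), mask)
    return {"grid": grid, "truth": truth, "mask": mask, "graph": graph}


@pytest.fixture(scope="session")
def long_tube():
    """Longer tube (L = 120 voxels) for segment-extraction tests."""
    grid, truth = vv.preset_tube(
        radius_voxels=4, length_voxels=120, blur_sigma_voxels=0.5, noise_sigma=8.0, seed=3
    )
    mask = vv.clean_mask(vv.threshold_segment(grid, 127.5), keep_largest=True)
    graph = vv.estimate_radii(vv.build_graph(vv.skeletonize(mask)), mask)
    return {"grid": grid, "truth": truth, "mask": mask, "graph": graph}


@pytest.fixture(scope="session")
def y_phantom():
    grid, truth = vv.preset_bifurcation()
    mask = vv.threshold_segment(grid, 127.5)
    graph = vv.estimate_radii(vv.build_graph(vv.skeletonize(mask)), mask)
    return {"grid": grid, "truth": truth, "mask": mask, "graph": graph}


@pytest.fixture(scope="session")
def ring_phantom():
    grid, truth = vv.preset_ring()
    mask = vv.threshold_segment(grid, 127.5)
    graph = vv.build_graph(vv.skeletonize(mask))
    return {"grid": grid, "truth": truth, "mask": mask, "graph": graph}


@pytest.fixture(scope="session")
def vaso_report():
    """Full pipeline on the matched sham/20%-spasm phantom pair."""
    from vesselvol.pipeline import analyze_vasospasm_pair

    return analyze_vasospasm_pair(severity=0.2, seed=1)
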