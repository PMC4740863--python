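"""Shared fixtures: the default study conditions, built once per session.

The study phantom is the default elliptic layered head (90 x 110 mm
semi-axes, ~12 mm skin/fat/skull/CSF shell); the imaging model is
calibrated from the phantom's own delay curves, the scan is the
equiangular 32-position ring at 15 mm standoff, and images use a 1 mm
grid over the 300 x 300 mm area (the fine 0.5 mm default grid is used
where sub-millimetre localization is asserted).
"""

import numpy as np
import pytest

import mwbrain as m
from mwbrain.phantom import (
    ForwardConfig,
    insert_target,
    make_head_phantom,
    permittivity_curves_from_phantom,
    simulate_reflection,
)

STUDY_TARGET = (0.0, 65.0)  # 20x20 mm bleed straddling the gray/white edge


@pytest.fixture(scope="session")
def base_phantom():
    return make_head_phantom()


@pytest.fixture(scope="session")
def calibrated_model(base_phantom):
    curves = permittivity_curves_from_phantom(base_phantom, np.arange(0, 360, 45))
    return m.fit_permittivity_model(curves).model


@pytest.fixture(scope="session")
def study_geometry(base_phantom):
    return m.make_offset_scan(base_phantom.boundary, 15.0, 32)


@pytest.fixture(scope="session")
def grid_1mm():
    return m.ImagingGrid(extent=(300.0, 300.0), cell_size=1.0)


@pytest.fixture(scope="session")
def study_table(study_geometry, base_phantom, grid_1mm, calibrated_model):
    return m.build_travel_time_table(
        study_geometry, base_phantom.boundary, grid_1mm, calibrated_model
    )


@pytest.fixture(scope="session")
def target_phantom(base_phantom):
    return insert_target(base_phantom, STUDY_TARGET, 20.0, 20.0)


@pytest.fixture(scope="session")
def clean_dataset(target_phantom, study_geometry):
    return simulate_reflection(
        target_phantom, study_geometry, m.FrequencySweep(), ForwardConfig(seed=1)
    )
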