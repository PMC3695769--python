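import numpy as np
import pytest

from cmrpost.geometry import (
    AHAModel,
    ContourStack,
    SliceGeometry,
    StudyMeta,
    regular_polygon,
    standard_segment_spans,
)


@pytest.fixture
def annulus_96():
    """Concentric endo/epi circles (radii 16/28 mm) on a 96×96 1-mm grid."""
    endo = regular_polygon(48, 48, 16, 128, "endocardial")
    epi = regular_polygon(48, 48, 28, 128, "epicardial")
    rows, cols = np.mgrid[0:96, 0:96]
    radius = np.hypot(cols - 48.0, rows - 48.0)
    return endo, epi, radius


@pytest.fixture
def single_slice_model():
    """One basal slice with the anterior RV insertion at 90 degrees."""
    return AHAModel(16, {0: "basal"}, {0: 90.0}, standard_segment_spans(16))


def make_single_slice_stack(contours_by_role, thickness=8.0, gap=2.0, **meta):
    slices = [SliceGeometry(0, 0.0, thickness, gap)]
    contours = {(0, 0, role): [poly] for role, poly in contours_by_role.items()}
    return ContourStack(slices, contours, 1, StudyMeta(**meta))
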