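import numpy as np
import pytest

from patchrig import scene as scn
from patchrig import vision


SINGLE_CELL_CONFIG = {
    "cells": [{"id": 0, "center": [0.0, 0.0, -120.0], "diameter": 10.0,
               "channel": "green", "peak_intensity": 15000.0}],
    "motion": {"breathing_amplitude": 0.0, "heartbeat_amplitude": 0.0},
}


@pytest.fixture
def single_cell_scene():
    """One 10-um soma at (0, 0, -120) um, physiological motion off."""
    return scn.make_scene(SINGLE_CELL_CONFIG, seed=1)


@pytest.fixture
def seg_config():
    return vision.SegmentationConfig()


@pytest.fixture
def acquire_segment(single_cell_scene, seg_config):
    """Noise-free frame source + segmenter for the single-cell scene."""
    scene = single_cell_scene

    def acquire(z):
        return scn.render_frame(scene, z, 0.0, noise=False,
                                include_pipette=False)

    def segment(frame):
        return (vision.segment_frame(frame, seg_config),
                frame.geometry(scene.imaging))

    return acquire, segment
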