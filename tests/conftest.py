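import numpy as np
import pytest
from PIL import Image

from chromaflow import (
    BUILTIN_ASSAYS,
    PreprocessConfig,
    Role,
    render_sample,
    run_session,
    scene_for_assay,
)


@pytest.fixture
def uniform_png(tmp_path):
    """Write a uniform-color PNG and return (path, color)."""

    def make(color=(120, 80, 60), size=(100, 100), mode="RGB", name="img.png"):
        h, w = size
        arr = np.zeros((h, w, len(mode)), dtype=np.uint8)
        arr[..., : min(3, len(mode))] = color[: min(3, len(mode))]
        if "A" in mode:
            arr[..., -1] = 200
        path = tmp_path / name
        Image.fromarray(arr.squeeze(), mode=mode).save(path)
        return path

    return make


@pytest.fixture
def fast_cfg():
    """Preprocessing config that skips the upscale (images already small)."""
    return PreprocessConfig(target_long_edge=100)


@pytest.fixture
def calibrated_session():
    """A clean noise-free calibration state per assay."""

    def make(assay_id="uric_acid", **scene_overrides):
        assay = BUILTIN_ASSAYS[assay_id]
        scene = scene_for_assay(assay_id, **scene_overrides)
        water = render_sample(0.0, Role.WATER, scene, assay_id)
        blank = render_sample(0.0, Role.BLANK, scene, assay_id)
        std = render_sample(
            assay.standard_concentration, Role.STANDARD, scene, assay_id
        )
        state = run_session(water, blank, std, assay)
        return state, assay, scene

    return make
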