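import numpy as np
import pytest

import ventriflow as vf


@pytest.fixture(scope="session")
def tube_88():
    """Tube with 8 diastolic / 8 systolic frames: closed-form 60/20/20/0."""
    return vf.make_tube_phantom(10, 4, 1.0, 8, 8)


@pytest.fixture(scope="session")
def tube_55():
    """Tube with 5/5 frames: closed-form 0/50/50/0 (no direct flow)."""
    return vf.make_tube_phantom(10, 4, 1.0, 5, 5)


@pytest.fixture(scope="session")
def rotation_cycle():
    """Solid-body rotation completing one full turn per cycle (16 frames)."""
    return vf.make_rotation_phantom(10, 2 * np.pi / 16, 16)


@pytest.fixture(scope="session")
def lv_coarse():
    """Coarse LV phantom for fast unit tests (3 mm, 12 frames)."""
    return vf.make_lv_phantom(160.0, 62.0, n_frames=12, spacing_mm=3.0,
                              oracle_substeps=60)


@pytest.fixture(scope="session")
def lv_standard():
    """Standard-scale LV phantom (2 mm, 20 frames, dense oracle at 100 substeps)."""
    return vf.make_lv_phantom()


@pytest.fixture(scope="session")
def lv_standard_result(lv_standard):
    return vf.analyze(lv_standard.field, lv_standard.lv_mask, lv_standard.mitral,
                      lv_standard.aortic, lv_standard.phases)
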