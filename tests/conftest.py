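import numpy as np
import pytest

from aggsplit.core import ChannelGeometry, PipelineConfig
from aggsplit.detection import calibrate_threshold
from aggsplit.synthetic import SceneSpec, render_stack, sample_ground_truth


@pytest.fixture(scope="session")
def geometry():
    """Full-scale study geometry: 100x40 um T-junction, 1216x700 px frames."""
    return ChannelGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced frame for rendering-heavy unit tests."""
    return ChannelGeometry(frame_shape_px=(260, 420), junction_origin_px=(80.0, 210.0))


@pytest.fixture(scope="session")
def config(geometry):
    return PipelineConfig(geometry=geometry)


@pytest.fixture(scope="session")
def small_config(small_geometry):
    return PipelineConfig(geometry=small_geometry)


@pytest.fixture(scope="session")
def reference_stack(geometry):
    """Non-aggregating (dispersed single-cell) calibration stack."""
    spec = SceneSpec(n_frames=10, structures_per_frame=80, mean_Astar=1.0,
                     rng_seed=7)
    return render_stack(sample_ground_truth(spec, geometry), geometry, spec,
                        label="reference")


@pytest.fixture(scope="session")
def calibrated(reference_stack, config):
    """(threshold, achieved mean area) from the standard reference."""
    return calibrate_threshold(reference_stack, config)
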