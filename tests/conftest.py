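import numpy as np
import pytest

from fidqa import phantom, pipeline


def make_config(**overrides) -> phantom.PhantomConfig:
    """Noise-free, migration-free baseline phantom used by many tests."""
    defaults = dict(
        seed=11,
        noise_sd=0.0,
        migration_sigma=0.0,
        frame_offset_mm=(2.0, -3.0),
    )
    defaults.update(overrides)
    return phantom.PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def clean_pair():
    """One deterministic noise-free phantom pair shared across tests."""
    return phantom.generate_phantom_pair(make_config())


def default_roi(truth, shape, margin_mm=15.0):
    return pipeline.roi_around_markers(
        truth.drr_marker_com, truth.pixel_spacing_drr, shape, margin_mm=margin_mm
    )


def matched_error_px(detected_mm: np.ndarray, truth_mm: np.ndarray, spacing: float) -> float:
    """Max nearest-neighbour distance between detected and true centres, in px."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(np.asarray(truth_mm)).query(np.asarray(detected_mm))
    return float(d.max() / spacing)
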