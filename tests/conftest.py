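import warnings

import numpy as np
import pytest

import colonytrack as ct


def make_object(x: float, y: float, frame_index: int = 0, size: int = 2):
    """DetectedObject whose centroid sits at (x, y): a size x size block."""
    r0, c0 = int(round(y)), int(round(x))
    rows, cols = np.mgrid[r0 : r0 + size, c0 : c0 + size]
    obj = ct.DetectedObject(
        frame_index=frame_index,
        rows=rows.ravel(),
        cols=cols.ravel(),
        bbox=(r0, c0, r0 + size, c0 + size),
    )
    # shift so the centroid is exactly (x, y)
    dy = y - obj.rows.mean()
    dx = x - obj.cols.mean()
    if abs(dx) > 1e-9 or abs(dy) > 1e-9:
        # fall back to a single pixel at the rounded location for odd offsets
        obj = ct.DetectedObject(
            frame_index=frame_index,
            rows=np.array([r0]),
            cols=np.array([c0]),
            bbox=(r0, c0, r0 + 1, c0 + 1),
        )
    return obj


@pytest.fixture(scope="session")
def small_cfg():
    return ct.SimulationConfig(
        n_colonies=6,
        seed=11,
        duration_days=6,
        frame_shape=(640, 640),
        debris_count=6,
        min_colony_separation_px=150.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return ct.simulate_ground_truth(small_cfg)


@pytest.fixture(scope="session")
def small_seq(small_truth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ct.render_sequence(small_truth)


@pytest.fixture(scope="session")
def small_results(small_seq):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ct.run_pipeline(small_seq, ct.PipelineConfig())
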