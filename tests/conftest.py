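import numpy as np
import pandas as pd
import pytest

from budmetrics.imaging import SegmentationConfig
from budmetrics.synthetic import ShapeSpec, render_scene


@pytest.fixture(scope="session")
def three_bud_scene():
    """Three well-separated bud shapes on one noisy canvas, with truth."""
    shapes = [
        ShapeSpec("stadium", 2.65, 0.35, (300, 600), 15.0),
        ShapeSpec("ellipse", 2.0, 0.30, (700, 300), 100.0),
        ShapeSpec("stadium", 1.6, 0.40, (950, 850), 60.0),
    ]
    scan, truth = render_scene(shapes, dpi=600, canvas_px=(1200, 1200), seed=11)
    return scan, truth


@pytest.fixture
def seg_cfg():
    return SegmentationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
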