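import numpy as np
import pytest

from dearray.pseudo_sim import PseudoSpec, make_template
from dearray.segmentation import SegmentationParams


@pytest.fixture(scope="session")
def template_slide():
    return make_template(PseudoSpec(seed=42))


@pytest.fixture(scope="session")
def template_image(template_slide):
    return template_slide.render()


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def lattice_centroids(n_rows: int, n_cols: int, pitch: float = 50.0,
                      origin: float = 100.0) -> np.ndarray:
    """Perfect lattice positions in row-major order."""
    pts = [(origin + j * pitch, origin + i * pitch)
           for i in range(n_rows) for j in range(n_cols)]
    return np.array(pts, dtype=float)
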