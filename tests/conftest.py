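import numpy as np
import pytest

from biotransparency import make_grid, HyperspectralCube


@pytest.fixture(scope="session")
def study_grid():
    """The study's sampling grid: 380-1000 nm every 5 nm, 125 bands."""
    return make_grid(380, 1000, 5)


@pytest.fixture
def flat_cube(study_grid):
    """A 32x32 cube of uniform background at 1000 counts."""
    arr = np.full((32, 32, study_grid.n_bands), 1000.0, dtype=np.float32)
    return HyperspectralCube(arr, study_grid, pixel_size_um=2.5)


def match_regions_to_truths(regions, scene, truths):
    """Pair each segmented region with the ground truth of the nearest egg
    centre -- robust to sort-order ties under noise."""
    centers = np.array([e.center_px for e in scene.eggs])
    pairs = []
    for region in regions:
        d = np.hypot(centers[:, 0] - region.centroid[0],
                     centers[:, 1] - region.centroid[1])
        pairs.append((region, truths[int(np.argmin(d))]))
    return pairs
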