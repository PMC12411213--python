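import numpy as np
import pytest

from nwuct.atlas_regions import build_synthetic_atlas


@pytest.fixture(scope="session")
def atlas():
    """The default synthetic head atlas, shared across the whole run."""
    return build_synthetic_atlas()


@pytest.fixture(scope="session")
def brain_points(atlas):
    """Subsampled world coordinates of brain voxels (for displacement checks)."""
    idx = np.argwhere(atlas.brain_mask.as_bool())[::50]
    return atlas.template.world_coords(idx)


def mean_displacement_mm(transform, points):
    """Mean |T(p) - p| over a point cloud, in mm."""
    moved = transform.apply(points)
    return float(np.linalg.norm(moved - points, axis=1).mean())
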