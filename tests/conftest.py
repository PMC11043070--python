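import numpy as np
import pytest

import ghostmap as gm


@pytest.fixture(scope="session")
def small_stack():
    """Noiseless 3D stack with 40 well-separated cells, 10% ghost."""
    spec = gm.ImageStackSpec(
        shape=(24, 160, 160), n_cells=40, ghost_fraction=0.10,
        channels=[gm.ChannelSpec("reporter", 100.0, 100.0, 0.0),
                  gm.ChannelSpec("pomc", 80.0, 0.0, 0.0)],
        seed=11)
    return gm.gen_image_stack(spec)


@pytest.fixture(scope="session")
def shifted_cloud():
    """Default study-condition point cloud: 200 um caudal ghost shift."""
    return gm.gen_point_cloud(gm.SpatialSpec(seed=1))


@pytest.fixture(scope="session")
def default_counts():
    """76-cell count matrix shaped like the patch-seq cohort (45/13/12/6)."""
    return gm.gen_count_matrix(gm.CountMatrixSpec(seed=1))


@pytest.fixture(scope="session")
def noiseless_cohort():
    recs, truth = gm.gen_ephys_cohort(gm.EphysCohortSpec(
        n_per_class={"activated": 2, "inhibited": 2, "nonresponsive": 2},
        noise_sd=0.0, seed=3))
    return recs, truth
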