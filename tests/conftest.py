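import numpy as np
import pytest

from volseg import fixtures
from volseg.core import LayeredDataset
from volseg.geometry import VolumeGeometry


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_ds(rng):
    """Random 12x16x20 uint8 dataset with anisotropic geometry."""
    img = rng.integers(0, 256, size=(12, 16, 20), dtype=np.uint8)
    return LayeredDataset(img, VolumeGeometry((5.0, 5.0, 20.0), "nm", (0.0, 0.0, 0.0)))


@pytest.fixture()
def blob_phantom():
    return fixtures.make_blobs_phantom(shape=(40, 40, 40), n=3, radius=(5, 8), seed=11)


@pytest.fixture(scope="session")
def mitotic_run():
    """Full 13-step workflow on the mitotic phantom (shared; ~15 s)."""
    import scipy.ndimage as ndi
    from volseg.pipelines import mitotic_cell_workflow

    ds, gt = fixtures.make_mitotic_phantom(seed=0)
    central = ndi.binary_dilation(gt.mask_of("chromosome"), iterations=3)
    out, report = mitotic_cell_workflow(ds, central_mask=central)
    return ds, gt, out, report
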