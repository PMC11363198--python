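import numpy as np
import pytest

import fsubextract as fx


@pytest.fixture(scope="session")
def default_spec() -> fx.PhantomSpec:
    """Two patches on the slab, one 100-streamline connecting bundle, 400 decoys."""
    return fx.PhantomSpec(
        patches=[
            fx.PatchSpec("A", (-9.0, 0.0), radius_mm=5.0, peak_stat=10.0),
            fx.PatchSpec("B", (9.0, 0.0), radius_mm=5.0, peak_stat=8.0),
        ],
        bundles=[fx.BundleSpec("target", "A", "B", n_streamlines=100,
                               endpoint_offset_mm=0.0, jitter_sd_mm=0.0)],
        n_decoys=400,
        seed=42,
    )


@pytest.fixture(scope="session")
def phantom(default_spec) -> fx.PhantomDataset:
    return fx.make_slab_phantom(default_spec)


@pytest.fixture(scope="session")
def gmwmi_mask(phantom) -> fx.BinaryMask:
    return fx.binarize(fx.compute_gmwmi(phantom.seg))


@pytest.fixture(scope="session")
def search_masks(phantom, gmwmi_mask):
    """fROI-GMWMI intersection masks for patches A and B."""
    out = {}
    for name in ("A", "B"):
        proj = fx.project_label_to_volume(phantom.mesh, phantom.labels[name], gmwmi_mask)
        out[name] = fx.intersect_masks(proj, gmwmi_mask)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
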